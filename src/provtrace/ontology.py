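"""Vocabulary and identifier grammar of the serialized provenance.

The RDF serialization extends the W3C PROV-O ontology with classes and
properties for function executions, data objects, files, and name--value
pairs, using the Alpaca provenance vocabulary (namespace
``https://purl.org/alpaca#``) so that the files interoperate with existing
consumers of that format.

Every object, file, function, execution and script is identified by a
deterministic URN. Equal content implies an equal URN across records,
sessions and processes, which is what makes provenance graphs from
separate runs unify when merged.
"""

from __future__ import annotations

from rdflib import Namespace, URIRef

PROV = Namespace("http://www.w3.org/ns/prov#")
ALPACA = Namespace("https://purl.org/alpaca#")

# Ontology classes
DataObjectEntity = ALPACA.DataObjectEntity
FileEntity = ALPACA.FileEntity
FunctionExecution = ALPACA.FunctionExecution
ScriptAgent = ALPACA.ScriptAgent
Function = ALPACA.Function
NameValuePair = ALPACA.NameValuePair

#: Serialized hashSource literal per internal hash method.
HASH_SOURCE_LITERALS = {
    "content_sha1": "joblib_SHA1",
    "builtin_hash": "Python_hash",
    "uuid": "UUID",
}

#: Host-language token used in the URN grammar.
LANGUAGE_TOKEN = "Python"


def object_urn(authority: str, class_name: str, object_hash: str) -> URIRef:
    """``urn:[authority]:alpaca:object:Python:[class name]:[object hash]``
    where the class name carries the full dotted module path."""
    return URIRef(f"urn:{authority}:alpaca:object:{LANGUAGE_TOKEN}:"
                  f"{class_name}:{object_hash}")


def file_urn(authority: str, hash_type: str, file_hash: str) -> URIRef:
    return URIRef(f"urn:{authority}:alpaca:file:{hash_type}:{file_hash}")


def function_urn(authority: str, function_name: str) -> URIRef:
    return URIRef(f"urn:{authority}:alpaca:function:{LANGUAGE_TOKEN}:"
                  f"{function_name}")


def execution_urn(authority: str, script_file_hash: str, session_id: str,
                  function_name: str, execution_id: str) -> URIRef:
    return URIRef(f"urn:{authority}:alpaca:function_execution:"
                  f"{LANGUAGE_TOKEN}:{script_file_hash}:{session_id}:"
                  f"{function_name}#{execution_id}")


def script_urn(authority: str, script_file_name: str, script_file_hash: str,
               session_id: str) -> URIRef:
    return URIRef(f"urn:{authority}:alpaca:script:{LANGUAGE_TOKEN}:"
                  f"{script_file_name}:{script_file_hash}#{session_id}")
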