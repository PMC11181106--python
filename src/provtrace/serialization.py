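"""Mapping of the capture history onto PROV-O RDF, and file I/O.

Each function-execution record contributes one ``FunctionExecution``
activity, one (deduplicated) ``Function`` node, entity nodes for its
inputs and outputs, and one ``ScriptAgent`` per session. Parameters,
attributes and annotations are serialized as ``NameValuePair`` blank
nodes. Documents are read and written in any RDF syntax supported by
rdflib (Turtle by default), and merging documents is a plain triple-set
union: entities with equal URNs unify automatically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Dict, Iterable, List, Optional, Sequence, Set, Union

from rdflib import RDF, RDFS, XSD, BNode, Graph, Literal, URIRef

from . import _ids, ontology
from .descriptors import (DataObjectDescriptor, Descriptor, FileDescriptor,
                          FunctionInfo)
from .records import ATTRIBUTE, FunctionExecutionRecord, INDEX
from .session import CaptureSession, current_session

#: Serialization formats by file extension.
_EXTENSION_FORMATS = {
    ".ttl": "turtle", ".turtle": "turtle",
    ".rdf": "xml", ".xml": "xml",
    ".nt": "nt", ".ntriples": "nt",
    ".json": "json-ld", ".jsonld": "json-ld",
    ".n3": "n3", ".trig": "trig",
}
SUPPORTED_FORMATS = ("turtle", "xml", "nt", "json-ld", "n3", "trig")

_MEMBERSHIP_PROPERTY = {
    ATTRIBUTE: ontology.ALPACA.fromAttribute,
    INDEX: ontology.ALPACA.containerIndex,
    # slice
}


def _literal(value: Any) -> Literal:
    if isinstance(value, bool):
        return Literal(value, datatype=XSD.boolean)
    if isinstance(value, int):
        return Literal(value, datatype=XSD.integer)
    if isinstance(value, float):
        return Literal(value, datatype=XSD.double)
    return Literal(str(value), datatype=XSD.string)


def guess_format(path: Union[str, Path],
                 format: Optional[str] = None) -> str:
    if format:
        if format not in SUPPORTED_FORMATS:
            raise ValueError(f"unknown RDF format {format!r}; supported: "
                             f"{', '.join(SUPPORTED_FORMATS)}")
        return format
    return _EXTENSION_FORMATS.get(Path(path).suffix.lower(), "turtle")


class ProvenanceDocument:
    """An RDF graph of serialized provenance records."""

    def __init__(self, graph: Optional[Graph] = None) -> None:
        self.graph = graph if graph is not None else Graph()
        self._bind_namespaces()
        self._described: Set[URIRef] = set()

    def _bind_namespaces(self) -> None:
        self.graph.bind("prov", ontology.PROV)
        self.graph.bind("alpaca", ontology.ALPACA)
        self.graph.bind("xsd", XSD)
        self.graph.bind("rdfs", RDFS)

    # -- building -----------------------------------------------------

    @classmethod
    def from_session(cls, session: CaptureSession) -> "ProvenanceDocument":
        document = cls()
        document.add_session(session)
        return document

    def add_session(self, session: CaptureSession) -> None:
        """Serialize every record of *session* into this document."""
        agent = ontology.script_urn(session.authority, session.script_name,
                                    session.script_file_hash,
                                    session.session_id)
        self.graph.add((agent, RDF.type, ontology.ScriptAgent))
        self.graph.add((agent, ontology.ALPACA.scriptPath,
                        _literal(session.script_path)))
        for record in session.history:
            self._add_record(session, agent, record)

    def _name_value_pair(self, subject: URIRef, predicate: URIRef,
                         name: str, value: Any) -> None:
        # blank-node ids come from the injectable id source, so documents
        # built under fixed ids serialize byte-identically
        pair = BNode("N" + _ids.new_uuid().replace("-", ""))
        self.graph.add((subject, predicate, pair))
        self.graph.add((pair, RDF.type, ontology.NameValuePair))
        self.graph.add((pair, ontology.ALPACA.pairName, _literal(name)))
        self.graph.add((pair, ontology.ALPACA.pairValue, _literal(value)))

    def _entity_uri(self, authority: str, descriptor: Descriptor) -> URIRef:
        if isinstance(descriptor, FileDescriptor):
            return ontology.file_urn(authority, descriptor.hash_type,
                                     descriptor.file_hash)
        return ontology.object_urn(authority, descriptor.qualified_type,
                                   descriptor.content_hash)

    def _add_entity(self, authority: str, descriptor: Descriptor) -> URIRef:
        uri = self._entity_uri(authority, descriptor)
        if uri in self._described:
            return uri
        self._described.add(uri)
        if isinstance(descriptor, FileDescriptor):
            self.graph.add((uri, RDF.type, ontology.FileEntity))
            self.graph.add((uri, ontology.ALPACA.filePath,
                            _literal(descriptor.path)))
            return uri
        self.graph.add((uri, RDF.type, ontology.DataObjectEntity))
        self.graph.add((uri, ontology.ALPACA.hashSource, _literal(
            ontology.HASH_SOURCE_LITERALS[descriptor.hash_method])))
        for name, value in descriptor.attributes.items():
            self._name_value_pair(uri, ontology.ALPACA.hasAttribute,
                                  name, value)
        for name, value in descriptor.annotations.items():
            self._name_value_pair(uri, ontology.ALPACA.hasAnnotation,
                                  name, value)
        return uri

    def _add_function(self, authority: str, info: FunctionInfo) -> URIRef:
        uri = ontology.function_urn(authority, info.qualified_name)
        if uri in self._described:
            return uri
        self._described.add(uri)
        self.graph.add((uri, RDF.type, ontology.Function))
        self.graph.add((uri, ontology.ALPACA.functionName,
                        _literal(info.name)))
        self.graph.add((uri, ontology.ALPACA.implementedIn,
                        _literal(info.module_path)))
        self.graph.add((uri, ontology.ALPACA.functionVersion,
                        _literal(info.version)))
        return uri

    def _add_record(self, session: CaptureSession, agent: URIRef,
                    record: FunctionExecutionRecord) -> None:
        authority = session.authority
        execution = ontology.execution_urn(
            authority, session.script_file_hash, session.session_id,
            record.function.qualified_name, record.execution_id)
        graph = self.graph
        graph.add((execution, RDF.type, ontology.FunctionExecution))
        graph.add((execution, ontology.PROV.wasAssociatedWith, agent))
        graph.add((execution, ontology.ALPACA.usedFunction,
                   self._add_function(authority, record.function)))
        graph.add((execution, ontology.ALPACA.executionOrder,
                   Literal(record.order, datatype=XSD.int)))
        if record.code_statement:
            graph.add((execution, ontology.ALPACA.codeStatement,
                       _literal(record.code_statement)))
        if record.time_start:
            graph.add((execution, ontology.PROV.startedAtTime,
                       Literal(record.time_start, datatype=XSD.dateTime)))
        if record.time_end:
            graph.add((execution, ontology.PROV.endedAtTime,
                       Literal(record.time_end, datatype=XSD.dateTime)))
        for name, value in record.parameters.items():
            self._name_value_pair(execution, ontology.ALPACA.hasParameter,
                                  name, value)
        for descriptor in record.inputs.values():
            entity = self._add_entity(authority, descriptor)
            graph.add((execution, ontology.PROV.used, entity))
        for descriptor in record.outputs:
            entity = self._add_entity(authority, descriptor)
            graph.add((entity, ontology.PROV.wasGeneratedBy, execution))
            graph.add((entity, ontology.PROV.wasAttributedTo, agent))
        for membership in record.memberships:
            container = self._add_entity(authority, membership.container)
            element = self._add_entity(authority, membership.element)
            graph.add((container, ontology.PROV.hasMember, element))
            prop = _MEMBERSHIP_PROPERTY.get(membership.relation,
                                            ontology.ALPACA.containerSlice)
            graph.add((element, prop, _literal(membership.accessor)))

    # -- I/O and merging ----------------------------------------------

    def save(self, path: Union[str, Path],
             format: Optional[str] = None) -> None:
        """Write the document; the format defaults from the extension
        (Turtle for ``.ttl`` and anything unrecognized)."""
        self.graph.serialize(destination=str(path),
                             format=guess_format(path, format))

    @classmethod
    def read(cls, paths: Union[str, Path, Sequence[Union[str, Path]]],
             format: Optional[str] = None) -> "ProvenanceDocument":
        """Parse one or more RDF files into a single document."""
        if isinstance(paths, (str, Path)):
            paths = [paths]
        document = cls()
        for path in paths:
            try:
                document.graph.parse(str(path),
                                     format=guess_format(path, format))
            except Exception as exc:
                raise ValueError(f"cannot parse RDF file {path}: "
                                 f"{exc}") from exc
        return document

    def __len__(self) -> int:
        return len(self.graph)


def merge(documents: Iterable[ProvenanceDocument]) -> ProvenanceDocument:
    """Triple-set union of provenance documents.

    Entities with equal URNs unify automatically, so records of the same
    data produced by different runs connect without any rewriting logic.
    """
    union = Graph()
    for document in documents:
        for triple in document.graph:
            union.add(triple)
    return ProvenanceDocument(union)


def build_document(session: Optional[CaptureSession] = None
                   ) -> ProvenanceDocument:
    """Serialize the (current, by default) session into a new document."""
    session = session or current_session()
    if session is None:
        raise RuntimeError("no capture session; call activate() first")
    return ProvenanceDocument.from_session(session)


def save_provenance(path: Union[str, Path],
                    format: Optional[str] = None,
                    session: Optional[CaptureSession] = None) -> None:
    """Serialize the history of the current session to *path*."""
    build_document(session).save(path, format=format)
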