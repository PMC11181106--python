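"""PROV-O mapping: node classes, URNs, round-trips, merging."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from rdflib import RDF, Graph, URIRef
from rdflib.compare import isomorphic

import provtrace
from provtrace import (Provenance, activate, build_document, configure,
                       deactivate, deterministic_ids, merge,
                       save_provenance)
from provtrace import ontology
from provtrace.serialization import ProvenanceDocument, guess_format

ALPACA = ontology.ALPACA
PROV = ontology.PROV


@Provenance(inputs=["signal"])
def _welch_like(signal, frequency_resolution=2.0):
    return signal * 0.5


@Provenance(file_input=["path"])
def _read_file(path):
    return Path(path).read_bytes()


@Provenance(inputs=["data"], file_output=["path"])
def _write_file(data, path):
    Path(path).write_bytes(data)


def _single_record_session():
    activate()
    _welch_like(np.arange(12.0))
    document = build_document()
    deactivate()
    return document


class TestBuildDocument:

    def test_single_execution_matches_expected_topology(self):
        """One tracked call serializes to exactly one activity, one
        function, one agent and two entities, with parameter and
        attribute name-value pairs as blank nodes."""
        document = _single_record_session()
        graph = document.graph
        assert len(list(graph.subjects(
            RDF.type, ontology.FunctionExecution))) == 1
        assert len(list(graph.subjects(
            RDF.type, ontology.DataObjectEntity))) == 2
        assert len(list(graph.subjects(RDF.type, ontology.Function))) == 1
        assert len(list(graph.subjects(RDF.type,
                                       ontology.ScriptAgent))) == 1
        parameters = list(graph.objects(None, ALPACA.hasParameter))
        names = {str(graph.value(p, ALPACA.pairName)) for p in parameters}
        assert names == {"frequency_resolution"}
        assert list(graph.triples((None, PROV.used, None)))
        assert list(graph.triples((None, PROV.wasGeneratedBy, None)))

    def test_empty_session_serializes_without_activities(self):
        activate()
        document = build_document()
        deactivate()
        assert not list(document.graph.subjects(
            RDF.type, ontology.FunctionExecution))
        # still a valid, parseable Turtle document
        text = document.graph.serialize(format="turtle")
        Graph().parse(data=text, format="turtle")

    def test_repeated_function_deduplicated(self):
        session = activate()
        _welch_like(np.arange(4.0))
        _welch_like(np.arange(5.0))
        document = build_document()
        deactivate()
        graph = document.graph
        assert len(session.history) == 2
        functions = set(graph.objects(None, ALPACA.usedFunction))
        assert len(functions) == 1
        assert len(list(graph.subjects(
            RDF.type, ontology.FunctionExecution))) == 2

    def test_every_activity_associated_with_exactly_one_agent(self):
        activate()
        for _ in range(3):
            _welch_like(np.arange(3.0))
        document = build_document()
        deactivate()
        graph = document.graph
        for execution in graph.subjects(RDF.type,
                                        ontology.FunctionExecution):
            agents = list(graph.objects(execution, PROV.wasAssociatedWith))
            assert len(agents) == 1
            assert (agents[0], RDF.type, ontology.ScriptAgent) in graph

    def test_hash_source_literal_vocabulary(self):
        configure(builtin_hash_packages={"builtins"})
        activate()
        _welch_like(np.arange(3.0))  # ndarray -> content hash

        @Provenance(inputs=["x"])
        def _touch(x):
            return None

        _touch(7)  # int -> builtin hash; None output -> UUID
        document = build_document()
        deactivate()
        sources = {str(v) for v in
                   document.graph.objects(None, ALPACA.hashSource)}
        assert sources == {"joblib_SHA1", "Python_hash", "UUID"}


class TestUrns:

    def test_authority_prefixes_every_urn(self):
        configure(authority="my-lab")
        document = _single_record_session()
        uris = {s for s in document.graph.subjects()
                if isinstance(s, URIRef)}
        assert uris
        for uri in uris:
            assert str(uri).startswith("urn:my-lab:alpaca:")

    def test_urn_grammar_per_class(self):
        document = _single_record_session()
        graph = document.graph
        entity = next(iter(graph.subjects(RDF.type,
                                          ontology.DataObjectEntity)))
        assert str(entity).startswith(
            "urn:my-authority:alpaca:object:Python:numpy.ndarray:")
        function = next(iter(graph.subjects(RDF.type, ontology.Function)))
        module = _welch_like.__wrapped__.__module__
        assert str(function) == ("urn:my-authority:alpaca:function:"
                                 f"Python:{module}._welch_like")
        execution = next(iter(graph.subjects(
            RDF.type, ontology.FunctionExecution)))
        assert ":function_execution:Python:" in str(execution)
        assert "#" in str(execution)

    def test_rebuild_produces_identical_uris(self):
        session = activate()
        _welch_like(np.arange(6.0))
        first = build_document(session)
        second = build_document(session)
        deactivate()
        uris = lambda d: {s for s in d.graph.subjects()
                          if isinstance(s, URIRef)}
        assert uris(first) == uris(second)


class TestRoundTrip:

    def test_save_and_reload_is_isomorphic(self, tmp_path):
        document = _single_record_session()
        path = tmp_path / "run.ttl"
        document.save(path)
        reloaded = ProvenanceDocument.read(path)
        assert isomorphic(document.graph, reloaded.graph)

    @pytest.mark.parametrize("extension,format", [
        (".ttl", None), (".nt", None), (".jsonld", None),
        (".xml", None), (".ttl", "turtle")])
    def test_formats_round_trip(self, tmp_path, extension, format):
        document = _single_record_session()
        path = tmp_path / f"run{extension}"
        document.save(path, format=format)
        assert isomorphic(document.graph,
                          ProvenanceDocument.read(path).graph)

    def test_unknown_format_error_lists_supported(self, tmp_path):
        document = ProvenanceDocument()
        with pytest.raises(ValueError, match="turtle"):
            document.save(tmp_path / "x.ttl", format="not-a-format")

    def test_fixed_ids_make_turtle_byte_stable(self, tmp_path):
        def run(tag):
            with deterministic_ids(5):
                activate()
                _welch_like(np.arange(10.0))
                path = tmp_path / f"{tag}.ttl"
                save_provenance(path)
                deactivate()
            return path.read_bytes()

        assert run("first") == run("second")


class TestMerge:

    def test_merge_with_empty_is_identity(self):
        document = _single_record_session()
        merged = merge([document, ProvenanceDocument()])
        assert isomorphic(merged.graph, document.graph)

    def test_merge_node_count_bound(self):
        first = _single_record_session()
        second = _single_record_session()

        def uris(doc):
            return {term for triple in doc.graph for term in triple
                    if isinstance(term, URIRef)}

        merged = merge([first, second])
        assert len(uris(merged)) <= len(uris(first)) + len(uris(second))
        # identical content across sessions shares entity URNs
        shared = uris(first) & uris(second)
        assert any(":object:" in str(u) for u in shared)

    def test_writer_and_reader_runs_share_file_entity(self, tmp_path):
        payload = b"intermediate result"
        target = tmp_path / "stage.bin"

        activate()
        _write_file(payload, str(target))
        writer_doc = build_document()
        deactivate()

        activate()
        _read_file(str(target))
        reader_doc = build_document()
        deactivate()

        expected = ontology.file_urn(
            "my-authority", "sha256",
            hashlib.sha256(payload).hexdigest())
        merged = merge([writer_doc, reader_doc])
        assert (expected, RDF.type, ontology.FileEntity) in merged.graph
        assert list(merged.graph.objects(expected, PROV.wasGeneratedBy))
        used_by = [s for s, p, o in merged.graph.triples(
            (None, PROV.used, expected))]
        assert used_by


class TestGuessFormat:

    @pytest.mark.parametrize("name,expected", [
        ("a.ttl", "turtle"), ("a.nt", "nt"), ("a.xml", "xml"),
        ("a.jsonld", "json-ld"), ("a.unknown", "turtle")])
    def test_extension_mapping(self, name, expected):
        assert guess_format(name) == expected
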