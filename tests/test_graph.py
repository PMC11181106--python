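"""Visualization graphs: projection, simplification, SNAP aggregation,
export."""

import numpy as np
import networkx as nx
import pytest
from lxml import etree

import provtrace
from provtrace import Provenance, ProvenanceGraph, activate, deactivate
from provtrace.demo.containers import AnalogSignal, Block, Segment
from provtrace.graph import (TIME_INTERVAL_KEY, aggregate, export,
                             snap_partition)


@Provenance(inputs=["signal"])
def _welch_like(signal, frequency_resolution=2.0):
    return signal * 0.5


@Provenance(inputs=["value"])
def _consume(value):
    return None


def _single_execution_graph(tmp_path):
    activate()
    _welch_like(np.arange(10.0))
    provtrace.save_provenance(tmp_path / "one.ttl")
    deactivate()
    return ProvenanceGraph(tmp_path / "one.ttl")


class TestProjection:

    def test_single_execution_projects_to_three_nodes(self, tmp_path):
        view = _single_execution_graph(tmp_path)
        graph = view.graph
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2
        types = sorted(nx.get_node_attributes(graph, "type").values())
        assert types == ["function", "object", "object"]
        function = [n for n, d in graph.nodes(data=True)
                    if d["type"] == "function"][0]
        assert graph.nodes[function]["label"] == "_welch_like"
        assert graph.nodes[function]["frequency_resolution"] == 2.0
        # data flow: input -> activity -> output
        assert graph.in_degree(function) == 1
        assert graph.out_degree(function) == 1

    def test_object_nodes_carry_label_path_and_interval(self, tmp_path):
        view = _single_execution_graph(tmp_path)
        objects = [d for _, d in view.graph.nodes(data=True)
                   if d["type"] == "object"]
        for data in objects:
            assert data["label"] == "ndarray"
            assert data["Python_name"] == "numpy.ndarray"
            assert data[TIME_INTERVAL_KEY] == "<[1, 1]>"
            assert data["shape"] == "(10,)"

    def test_loading_same_file_twice_is_idempotent(self, tmp_path):
        activate()
        _welch_like(np.arange(7.0))
        provtrace.save_provenance(tmp_path / "run.ttl")
        deactivate()
        once = ProvenanceGraph(tmp_path / "run.ttl")
        twice = ProvenanceGraph(tmp_path / "run.ttl", tmp_path / "run.ttl")
        assert nx.utils.graphs_equal(once.graph, twice.graph)

    def test_unparseable_file_raises_naming_the_file(self, tmp_path):
        bad = tmp_path / "broken.ttl"
        bad.write_text("this is not turtle {{{")
        with pytest.raises(ValueError, match="broken.ttl"):
            ProvenanceGraph(bad)


class TestRemoveNone:

    def test_removes_exactly_the_none_entities(self, tmp_path):
        activate()
        _consume(np.arange(3.0))
        _consume(np.arange(4.0))
        provtrace.save_provenance(tmp_path / "run.ttl")
        deactivate()
        view = ProvenanceGraph(tmp_path / "run.ttl")
        none_nodes = [n for n, d in view.graph.nodes(data=True)
                      if d.get("Python_name") == "builtins.NoneType"]
        before = view.graph.number_of_nodes()
        view.remove_none()
        assert view.graph.number_of_nodes() == before - len(none_nodes)
        assert len([n for n, d in view.graph.nodes(data=True)
                    if d["type"] == "function"]) == 2

    def test_noop_on_graph_without_none(self, tmp_path):
        view = _single_execution_graph(tmp_path)
        before = view.graph.number_of_nodes()
        view.remove_none()
        assert view.graph.number_of_nodes() == before


class TestCondenseMemberships:

    def _membership_graph(self, tmp_path, reuse_intermediate=False):
        activate()
        block = Block()
        segment = Segment(t_start=0.0, t_stop=1.0)
        segment.analogsignals.append(
            AnalogSignal(np.zeros((6, 2)), sampling_rate=6.0))
        block.segments.append(segment)
        _consume(block.segments[0])
        if reuse_intermediate:
            _consume(block.segments)
        provtrace.save_provenance(tmp_path / "m.ttl")
        deactivate()
        return ProvenanceGraph(tmp_path / "m.ttl")

    def test_chain_collapses_to_single_labeled_edge(self, tmp_path):
        view = self._membership_graph(tmp_path)
        view.condense_memberships()
        labels = [d.get("label") for _, _, d in view.graph.edges(data=True)
                  if d.get("membership")]
        assert ".segments[0]" in labels
        # the intermediate pure-container list node is gone
        assert not any(d.get("label") == "list"
                       for _, d in view.graph.nodes(data=True))

    def test_intermediate_with_other_edges_is_retained(self, tmp_path):
        view = self._membership_graph(tmp_path, reuse_intermediate=True)
        view.condense_memberships()
        assert any(d.get("label") == "list"
                   for _, d in view.graph.nodes(data=True))

    def test_condensation_preserves_reachability(self, tmp_path):
        view = self._membership_graph(tmp_path)
        before = view.graph.copy()
        view.condense_memberships()
        kept = set(view.graph.nodes)
        for source in kept:
            for target in kept:
                assert nx.has_path(view.graph, source, target) == \
                    nx.has_path(before, source, target)

    def test_graph_without_memberships_unchanged(self, tmp_path):
        view = _single_execution_graph(tmp_path)
        before = view.graph.copy()
        view.condense_memberships()
        assert nx.utils.graphs_equal(before, view.graph)


def _toy_graph(n_paths=3, distinct_attr=False):
    """n identical two-node paths feeding one shared sink."""
    graph = nx.DiGraph()
    graph.add_node("sink", type="function", label="plot", Python_name="p")
    for i in range(n_paths):
        attrs = {"type": "object", "label": "Quantity",
                 "Python_name": "demo.Quantity"}
        if distinct_attr:
            attrs["trial_type"] = f"T{i}"
        graph.add_node(f"obj{i}", **attrs)
        graph.add_node(f"fn{i}", type="function", label="compute",
                       Python_name="c", cutoff=250.0)
        graph.add_edge(f"fn{i}", f"obj{i}")
        graph.add_edge(f"obj{i}", "sink")
    return graph


class TestAggregation:

    def test_identical_isolated_nodes_collapse_to_one_supernode(self):
        graph = nx.DiGraph()
        for i in range(6):
            graph.add_node(f"n{i}", type="object", label="ndarray",
                           Python_name="numpy.ndarray")
        summary = aggregate(graph)
        assert summary.number_of_nodes() == 1
        node = next(iter(summary.nodes))
        assert summary.nodes[node]["member_count"] == 6
        assert sorted(summary.nodes[node]["members"]) == \
            [f"n{i}" for i in range(6)]

    def test_member_count_conservation(self):
        graph = _toy_graph(4, distinct_attr=True)
        for attrs in ([], ["trial_type"]):
            summary = aggregate(graph, attrs)
            assert sum(nx.get_node_attributes(
                summary, "member_count").values()) == \
                graph.number_of_nodes()

    def test_grouping_attribute_splits_paths(self):
        graph = _toy_graph(4, distinct_attr=True)
        merged = aggregate(graph)
        split = aggregate(graph, ["trial_type"])
        merged_objects = [n for n, d in merged.nodes(data=True)
                          if d["label"] == "Quantity"]
        split_objects = [n for n, d in split.nodes(data=True)
                         if d["label"] == "Quantity"]
        assert len(merged_objects) == 1
        assert len(split_objects) == 4

    def test_parameter_values_split_function_groups(self):
        graph = _toy_graph(2)
        graph.nodes["fn0"]["cutoff"] = 250.0
        graph.nodes["fn1"]["cutoff"] = 100.0
        plain = aggregate(graph, use_parameters=False)
        with_params = aggregate(graph, use_parameters=True)
        count = lambda g: len([n for n, d in g.nodes(data=True)
                               if d.get("label") == "compute"])
        assert count(plain) == 1
        assert count(with_params) == 2

    def test_partition_is_stable_and_maximal(self):
        """The computed partition satisfies the pairwise-edge condition,
        and no two groups with equal keys can be merged without
        violating it (coarsest stable refinement)."""
        graph = _toy_graph(3, distinct_attr=True)
        graph.add_edge("obj0", "fn1")  # break symmetry
        partition = snap_partition(graph, ["trial_type"])

        def neighbor_groups(node):
            return (frozenset(partition[s] for s in graph.successors(node)),
                    frozenset(partition[p]
                              for p in graph.predecessors(node)))

        groups = {}
        for node, gid in partition.items():
            groups.setdefault(gid, []).append(node)
        for nodes in groups.values():
            signatures = {neighbor_groups(n) for n in nodes}
            assert len(signatures) == 1  # stability
        # maximality: merging any two groups with identical keys breaks
        # edge compatibility
        from provtrace.graph import _group_key
        for a in groups:
            for b in groups:
                if a >= b:
                    continue
                key = lambda gid: _group_key(
                    graph.nodes[groups[gid][0]], ["trial_type"], False)
                if key(a) != key(b):
                    continue
                assert neighbor_groups(groups[a][0]) != \
                    neighbor_groups(groups[b][0])

    def test_matches_networkx_snap_on_undirected_toy(self):
        """Independent oracle: NetworkX's SNAP summarization groups the
        same toy graph into the same member partition."""
        graph = _toy_graph(3, distinct_attr=True)
        partition = snap_partition(graph, ["trial_type"])
        ours = {frozenset(n for n in partition if partition[n] == gid)
                for gid in set(partition.values())}

        undirected = nx.Graph()
        for node, data in graph.nodes(data=True):
            undirected.add_node(node, label=data["label"],
                                trial_type=data.get("trial_type", "-"))
        for u, v in graph.edges:
            undirected.add_edge(u, v, types="flow")
        summary = nx.snap_aggregation(
            undirected, node_attributes=("label", "trial_type"))
        theirs = {frozenset(d["group"])
                  for _, d in summary.nodes(data=True)}
        assert ours == theirs


class TestExport:

    def test_gexf_round_trip_preserves_topology_and_attributes(
            self, tmp_path):
        view = _single_execution_graph(tmp_path)
        out = tmp_path / "graph.gexf"
        view.save_gexf(out)
        back = nx.read_gexf(out)
        assert set(back.nodes) == set(view.graph.nodes)
        assert set(back.edges) == set(view.graph.edges)
        for node in view.graph.nodes:
            assert back.nodes[node]["type"] == \
                view.graph.nodes[node]["type"]

    def test_graphml_round_trip(self, tmp_path):
        view = _single_execution_graph(tmp_path)
        out = tmp_path / "graph.graphml"
        view.save_graphml(out)
        back = nx.read_graphml(out)
        assert set(back.nodes) == set(view.graph.nodes)
        assert set(back.edges) == set(view.graph.edges)

    def test_gexf_is_wellformed_xml_with_gexf_root(self, tmp_path):
        view = _single_execution_graph(tmp_path)
        out = tmp_path / "graph.gexf"
        export(view, out, format="gexf")
        root = etree.parse(str(out)).getroot()
        assert root.tag.endswith("gexf")
        assert root.get("version")

    def test_empty_graph_exports_validly(self, tmp_path):
        graph = nx.DiGraph()
        out = tmp_path / "empty.gexf"
        export(graph, out, format="gexf")
        root = etree.parse(str(out)).getroot()
        assert root.tag.endswith("gexf")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="gexf"):
            export(nx.DiGraph(), tmp_path / "x.dot", format="dot")

    def test_aggregated_graph_exports_members_as_string(self, tmp_path):
        graph = _toy_graph(2)
        summary = aggregate(graph)
        out = tmp_path / "agg.gexf"
        export(summary, out, format="gexf")
        back = nx.read_gexf(out)
        members = nx.get_node_attributes(back, "members")
        assert members and all(isinstance(v, str)
                               for v in members.values())
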