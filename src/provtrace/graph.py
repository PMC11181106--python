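"""Projection of serialized provenance into visualization graphs.

The RDF provenance records are projected into a directed NetworkX graph
whose nodes are data objects, files, and function executions, and whose
edges follow the data flow (used entity -> activity -> generated entity).
The graph can be simplified (dropping ``None`` returns, condensing chains
of container accesses into a single labeled edge), summarized with a
SNAP-style aggregation (grouping nodes on attributes with pairwise-edge
refinement), and exported to GEXF or GraphML for tools such as Gephi.
"""

from __future__ import annotations

from pathlib import Path
from typing import (Any, Dict, Iterable, List, Optional, Sequence, Tuple,
                    Union)

import networkx as nx
from rdflib import RDF, Graph, URIRef

from . import ontology
from .serialization import ProvenanceDocument

NONE_TYPE_PATH = "builtins.NoneType"

#: Node-attribute keys kept bit-compatible with existing graph exports.
PYTHON_NAME_KEY = "Python_name"
TIME_INTERVAL_KEY = "Time Interval"

#: Node-attribute keys owned by the projection itself.
_RESERVED_KEYS = {"type", "label", PYTHON_NAME_KEY, TIME_INTERVAL_KEY,
                  "execution_order", "members", "member_count",
                  "hash_source", "File_path", "data_hash"}

_MEMBERSHIP_LABELS = (
    (ontology.ALPACA.fromAttribute, ".{}"),
    (ontology.ALPACA.containerIndex, "[{}]"),
    (ontology.ALPACA.containerSlice, "[{}]"),
)


def _pairs(rdf: Graph, subject: URIRef, predicate: URIRef
           ) -> Dict[str, str]:
    values = {}
    for pair in rdf.objects(subject, predicate):
        name = rdf.value(pair, ontology.ALPACA.pairName)
        value = rdf.value(pair, ontology.ALPACA.pairValue)
        if name is not None:
            values[str(name)] = value.toPython() if value is not None \
                else None
    return values


def _selected(values: Dict[str, Any],
              selection: Optional[Sequence[str]]) -> Dict[str, Any]:
    if selection is None:
        return values
    return {k: v for k, v in values.items() if k in selection}


class ProvenanceGraph:
    """Property-graph view of one or more serialized provenance files.

    Parameters
    ----------
    rdf_paths
        RDF files to load; their triple sets are merged before projection,
        so graphs of a split pipeline connect through shared URNs.
    attributes, annotations
        Names of object attributes / annotations to copy into node
        attributes; ``None`` selects all recorded ones.
    prefix_parameters
        Prefix function-parameter attributes with the function name
        (``butter:lowpass_frequency``) so they are identifiable after
        aggregation.
    """

    def __init__(self, *rdf_paths: Union[str, Path],
                 attributes: Optional[Sequence[str]] = None,
                 annotations: Optional[Sequence[str]] = None,
                 prefix_parameters: bool = False) -> None:
        document = ProvenanceDocument.read(list(rdf_paths)) if rdf_paths \
            else ProvenanceDocument()
        self.graph = self._project(document.graph, attributes, annotations,
                                   prefix_parameters)
        self._assign_intervals()

    # -- projection ---------------------------------------------------

    @staticmethod
    def _project(rdf: Graph, attributes: Optional[Sequence[str]],
                 annotations: Optional[Sequence[str]],
                 prefix_parameters: bool) -> nx.DiGraph:
        graph = nx.DiGraph()

        for execution in rdf.subjects(RDF.type, ontology.FunctionExecution):
            function = rdf.value(execution, ontology.ALPACA.usedFunction)
            name = rdf.value(function, ontology.ALPACA.functionName)
            module = rdf.value(function, ontology.ALPACA.implementedIn)
            order = rdf.value(execution, ontology.ALPACA.executionOrder)
            label = str(name) if name is not None else "<function>"
            node_attrs: Dict[str, Any] = {
                "type": "function",
                "label": label,
                PYTHON_NAME_KEY: f"{module}.{label}" if module else label,
                "execution_order": int(order) if order is not None else 0,
            }
            parameters = _pairs(rdf, execution, ontology.ALPACA.hasParameter)
            for key, value in parameters.items():
                # parameters may not clobber the structural node attributes
                attr = f"{label}:{key}" if prefix_parameters or \
                    key in _RESERVED_KEYS else key
                node_attrs[attr] = value
            graph.add_node(str(execution), **node_attrs)

        for entity in rdf.subjects(RDF.type, ontology.DataObjectEntity):
            parts = str(entity).split(":")
            class_path = parts[5] if len(parts) > 6 else ""
            node_attrs = {
                "type": "object",
                "label": class_path.rpartition(".")[2] or "<object>",
                PYTHON_NAME_KEY: class_path,
                "hash_source": str(rdf.value(entity,
                                             ontology.ALPACA.hashSource)
                                   or ""),
            }
            metadata = dict(_selected(
                _pairs(rdf, entity, ontology.ALPACA.hasAttribute),
                attributes))
            metadata.update(_selected(
                _pairs(rdf, entity, ontology.ALPACA.hasAnnotation),
                annotations))
            for key, value in metadata.items():
                node_attrs[f"obj:{key}" if key in _RESERVED_KEYS
                           else key] = value
            graph.add_node(str(entity), **node_attrs)

        for entity in rdf.subjects(RDF.type, ontology.FileEntity):
            parts = str(entity).split(":")
            graph.add_node(str(entity), **{
                "type": "file",
                "label": "File",
                PYTHON_NAME_KEY: "",
                "File_path": str(rdf.value(entity,
                                           ontology.ALPACA.filePath) or ""),
                "data_hash": parts[5] if len(parts) > 5 else "",
            })

        # data-flow edges: used entity -> activity -> generated entity
        for execution, _, entity in rdf.triples(
                (None, ontology.PROV.used, None)):
            if str(entity) in graph and str(execution) in graph:
                graph.add_edge(str(entity), str(execution), membership=False)
        for entity, _, execution in rdf.triples(
                (None, ontology.PROV.wasGeneratedBy, None)):
            if str(entity) in graph and str(execution) in graph:
                graph.add_edge(str(execution), str(entity), membership=False)

        # membership edges: container -> element, labeled by the accessor
        for container, _, element in rdf.triples(
                (None, ontology.PROV.hasMember, None)):
            if str(container) not in graph or str(element) not in graph:
                continue
            label = ""
            for predicate, template in _MEMBERSHIP_LABELS:
                value = rdf.value(element, predicate)
                if value is not None:
                    label = template.format(value)
                    break
            graph.add_edge(str(container), str(element), membership=True,
                           label=label)
        return graph

    def _assign_intervals(self) -> None:
        """Time-interval strings built from execution order.

        Function nodes span their own order; entities span from first
        generation to last use; container nodes reached only through
        memberships inherit the hull of their neighbors' intervals.
        """
        graph = self.graph
        spans: Dict[str, Tuple[int, int]] = {}
        for node, data in graph.nodes(data=True):
            if data["type"] == "function":
                order = data.get("execution_order", 0)
                spans[node] = (order, order)
        for node, data in graph.nodes(data=True):
            if data["type"] == "function":
                continue
            orders = [spans[nbr][0] for nbr in
                      list(graph.predecessors(node)) +
                      list(graph.successors(node))
                      if nbr in spans
                      and graph.nodes[nbr]["type"] == "function"]
            if orders:
                spans[node] = (min(orders), max(orders))
        # propagate along membership edges to pure-container nodes
        for _ in range(len(graph)):
            changed = False
            for node in graph.nodes:
                if node in spans:
                    continue
                neighbor_spans = [spans[nbr] for nbr in
                                  list(graph.predecessors(node)) +
                                  list(graph.successors(node))
                                  if nbr in spans]
                if neighbor_spans:
                    spans[node] = (min(s[0] for s in neighbor_spans),
                                   max(s[1] for s in neighbor_spans))
                    changed = True
            if not changed:
                break
        for node, (start, end) in spans.items():
            graph.nodes[node][TIME_INTERVAL_KEY] = f"<[{start}, {end}]>"

    # -- simplification -----------------------------------------------

    def remove_none(self) -> "ProvenanceGraph":
        """Drop entities describing the builtin ``None`` return value."""
        victims = [node for node, data in self.graph.nodes(data=True)
                   if data.get(PYTHON_NAME_KEY) == NONE_TYPE_PATH]
        self.graph.remove_nodes_from(victims)
        return self

    def condense_memberships(self) -> "ProvenanceGraph":
        """Collapse chains of container accesses into single labeled edges.

        A maximal chain ``container -> ... -> element`` of membership
        edges is replaced by one edge whose label concatenates the
        accessors (e.g. ``.segments[0]``); intermediate pure-container
        nodes with no other incident provenance edges are removed.
        """
        graph = self.graph
        changed = True
        while changed:
            changed = False
            for node in list(graph.nodes):
                in_edges = list(graph.in_edges(node, data=True))
                out_edges = list(graph.out_edges(node, data=True))
                if len(in_edges) != 1 or len(out_edges) != 1:
                    continue
                (source, _, in_data), (_, target, out_data) = \
                    in_edges[0], out_edges[0]
                if not (in_data.get("membership") and
                        out_data.get("membership")):
                    continue
                if source == node or target == node:
                    continue
                label = in_data.get("label", "") + out_data.get("label", "")
                graph.remove_node(node)
                graph.add_edge(source, target, membership=True, label=label)
                changed = True
        return self

    # -- aggregation --------------------------------------------------

    def aggregate(self, group_attributes: Sequence[str] = (),
                  use_parameters: bool = False) -> nx.DiGraph:
        return aggregate(self.graph, group_attributes,
                         use_parameters=use_parameters)

    # -- export -------------------------------------------------------

    def save_gexf(self, path: Union[str, Path]) -> None:
        nx.write_gexf(_exportable(self.graph), str(path))

    def save_graphml(self, path: Union[str, Path]) -> None:
        nx.write_graphml(_exportable(self.graph), str(path))


def _exportable(graph: nx.DiGraph) -> nx.DiGraph:
    """Copy with attribute values coerced to types the XML formats take."""
    copy = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        copy.add_node(node, **{k: v if isinstance(v, (bool, int, float, str))
                               else "; ".join(map(str, v))
                               if isinstance(v, (list, tuple, set))
                               else str(v)
                               for k, v in data.items() if v is not None})
    for source, target, data in graph.edges(data=True):
        copy.add_edge(source, target,
                      **{k: v if isinstance(v, (bool, int, float, str))
                         else str(v)
                         for k, v in data.items() if v is not None})
    return copy


# -- SNAP-style aggregation -------------------------------------------

_MISSING_VALUE = "<missing>"


def _group_key(data: Dict[str, Any], group_attributes: Sequence[str],
               use_parameters: bool) -> Tuple:
    key: List[Any] = [data.get("type", ""), data.get("label", ""),
                      data.get(PYTHON_NAME_KEY, "")]
    for attribute in group_attributes:
        key.append(str(data.get(attribute, _MISSING_VALUE)))
    if use_parameters and data.get("type") == "function":
        reserved = {"type", "label", PYTHON_NAME_KEY, "execution_order",
                    TIME_INTERVAL_KEY}
        parameters = sorted((k, str(v)) for k, v in data.items()
                            if k not in reserved)
        key.append(tuple(parameters))
    return tuple(key)


def snap_partition(graph: nx.DiGraph, group_attributes: Sequence[str] = (),
                   use_parameters: bool = False) -> Dict[str, int]:
    """Coarsest attribute-compatible, edge-compatible node partition.

    Nodes start grouped by (type, label, dotted path, selected attribute
    values, and function parameters when requested; missing values form a
    distinct key). Groups are then iteratively split until every node in a
    group has edges to the same set of groups, in both directions
    (the pairwise-edge condition of SNAP summarization).
    """
    keys = {node: _group_key(data, group_attributes, use_parameters)
            for node, data in graph.nodes(data=True)}
    key_ids: Dict[Tuple, int] = {}
    group = {node: key_ids.setdefault(key, len(key_ids))
             for node, key in keys.items()}

    while True:
        signatures = {}
        for node in graph.nodes:
            signatures[node] = (
                group[node],
                frozenset(group[nbr] for nbr in graph.successors(node)),
                frozenset(group[nbr] for nbr in graph.predecessors(node)),
            )
        signature_ids: Dict[Tuple, int] = {}
        refined = {node: signature_ids.setdefault(sig, len(signature_ids))
                   for node, sig in signatures.items()}
        if len(signature_ids) == len(set(group.values())):
            return refined
        group = refined


def aggregate(graph: nx.DiGraph, group_attributes: Sequence[str] = (),
              use_parameters: bool = False) -> nx.DiGraph:
    """SNAP-style summary graph.

    Each group of the stable partition becomes one supernode carrying the
    shared attribute values, the sorted list of member URNs (``members``)
    and their count (``member_count``); superedges connect groups whose
    members are connected.
    """
    partition = snap_partition(graph, group_attributes, use_parameters)
    members: Dict[int, List[str]] = {}
    for node, gid in partition.items():
        members.setdefault(gid, []).append(node)

    summary = nx.DiGraph()
    node_of_group: Dict[int, str] = {}
    for gid, nodes in members.items():
        data = graph.nodes[sorted(nodes)[0]]
        key = _group_key(data, group_attributes, use_parameters)
        node_of_group[gid] = ":".join(str(part) for part in key[:3]) \
            or "group"
    # disambiguate supernodes sharing the same key prefix
    seen: Dict[str, int] = {}
    for gid in sorted(node_of_group, key=lambda g: sorted(members[g])[0]):
        base = node_of_group[gid]
        count = seen.get(base, 0)
        seen[base] = count + 1
        node_of_group[gid] = base if count == 0 else f"{base}#{count}"

    for gid, nodes in members.items():
        nodes = sorted(nodes)
        data = dict(graph.nodes[nodes[0]])
        shared = {k: v for k, v in data.items()
                  if all(graph.nodes[n].get(k) == v for n in nodes[1:])}
        shared.pop(TIME_INTERVAL_KEY, None)
        intervals = [graph.nodes[n].get(TIME_INTERVAL_KEY)
                     for n in nodes]
        bounds = [_parse_interval(i) for i in intervals if i]
        if bounds:  # hull of the member intervals
            shared[TIME_INTERVAL_KEY] = (
                f"<[{min(b[0] for b in bounds)}, "
                f"{max(b[1] for b in bounds)}]>")
        shared["members"] = nodes
        shared["member_count"] = len(nodes)
        summary.add_node(node_of_group[gid], **shared)

    for source, target, data in graph.edges(data=True):
        s, t = node_of_group[partition[source]], node_of_group[
            partition[target]]
        if summary.has_edge(s, t):
            existing = summary.edges[s, t]
            if data.get("label") and data["label"] not in existing.get(
                    "label", ""):
                existing["label"] = existing.get("label", "") or \
                    data["label"]
        else:
            summary.add_edge(s, t, **{k: v for k, v in data.items()
                                      if v is not None})
    return summary


def _parse_interval(text: str) -> Tuple[int, int]:
    inner = text.strip("<>[] ")
    start, _, end = inner.partition(",")
    return int(float(start)), int(float(end))


# -- spec-surface convenience wrappers --------------------------------

def load_graph(rdf_paths: Sequence[Union[str, Path]],
               **options: Any) -> ProvenanceGraph:
    return ProvenanceGraph(*rdf_paths, **options)


def remove_none_nodes(graph: ProvenanceGraph) -> ProvenanceGraph:
    return graph.remove_none()


def condense_memberships(graph: ProvenanceGraph) -> ProvenanceGraph:
    return graph.condense_memberships()


def export(graph: Union[ProvenanceGraph, nx.DiGraph],
           path: Union[str, Path], format: str = "gexf") -> None:
    """Write a visualization graph as GEXF (default) or GraphML."""
    nxgraph = graph.graph if isinstance(graph, ProvenanceGraph) else graph
    if format.lower() == "gexf":
        nx.write_gexf(_exportable(nxgraph), str(path))
    elif format.lower() == "graphml":
        nx.write_graphml(_exportable(nxgraph), str(path))
    else:
        raise ValueError(f"unknown graph format {format!r}; "
                         "supported: gexf, graphml")
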