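"""Read back recorded facts from serialized provenance files.

These helpers answer questions about an analysis run using only its RDF
sidecar — no access to the run or its data — e.g. which array shapes
passed through a given stage, or which parameters a stage was called
with. They operate on the visualization projection, so they work on
merged multi-run files as well.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from ..graph import ProvenanceGraph


def _first_dim(shape_text: Optional[str]) -> Optional[int]:
    if not shape_text:
        return None
    try:
        shape = ast.literal_eval(shape_text)
    except (ValueError, SyntaxError):
        return None
    if isinstance(shape, tuple) and shape:
        return int(shape[0])
    return None


def stage_shape_transitions(ttl_paths: Union[str, Path, List],
                            function_label: str
                            ) -> List[Tuple[int, int]]:
    """Recorded (input, output) first-dimension lengths across a stage.

    For every execution of the function labeled *function_label*, reads
    the ``shape`` attribute recorded for its array-like input and output
    entities and returns the first-dimension pairs.
    """
    if isinstance(ttl_paths, (str, Path)):
        ttl_paths = [ttl_paths]
    view = ProvenanceGraph(*ttl_paths)
    graph = view.graph
    transitions = []
    for node, data in graph.nodes(data=True):
        if data.get("type") != "function" or \
                data.get("label") != function_label:
            continue
        in_dims = [_first_dim(graph.nodes[p].get("shape"))
                   for p in graph.predecessors(node)]
        out_dims = [_first_dim(graph.nodes[s].get("shape"))
                    for s in graph.successors(node)]
        for in_dim in in_dims:
            for out_dim in out_dims:
                if in_dim is not None and out_dim is not None:
                    transitions.append((in_dim, out_dim))
    return transitions


def frequency_bin_count(ttl_paths: Union[str, Path, List]) -> Optional[int]:
    """First-dimension length recorded for the frequency-array entity
    generated by the Welch-PSD stage (identified by its ``Hz`` units)."""
    if isinstance(ttl_paths, (str, Path)):
        ttl_paths = [ttl_paths]
    view = ProvenanceGraph(*ttl_paths)
    graph = view.graph
    for node, data in graph.nodes(data=True):
        if data.get("type") != "function" or data.get("label") != \
                "welch_psd":
            continue
        for successor in graph.successors(node):
            attrs = graph.nodes[successor]
            if attrs.get("units") == "Hz":
                return _first_dim(attrs.get("shape"))
    return None


def recorded_parameters(ttl_paths: Union[str, Path, List],
                        function_label: str) -> List[Dict[str, object]]:
    """Parameter dictionaries of every recorded execution of a stage."""
    if isinstance(ttl_paths, (str, Path)):
        ttl_paths = [ttl_paths]
    view = ProvenanceGraph(*ttl_paths)
    structural = {"type", "label", "Python_name", "execution_order",
                  "Time Interval"}
    parameters = []
    for _, data in view.graph.nodes(data=True):
        if data.get("type") == "function" and \
                data.get("label") == function_label:
            parameters.append({k: v for k, v in data.items()
                               if k not in structural})
    return parameters
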