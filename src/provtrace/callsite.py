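"""Static analysis of the call site of a tracked function.

The statement containing a tracked call is inspected as an abstract syntax
tree. Every argument expression that reaches the call through attribute
access, indexing or slicing of a container (possibly chained, e.g.
``block.segments[0]``) yields one :class:`MembershipRecord` per hop, with
the intermediate objects resolved from the live frame and described by
content. These records become ``hasMember`` relations in the serialized
graph, linking containers to the elements actually used.

Dynamically generated code that cannot be matched to the parsed source
produces no memberships; the call itself is still recorded.
"""

from __future__ import annotations

import ast
import inspect
import warnings
from types import FrameType
from typing import Any, List, Optional, Tuple

from .descriptors import describe_object
from .records import ATTRIBUTE, INDEX, SLICE, MembershipRecord
from .settings import CaptureSettings

_MISSING = object()


def _resolve_name(frame: FrameType, name: str) -> Any:
    if name in frame.f_locals:
        return frame.f_locals[name]
    if name in frame.f_globals:
        return frame.f_globals[name]
    return frame.f_builtins.get(name, _MISSING)


def _resolve_expression(node: ast.expr, frame: FrameType) -> Any:
    """Resolve a simple expression (names, attributes, constant subscripts)
    against the live frame, without executing arbitrary code."""
    if isinstance(node, ast.Name):
        return _resolve_name(frame, node.id)
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Attribute):
        base = _resolve_expression(node.value, frame)
        if base is _MISSING:
            return _MISSING
        return getattr(base, node.attr, _MISSING)
    if isinstance(node, ast.Subscript):
        base = _resolve_expression(node.value, frame)
        key = _resolve_expression(node.slice, frame)
        if base is _MISSING or key is _MISSING:
            return _MISSING
        try:
            return base[key]
        except Exception:
            return _MISSING
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        operand = _resolve_expression(node.operand, frame)
        if isinstance(operand, (int, float)):
            return -operand
        return _MISSING
    if isinstance(node, ast.Tuple):
        items = [_resolve_expression(item, frame) for item in node.elts]
        if any(item is _MISSING for item in items):
            return _MISSING
        return tuple(items)
    return _MISSING


def find_tracked_calls(statement: ast.stmt, frame: FrameType,
                       wrapper: Any) -> List[ast.Call]:
    """Call nodes in *statement* whose function resolves to *wrapper*."""
    calls = []
    for node in ast.walk(statement):
        if isinstance(node, ast.Call):
            func = _resolve_expression(node.func, frame)
            if func is wrapper:
                calls.append(node)
    return calls


def _chain_of(node: ast.expr) -> Optional[Tuple[ast.expr, List[ast.expr]]]:
    """Decompose ``base.attr[i]...`` into (base name node, access hops)."""
    hops: List[ast.expr] = []
    while isinstance(node, (ast.Attribute, ast.Subscript)):
        hops.append(node)
        node = node.value
    if not hops or not isinstance(node, ast.Name):
        return None
    hops.reverse()  # innermost (closest to the base) first
    return node, hops


def _slice_text(node: ast.Slice, source: str) -> str:
    segment = ast.get_source_segment(source, node)
    if segment:
        return segment
    parts = [ast.unparse(part) if part is not None else ""
             for part in (node.lower, node.upper)]
    text = ":".join(parts)
    if node.step is not None:
        text += f":{ast.unparse(node.step)}"
    return text


def analyze_call_site(call: ast.Call, frame: FrameType, source: str,
                      settings: CaptureSettings,
                      signature: Optional[inspect.Signature] = None,
                      input_names: Optional[set] = None
                      ) -> List[MembershipRecord]:
    """Membership records for every container access feeding *call*.

    When *signature* and *input_names* are given, only the argument
    expressions bound to data-input roles are analyzed — parameter
    expressions (e.g. ``config.cutoff``) do not describe data flow.
    """
    arguments: List[ast.expr] = []
    if signature is None or input_names is None:
        arguments = list(call.args) + [kw.value for kw in call.keywords
                                       if kw.value is not None]
    else:
        positional = [p.name for p in signature.parameters.values()
                      if p.kind in (p.POSITIONAL_ONLY,
                                    p.POSITIONAL_OR_KEYWORD)]
        for position, expression in enumerate(call.args):
            if position < len(positional) and \
                    positional[position] in input_names:
                arguments.append(expression)
        arguments += [kw.value for kw in call.keywords
                      if kw.arg in input_names and kw.value is not None]

    records: List[MembershipRecord] = []
    for argument in arguments:
        chain = _chain_of(argument)
        if chain is None:
            continue
        base_node, hops = chain
        container = _resolve_name(frame, base_node.id)
        if container is _MISSING:
            continue
        try:
            records.extend(_walk_chain(container, hops, frame, source,
                                       settings))
        except Exception as exc:  # never abort the user's computation
            warnings.warn(f"call-site analysis failed for "
                          f"{ast.unparse(argument)!r}: {exc}", stacklevel=2)
    return records


def _walk_chain(container: Any, hops: List[ast.expr], frame: FrameType,
                source: str, settings: CaptureSettings
                ) -> List[MembershipRecord]:
    records: List[MembershipRecord] = []
    for hop in hops:
        if isinstance(hop, ast.Attribute):
            element = getattr(container, hop.attr, _MISSING)
            relation, accessor = ATTRIBUTE, hop.attr
        elif isinstance(hop, ast.Subscript) and isinstance(hop.slice,
                                                           ast.Slice):
            bounds = [_resolve_expression(part, frame)
                      if part is not None else None
                      for part in (hop.slice.lower, hop.slice.upper,
                                   hop.slice.step)]
            if any(b is _MISSING for b in bounds):
                break
            try:
                element = container[slice(*bounds)]
            except Exception:
                break
            relation, accessor = SLICE, _slice_text(hop.slice, source)
        else:  # plain subscript: index or key
            key = _resolve_expression(hop.slice, frame)
            if key is _MISSING:
                break
            try:
                element = container[key]
            except Exception:
                break
            relation, accessor = INDEX, str(key)
        if element is _MISSING:
            break
        records.append(MembershipRecord(
            container=describe_object(container, settings),
            element=describe_object(element, settings),
            relation=relation,
            accessor=accessor,
        ))
        container = element
    return records
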