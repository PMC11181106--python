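"""Record types for one tracked function execution."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List

from .descriptors import DataObjectDescriptor, Descriptor, FunctionInfo

#: Membership relation kinds.
ATTRIBUTE = "attribute"
INDEX = "index"
SLICE = "slice"


@dataclass(frozen=True)
class MembershipRecord:
    """One container-access hop: ``container -> element``.

    ``relation`` states how the element was reached (attribute access,
    indexing, or slicing) and ``accessor`` holds the attribute name, index
    expression, or slice expression used.
    """

    container: DataObjectDescriptor
    element: DataObjectDescriptor
    relation: str
    accessor: str

    def __post_init__(self) -> None:
        if self.relation not in (ATTRIBUTE, INDEX, SLICE):
            raise ValueError(f"unknown membership relation {self.relation!r}")
        if not self.accessor:
            raise ValueError("membership accessor must be non-empty")


@dataclass
class FunctionExecutionRecord:
    """One tracked call: function identity, arguments by role, and context.

    Every argument of the call appears in exactly one of ``inputs`` (data
    objects / input files), ``parameters`` (literal snapshots) or — for
    file-output arguments — contributes to ``outputs``. ``order`` is the
    value of the session's global execution counter for this call.
    """

    execution_id: str
    function: FunctionInfo
    inputs: Dict[str, Descriptor] = field(default_factory=dict)
    parameters: Dict[str, Any] = field(default_factory=dict)
    outputs: List[Descriptor] = field(default_factory=list)
    memberships: List[MembershipRecord] = field(default_factory=list)
    order: int = 0
    time_start: str = ""
    time_end: str = ""
    code_statement: str = ""
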