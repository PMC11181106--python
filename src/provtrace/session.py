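"""Capture sessions.

A session identifies one execution of a tracked script: a fresh UUID, the
script path and the SHA-256 hash of its source file, a global execution
counter, and the ordered history of function-execution records. The source
of the activated scope is parsed once so that the statement containing each
tracked call can be located by line number during call analysis.
"""

from __future__ import annotations

import ast
import hashlib
import inspect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

from . import _ids, descriptors
from .records import FunctionExecutionRecord
from .settings import CaptureSettings, get_settings


class ActivationError(RuntimeError):
    """Raised when a session cannot be started or is started twice."""


@dataclass
class CaptureSession:
    """Per-run capture state."""

    session_id: str
    script_path: str
    script_file_hash: str
    settings: CaptureSettings
    source_lines: List[str] = field(default_factory=list, repr=False)
    source_tree: Optional[ast.Module] = field(default=None, repr=False)
    execution_counter: int = 0
    history: List[FunctionExecutionRecord] = field(default_factory=list)
    active: bool = True

    @property
    def script_name(self) -> str:
        return Path(self.script_path).name

    @property
    def authority(self) -> str:
        return self.settings.authority

    def next_order(self) -> int:
        self.execution_counter += 1
        return self.execution_counter

    def statement_at(self, lineno: int) -> Optional[ast.stmt]:
        """Smallest source statement covering *lineno* (1-based)."""
        if self.source_tree is None:
            return None
        best: Optional[ast.stmt] = None
        for node in ast.walk(self.source_tree):
            if not isinstance(node, ast.stmt):
                continue
            end = getattr(node, "end_lineno", node.lineno)
            if node.lineno <= lineno <= end:
                if best is None or (node.lineno, -end) > (best.lineno,
                                                          -best.end_lineno):
                    best = node
        return best

    def statement_source(self, statement: ast.stmt) -> str:
        segment = ast.get_source_segment("".join(self.source_lines),
                                         statement)
        if segment is not None:
            return segment
        lines = self.source_lines[statement.lineno - 1:
                                  getattr(statement, "end_lineno",
                                          statement.lineno)]
        return "".join(lines).strip()


_current_session: Optional[CaptureSession] = None


def current_session() -> Optional[CaptureSession]:
    return _current_session


def activate(settings: CaptureSettings | None = None,
             _frame_offset: int = 1) -> CaptureSession:
    """Start provenance capture for the calling scope.

    The caller's source file is identified, hashed (SHA-256 of the source
    bytes) and parsed so statements of tracked calls can be resolved later.
    Only one session may be active at a time.
    """
    global _current_session
    if _current_session is not None and _current_session.active:
        raise ActivationError(
            "a capture session is already active; call deactivate() first")

    frame = inspect.currentframe()
    for _ in range(_frame_offset):
        frame = frame.f_back  # type: ignore[union-attr]
    script_path = Path(frame.f_code.co_filename)  # type: ignore[union-attr]
    try:
        source_bytes = script_path.read_bytes()
    except OSError as exc:
        raise ActivationError(
            f"cannot read tracked source file {script_path}: {exc}") from exc

    try:
        tree: Optional[ast.Module] = ast.parse(source_bytes.decode("utf-8"))
        source_lines = source_bytes.decode("utf-8").splitlines(keepends=True)
    except (SyntaxError, UnicodeDecodeError):
        tree, source_lines = None, []

    descriptors.reset_none_uuid()
    _current_session = CaptureSession(
        session_id=_ids.new_uuid(),
        script_path=str(script_path.resolve()),
        script_file_hash=hashlib.sha256(source_bytes).hexdigest(),
        settings=settings or get_settings(),
        source_lines=source_lines,
        source_tree=tree,
    )
    return _current_session


def deactivate() -> Optional[CaptureSession]:
    """Stop the active session (history is kept for serialization)."""
    global _current_session
    session = _current_session
    if session is not None:
        session.active = False
    _current_session = None
    return session
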