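"""Run-time instrumentation of data-processing functions.

The :class:`Provenance` decorator wraps each data-processing function of a
script. When a capture session is active, every call is recorded: inputs
and outputs are described by content, all remaining arguments (including
defaults not written at the call site) are recorded as parameters, the
source statement is located and analyzed for container accesses, and the
record is appended to the session history with the value of the global
execution counter. The wrapped call's behavior and return value are
identical to the unwrapped call; capture failures warn and degrade but
never alter the user's computation.
"""

from __future__ import annotations

import ast
import functools
import importlib.metadata
import inspect
import warnings
from pathlib import Path
from types import FrameType
from typing import Any, Callable, Dict, Iterable, List, Optional, Set, Tuple

from . import _ids
from .callsite import analyze_call_site, find_tracked_calls
from .descriptors import (DataObjectDescriptor, Descriptor, FileDescriptor,
                          FunctionInfo, _snapshot, describe_file,
                          describe_object)
from .records import INDEX, FunctionExecutionRecord, MembershipRecord
from .session import CaptureSession, current_session

#: Containers larger than this are not expanded element-wise.
_MAX_EXPANDED_ELEMENTS = 64


def _container_memberships(value: Any) -> List[MembershipRecord]:
    """Element-wise memberships for builtin containers.

    A tracked function may return or take a plain list/tuple/dict of data
    objects (e.g. the list of trial segments produced by a cutting stage,
    later iterated in a loop). The loop variable hides the subscript from
    the call-site analysis, so the container -> element relations are
    recorded here instead, keeping each element connected to the call
    that produced or consumed the container.
    """
    if isinstance(value, (list, tuple)):
        items = list(enumerate(value))
    elif isinstance(value, dict):
        items = list(value.items())
    else:
        return []
    if not 0 < len(items) <= _MAX_EXPANDED_ELEMENTS:
        return []
    elements = [(key, element) for key, element in items
                if not isinstance(element, (bool, int, float, str,
                                            type(None)))]
    if not elements:
        return []
    container = _describe_object_safe(value)
    return [MembershipRecord(container=container,
                             element=_describe_object_safe(element),
                             relation=INDEX, accessor=str(key))
            for key, element in elements]


def _as_set(names: Optional[Iterable[str]]) -> Set[str]:
    if names is None:
        return set()
    if isinstance(names, str):
        return {names}
    return set(names)


def function_info(function: Callable,
                  script_path: Optional[str] = None) -> FunctionInfo:
    """Name, module and package version of a tracked function.

    The version is looked up from the installed distribution of the
    function's root package; functions defined in the tracked script
    itself (or any module without distribution metadata) get ``"NA"``.
    """
    module = getattr(function, "__module__", "") or ""
    name = getattr(function, "__name__", repr(function))
    version = "NA"
    source_file = getattr(getattr(function, "__code__", None),
                          "co_filename", None)
    in_script = (script_path is not None and source_file is not None
                 and str(Path(source_file).resolve()) == script_path)
    if module not in ("", "__main__") and not in_script:
        try:
            version = importlib.metadata.version(module.partition(".")[0])
        except importlib.metadata.PackageNotFoundError:
            version = "NA"
    return FunctionInfo(name=name, module_path=module, version=version)


def _describe_file_safe(path: Any) -> FileDescriptor:
    try:
        return describe_file(path)
    except OSError as exc:
        warnings.warn(f"cannot hash file {path!r}: {exc}", stacklevel=3)
        return FileDescriptor(file_hash="", path=str(path))


def _describe_object_safe(value: Any) -> DataObjectDescriptor:
    try:
        return describe_object(value)
    except Exception as exc:
        warnings.warn(f"cannot describe {type(value).__name__}: {exc}",
                      stacklevel=3)
        return DataObjectDescriptor(
            type_name=type(value).__name__,
            module_path=type(value).__module__,
            content_hash=f"<description failed: {exc}>"[:256],
            hash_method="builtin_hash",
            memory_address=id(value),
        )


def record_execution(session: CaptureSession,
                     info: FunctionInfo,
                     bound_args: Dict[str, Any],
                     input_names: Set[str],
                     file_input_names: Set[str],
                     file_output_names: Set[str],
                     return_value: Any,
                     returned_anything: bool,
                     pre_call_inputs: Dict[str, Descriptor],
                     time_start: str,
                     time_end: str,
                     code_statement: str = "",
                     memberships: Optional[List[MembershipRecord]] = None,
                     ) -> FunctionExecutionRecord:
    """Build one execution record and append it to the session history.

    Inputs are taken from the pre-call descriptors (data state before the
    function ran). Return values are enumerated positionally as outputs; a
    file-output argument contributes a file descriptor hashed after the
    call; an input whose content hash changed during the call was mutated
    in place and is additionally emitted as an output.
    """
    parameters = {
        name: _snapshot(value) for name, value in bound_args.items()
        if name not in input_names and name not in file_input_names
        and name not in file_output_names
    }

    outputs: List[Descriptor] = []
    if returned_anything:
        values = return_value if isinstance(return_value, tuple) \
            else (return_value,)
        outputs.extend(_describe_object_safe(value) for value in values)
    for name in sorted(file_output_names):
        outputs.append(_describe_file_safe(bound_args[name]))
    for name in sorted(input_names):
        before = pre_call_inputs.get(name)
        if not isinstance(before, DataObjectDescriptor):
            continue
        after = _describe_object_safe(bound_args[name])
        if isinstance(after, DataObjectDescriptor) and \
                not after.same_data(before):
            outputs.append(after)  # in-place modification

    memberships = list(memberships or [])
    for name in sorted(input_names):
        if name in bound_args:
            memberships.extend(_container_memberships(bound_args[name]))
    if returned_anything:
        for value in values:
            memberships.extend(_container_memberships(value))

    record = FunctionExecutionRecord(
        execution_id=_ids.new_uuid(),
        function=info,
        inputs=pre_call_inputs,
        parameters=parameters,
        outputs=outputs,
        memberships=memberships or [],
        order=session.next_order(),
        time_start=time_start,
        time_end=time_end,
        code_statement=code_statement,
    )
    session.history.append(record)
    return record


def _script_frame(session: CaptureSession,
                  frame: Optional[FrameType]) -> Optional[FrameType]:
    """Nearest caller frame that lives in the activated script."""
    while frame is not None:
        filename = frame.f_code.co_filename
        if filename == session.script_path or \
                str(Path(filename).resolve()) == session.script_path:
            return frame
        frame = frame.f_back
    return None


class Provenance:
    """Decorator declaring the argument roles of a data-processing function.

    Parameters
    ----------
    inputs
        Argument names holding data-object inputs.
    file_input
        Argument names holding paths of files read by the function
        (hashed before the call).
    file_output
        Argument names holding paths of files written by the function
        (hashed after the call returns).

    All other arguments are recorded as parameters. The three role sets
    must be disjoint subsets of the function's declared argument names.
    """

    def __init__(self,
                 inputs: Optional[Iterable[str]] = None,
                 file_input: Optional[Iterable[str]] = None,
                 file_output: Optional[Iterable[str]] = None) -> None:
        self.input_names = _as_set(inputs)
        self.file_input_names = _as_set(file_input)
        self.file_output_names = _as_set(file_output)

    def _validate(self, function: Callable,
                  signature: inspect.Signature) -> None:
        declared = set(signature.parameters)
        roles = (("inputs", self.input_names),
                 ("file_input", self.file_input_names),
                 ("file_output", self.file_output_names))
        for label, names in roles:
            unknown = names - declared
            if unknown:
                raise ValueError(
                    f"{label} names {sorted(unknown)} are not arguments of "
                    f"{function.__name__}{signature}")
        overlap = (self.input_names & self.file_input_names) | \
                  (self.input_names & self.file_output_names) | \
                  (self.file_input_names & self.file_output_names)
        if overlap:
            raise ValueError(f"argument roles overlap: {sorted(overlap)}")

    def __call__(self, function: Callable) -> Callable:
        signature = inspect.signature(function)
        self._validate(function, signature)

        @functools.wraps(function)
        def wrapper(*args: Any, **kwargs: Any) -> Any:
            session = current_session()
            if session is None or not session.active:
                return function(*args, **kwargs)

            bound_args: Optional[Dict[str, Any]] = None
            pre_call: Dict[str, Descriptor] = {}
            try:
                bound = signature.bind(*args, **kwargs)
                bound.apply_defaults()
                bound_args = dict(bound.arguments)
                for name in self.input_names:
                    if name in bound_args:
                        pre_call[name] = _describe_object_safe(
                            bound_args[name])
                for name in self.file_input_names:
                    if name in bound_args:
                        pre_call[name] = _describe_file_safe(bound_args[name])
            except Exception as exc:
                warnings.warn(f"provenance pre-call capture failed for "
                              f"{function.__name__}: {exc}", stacklevel=2)
                bound_args = None

            time_start = _ids.timestamp()
            result = function(*args, **kwargs)
            time_end = _ids.timestamp()

            if bound_args is not None:
                try:
                    statement_text, memberships = self._call_context(
                        session, wrapper, signature)
                    record_execution(
                        session=session,
                        info=function_info(function, session.script_path),
                        bound_args=bound_args,
                        input_names=self.input_names,
                        file_input_names=self.file_input_names,
                        file_output_names=self.file_output_names,
                        return_value=result,
                        returned_anything=True,
                        pre_call_inputs=pre_call,
                        time_start=time_start,
                        time_end=time_end,
                        code_statement=statement_text,
                        memberships=memberships,
                    )
                except Exception as exc:
                    warnings.warn(
                        f"provenance capture failed for "
                        f"{function.__name__}: {exc}", stacklevel=2)
            return result

        wrapper.__wrapped__ = function
        wrapper.__provenance__ = self
        return wrapper

    def _call_context(self, session: CaptureSession, wrapper: Callable,
                      signature: inspect.Signature
                      ) -> Tuple[str, List[MembershipRecord]]:
        """Locate the source statement of the current tracked call and
        analyze its container accesses."""
        frame = _script_frame(session,
                              inspect.currentframe().f_back.f_back)
        if frame is None:
            return "", []
        statement = session.statement_at(frame.f_lineno)
        if statement is None:
            return "", []
        text = session.statement_source(statement)
        calls = find_tracked_calls(statement, frame, wrapper)
        if not calls:
            return text, []
        source = "".join(session.source_lines)
        memberships = analyze_call_site(calls[0], frame, source,
                                        session.settings,
                                        signature=signature,
                                        input_names=self.input_names)
        return text, memberships


def track(function: Callable,
          input_names: Optional[Iterable[str]] = None,
          file_input_names: Optional[Iterable[str]] = None,
          file_output_names: Optional[Iterable[str]] = None) -> Callable:
    """Functional form of :class:`Provenance` for wrapping an existing
    function: ``tracked = track(f, input_names={"data"})``."""
    return Provenance(inputs=input_names, file_input=file_input_names,
                      file_output=file_output_names)(function)
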