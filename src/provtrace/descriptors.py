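"""Identity and metadata snapshots of data objects and files.

A :class:`DataObjectDescriptor` captures what is needed to identify one
in-memory object across records, sessions and processes: its type, a
content hash, and a snapshot of its metadata (instance attributes plus
annotation dictionaries). Identity is content-based — two objects with
equal type and content hash denote the same logical data state, which is
what lets provenance graphs from separate runs connect on merge.

Files are identified by the SHA-256 digest of their bytes, so the same
content under two paths unifies to one entity.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Tuple, Union

import joblib
import numpy as np

from . import _ids
from .settings import CaptureSettings, get_settings

#: hash_method values; the serialized ``hashSource`` literal is mapped from
#: these in the ontology layer ("joblib_SHA1", "Python_hash", "UUID").
CONTENT_SHA1 = "content_sha1"
BUILTIN_HASH = "builtin_hash"
UUID_HASH = "uuid"

#: Snapshot bound for non-scalar attribute values.
MAX_REPR_LENGTH = 256

#: Attributes captured when present even if not in the instance ``__dict__``
#: (array shape/dtype, physical units, timing metadata of electrophysiology
#: data models, and generic identity attributes of other data models).
SPECIAL_ATTRIBUTES = (
    "shape", "dtype", "units", "t_start", "t_stop", "nix_name",
    "dimensionality", "id", "pid", "create_time",
)


@dataclass(frozen=True)
class DataObjectDescriptor:
    """Identity + metadata snapshot of one in-memory data object."""

    type_name: str
    module_path: str
    content_hash: str
    hash_method: str
    memory_address: int
    attributes: Dict[str, Any] = field(default_factory=dict)
    annotations: Dict[str, Any] = field(default_factory=dict)

    @property
    def qualified_type(self) -> str:
        """Full dotted path of the class (``module.Class``)."""
        if self.module_path:
            return f"{self.module_path}.{self.type_name}"
        return self.type_name

    def same_data(self, other: "DataObjectDescriptor") -> bool:
        """Whether both descriptors denote the same logical data state."""
        return (self.type_name, self.content_hash, self.hash_method) == \
               (other.type_name, other.content_hash, other.hash_method)


@dataclass(frozen=True)
class FileDescriptor:
    """Identity of a file input/output: content digest plus location."""

    file_hash: str
    path: str
    hash_type: str = "sha256"


@dataclass(frozen=True)
class FunctionInfo:
    """Identity of a tracked function: name, module, package version."""

    name: str
    module_path: str
    version: str = "NA"

    @property
    def qualified_name(self) -> str:
        if self.module_path:
            return f"{self.module_path}.{self.name}"
        return self.name


Descriptor = Union[DataObjectDescriptor, FileDescriptor]

# The builtin None is a single object shared throughout the interpreter, so
# it is identified by one UUID per capture session rather than a content
# hash; this avoids duplicating a meaningless entity.
_none_uuid: str | None = None


def reset_none_uuid() -> None:
    global _none_uuid
    _none_uuid = None


def _root_package(module_path: str) -> str:
    return module_path.partition(".")[0]


def _array_content_digest(obj: np.ndarray) -> str:
    """SHA-1 over type identity + raw buffer + shape + dtype + unit string."""
    cls = type(obj)
    digest = hashlib.sha1()
    digest.update(f"{cls.__module__}.{cls.__name__}".encode())
    digest.update(str(obj.shape).encode())
    digest.update(str(obj.dtype).encode())
    units = getattr(obj, "units", None)
    if units is not None:
        digest.update(str(units).encode())
    digest.update(np.ascontiguousarray(obj).view(np.ndarray).tobytes())
    return digest.hexdigest()


def hash_object(obj: Any,
                settings: CaptureSettings | None = None) -> Tuple[str, str]:
    """Return ``(digest, hash_method)`` identifying *obj* by content.

    ``None`` maps to a session-shared UUID. Objects from packages listed in
    ``settings.builtin_hash_packages`` use the object's own ``hash()``
    value. Everything else gets a deterministic SHA-1 content digest over
    the type identity and object state (raw buffer bytes, shape, dtype and
    unit string for array-likes; a canonical pickle otherwise). A failing
    content hash degrades to the builtin hash with a warning.
    """
    settings = settings or get_settings()
    if obj is None:
        global _none_uuid
        if _none_uuid is None:
            _none_uuid = _ids.new_uuid()
        return _none_uuid, UUID_HASH

    package = _root_package(type(obj).__module__)
    if package in settings.builtin_hash_packages:
        return str(hash(obj)), BUILTIN_HASH

    try:
        if isinstance(obj, np.ndarray) and obj.dtype != object:
            return _array_content_digest(obj), CONTENT_SHA1
        cls = type(obj)
        payload = (f"{cls.__module__}.{cls.__name__}", obj)
        return joblib.hash(payload, hash_name="sha1"), CONTENT_SHA1
    except Exception as exc:  # degrade, never abort the user's computation
        warnings.warn(
            f"content hashing failed for {type(obj).__name__}: {exc}; "
            "falling back to the builtin hash", stacklevel=2)
        try:
            return str(hash(obj)), BUILTIN_HASH
        except TypeError:
            return str(id(obj)), BUILTIN_HASH


def _snapshot(value: Any) -> Any:
    """Literal snapshot of an attribute/parameter value.

    Scalars are kept as-is; anything else becomes a bounded string
    representation so bulk data never ends up embedded in metadata.
    """
    if isinstance(value, (bool, int, float)) or value is None:
        return value
    if isinstance(value, str):
        return value[:MAX_REPR_LENGTH]
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.dtype):
        return str(value)
    try:
        return repr(value)[:MAX_REPR_LENGTH]
    except Exception:
        return f"<unrepresentable {type(value).__name__}>"


def describe_object(obj: Any,
                    settings: CaptureSettings | None = None
                    ) -> DataObjectDescriptor:
    """Build the identity + metadata descriptor of one data object.

    Captures the type, content hash (via :func:`hash_object`), current
    memory address, a snapshot of all instance attributes plus the special
    attributes in :data:`SPECIAL_ATTRIBUTES` when present, and annotation
    dictionaries extracted through the metadata plugin registry.
    """
    settings = settings or get_settings()
    cls = type(obj)
    digest, method = hash_object(obj, settings)

    attributes: Dict[str, Any] = {}
    instance_dict = getattr(obj, "__dict__", None)
    if isinstance(instance_dict, dict):
        for name, value in instance_dict.items():
            if name.startswith("_") or name in ("annotations",
                                                "array_annotations"):
                continue
            attributes[name] = _snapshot(value)
    for name in SPECIAL_ATTRIBUTES:
        if name in attributes:
            continue
        try:
            value = getattr(obj, name)
        except Exception:
            continue
        if value is not None and not callable(value):
            attributes[name] = _snapshot(value)

    annotations: Dict[str, Any] = {}
    if obj is not None:
        plugin = settings.metadata_plugins.get(
            _root_package(cls.__module__),
            settings.metadata_plugins.get(""))
        if plugin is not None:
            try:
                for group in plugin(obj).values():
                    for key, value in group.items():
                        annotations[key] = _snapshot(value)
            except Exception as exc:
                warnings.warn(f"annotation extraction failed: {exc}",
                              stacklevel=2)

    return DataObjectDescriptor(
        type_name=cls.__name__,
        module_path=cls.__module__,
        content_hash=digest,
        hash_method=method,
        memory_address=id(obj),
        attributes=attributes,
        annotations=annotations,
    )


def describe_file(path: Union[str, Path]) -> FileDescriptor:
    """Describe a file by the SHA-256 digest of its content."""
    resolved = Path(path).resolve()
    digest = hashlib.sha256()
    with open(resolved, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return FileDescriptor(file_hash=digest.hexdigest(), path=str(resolved))
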