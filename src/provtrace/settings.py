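"""Global capture settings.

Settings act globally within the toolbox and control how objects are
identified (the ``authority`` component of every URN) and hashed (packages
whose objects are hashed with the builtin ``hash`` instead of a content
digest), plus the plugin registry used to extract annotation metadata from
package-specific data models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Dict, Set

#: Plugin signature: obj -> {"annotations": {...}, "array_annotations": {...}}
MetadataPlugin = Callable[[Any], Dict[str, Dict[str, Any]]]


def _default_annotation_plugin(obj: Any) -> Dict[str, Dict[str, Any]]:
    """Read the conventional ``annotations``/``array_annotations`` dicts."""
    result: Dict[str, Dict[str, Any]] = {}
    for attr in ("annotations", "array_annotations"):
        value = getattr(obj, attr, None)
        if isinstance(value, dict) and value:
            result[attr] = value
    return result


@dataclass
class CaptureSettings:
    """Global options for provenance capture.

    Parameters
    ----------
    authority
        Organizational identifier used in every generated URN
        (``urn:[authority]:alpaca:...``).
    builtin_hash_packages
        Root package names whose objects are identified by their builtin
        ``hash()`` value instead of a content digest. Useful for objects
        that implement a meaningful ``__hash__``, or to avoid provenance
        that is overly sensitive to small content changes.
    metadata_plugins
        Registry mapping a root package name to a hook extracting
        annotation dictionaries from that package's objects. The ``""``
        key is the fallback applied to any object.
    """

    authority: str = "my-authority"
    builtin_hash_packages: Set[str] = field(default_factory=set)
    metadata_plugins: Dict[str, MetadataPlugin] = field(
        default_factory=lambda: {"": _default_annotation_plugin})


_settings = CaptureSettings()


def get_settings() -> CaptureSettings:
    return _settings


def configure(**changes: Any) -> CaptureSettings:
    """Update global capture settings.

    Accepts any field of :class:`CaptureSettings` as a keyword argument.
    May be called before activation; the authority is used in all URNs
    generated afterwards. Unknown names raise ``ValueError``.
    """
    valid = set(CaptureSettings.__dataclass_fields__)
    for name, value in changes.items():
        if name not in valid:
            raise ValueError(
                f"unknown setting {name!r}; valid settings: {sorted(valid)}")
        if name == "authority" and (not isinstance(value, str) or not value):
            raise ValueError("authority must be a non-empty string")
        if name == "builtin_hash_packages":
            value = set(value)
        setattr(_settings, name, value)
    return _settings


def register_metadata_plugin(package: str, plugin: MetadataPlugin) -> None:
    """Register a metadata-extraction hook for objects of *package*."""
    _settings.metadata_plugins[package] = plugin
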