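"""Injectable sources for UUIDs and timestamps.

Every identifier and timestamp written into a provenance record goes
through the module-level :data:`id_source`, so that tests (and golden-file
comparisons) can replace randomness and wall-clock time with deterministic
sequences without monkey-patching the capture machinery.
"""

from __future__ import annotations

import contextlib
import datetime
import random
import uuid
from typing import Iterator


class IdSource:
    """Default source: random version-4 UUIDs and UTC wall-clock time."""

    def new_uuid(self) -> str:
        return str(uuid.uuid4())

    def now(self) -> datetime.datetime:
        return datetime.datetime.now(datetime.timezone.utc)


class FixedIdSource(IdSource):
    """Deterministic source for reproducible serializations.

    UUIDs are drawn from a seeded RNG (still valid version-4 UUIDs) and the
    clock advances by a fixed step from a fixed start, so two captures of
    the same computation produce byte-identical records.
    """

    def __init__(self, seed: int = 0,
                 start: datetime.datetime | None = None,
                 step_us: int = 1000) -> None:
        self._rng = random.Random(seed)
        self._time = start or datetime.datetime(
            2000, 1, 1, tzinfo=datetime.timezone.utc)
        self._step = datetime.timedelta(microseconds=step_us)

    def new_uuid(self) -> str:
        return str(uuid.UUID(int=self._rng.getrandbits(128), version=4))

    def now(self) -> datetime.datetime:
        t = self._time
        self._time = t + self._step
        return t


id_source: IdSource = IdSource()


def set_id_source(source: IdSource) -> IdSource:
    """Install *source* globally; returns the previous source."""
    global id_source
    previous = id_source
    id_source = source
    return previous


@contextlib.contextmanager
def deterministic_ids(seed: int = 0) -> Iterator[FixedIdSource]:
    """Context manager fixing UUIDs and timestamps for the enclosed code."""
    source = FixedIdSource(seed)
    previous = set_id_source(source)
    try:
        yield source
    finally:
        set_id_source(previous)


def new_uuid() -> str:
    return id_source.new_uuid()


def timestamp() -> str:
    """Current time as ISO-8601 UTC with microsecond precision."""
    return id_source.now().isoformat(timespec="microseconds")
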