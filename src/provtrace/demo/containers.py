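"""Lightweight electrophysiology data containers for the demo pipeline.

A minimal stand-in for the field's standard object model: a ``Block``
holds ``Segment`` containers, which group multichannel time series
(``AnalogSignal``), labeled timestamps (``Event``) and time windows
(``Epoch``) sharing a common time axis. Objects carry ``annotations``
(whole-object key--value metadata) and ``array_annotations`` (one value
per data element, e.g. per channel or per event), which the capture layer
picks up through its metadata plugin registry.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np


class Quantity(np.ndarray):
    """A numeric array with an attached physical-unit string."""

    def __new__(cls, data, units: str = "") -> "Quantity":
        obj = np.asarray(data).view(cls)
        obj.units = units
        return obj

    def __array_finalize__(self, obj) -> None:
        self.units = getattr(obj, "units", "")


class AnalogSignal:
    """Continuous multichannel time series sampled at a fixed rate.

    ``data`` has shape (samples, channels); the time axis is defined by
    ``t_start`` (seconds) and ``sampling_rate`` (Hz).
    """

    def __init__(self, data: np.ndarray, sampling_rate: float,
                 t_start: float = 0.0, units: str = "uV",
                 annotations: Optional[Dict] = None,
                 array_annotations: Optional[Dict] = None) -> None:
        self.data = np.asarray(data)
        if self.data.ndim != 2:
            raise ValueError("AnalogSignal data must be 2-D "
                             "(samples, channels)")
        self.sampling_rate = float(sampling_rate)
        self.t_start = float(t_start)
        self.units = units
        self.annotations = dict(annotations or {})
        self.array_annotations = dict(array_annotations or {})

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def t_stop(self) -> float:
        return self.t_start + self.data.shape[0] / self.sampling_rate

    def time_slice(self, t_start: float, t_stop: float) -> "AnalogSignal":
        i0 = int(round((t_start - self.t_start) * self.sampling_rate))
        i1 = int(round((t_stop - self.t_start) * self.sampling_rate))
        return AnalogSignal(self.data[i0:i1], self.sampling_rate,
                            t_start=t_start, units=self.units,
                            annotations=self.annotations,
                            array_annotations=self.array_annotations)


class Event:
    """Labeled timestamps (seconds), with per-event array annotations."""

    def __init__(self, times: Sequence[float], labels: Sequence[str],
                 annotations: Optional[Dict] = None,
                 array_annotations: Optional[Dict] = None) -> None:
        self.times = np.asarray(times, dtype=float)
        self.labels = np.asarray(labels)
        self.annotations = dict(annotations or {})
        self.array_annotations = {
            key: np.asarray(value)
            for key, value in (array_annotations or {}).items()}

    @property
    def shape(self):
        return self.times.shape

    def __len__(self) -> int:
        return len(self.times)

    def select(self, mask: np.ndarray) -> "Event":
        return Event(self.times[mask], self.labels[mask],
                     annotations=self.annotations,
                     array_annotations={k: v[mask] for k, v in
                                        self.array_annotations.items()})


class Epoch:
    """Time windows: start times plus durations (both seconds)."""

    def __init__(self, times: Sequence[float], durations: Sequence[float],
                 labels: Optional[Sequence[str]] = None,
                 annotations: Optional[Dict] = None) -> None:
        self.times = np.asarray(times, dtype=float)
        self.durations = np.asarray(durations, dtype=float)
        self.labels = np.asarray(labels if labels is not None
                                 else [""] * len(self.times))
        self.annotations = dict(annotations or {})

    def __len__(self) -> int:
        return len(self.times)


class Segment:
    """Container grouping data objects sharing one time axis."""

    def __init__(self, t_start: float = 0.0, t_stop: float = 0.0,
                 annotations: Optional[Dict] = None) -> None:
        self.analogsignals: List[AnalogSignal] = []
        self.events: List[Event] = []
        self.epochs: List[Epoch] = []
        self.t_start = float(t_start)
        self.t_stop = float(t_stop)
        self.annotations = dict(annotations or {})


class Block:
    """Top-level container holding one or more segments."""

    def __init__(self, annotations: Optional[Dict] = None) -> None:
        self.segments: List[Segment] = []
        self.annotations = dict(annotations or {})
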