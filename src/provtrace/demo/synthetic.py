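"""Synthetic multichannel recordings with a known spectral ground truth.

The generator emulates the structure of a multielectrode reach-to-grasp
recording session: a continuous multichannel signal sampled at 30 kHz,
with behavioral events of four trial types (side/precision grip x
low/high force) embedded as labeled timestamps. The signal is a sinusoid
of known frequency on every channel plus white noise, so the spectral
content of every pipeline stage is predictable (a pure 20 Hz tone must
produce a peak at the 20 Hz bin of a Welch estimate).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Tuple, Union

import numpy as np

from .containers import AnalogSignal, Block, Event, Segment

TRIAL_TYPES = ("SGLF", "SGHF", "PGLF", "PGHF")
#: Within-trial event labels, as offsets (s) from trial start.
TRIAL_EVENTS = (("CUE-ON", -1.3), ("CUE-OFF", 0.0), ("GO-ON", 1.0))


@dataclass(frozen=True)
class DemoConfig:
    """Study conditions of the demo pipeline.

    The defaults reproduce the conditions of the multielectrode use case:
    96-channel Utah-array-like recording at 30 kHz, four trial types,
    500 ms analysis epochs after the CUE-OFF event, a 250 Hz low-pass
    Butterworth filter, downsampling by 60 (to 500 Hz), and a Welch PSD
    with 2 Hz frequency resolution (Hanning window, 50% overlap).
    """

    channels: int = 96
    sampling_rate: float = 30000.0  # Hz
    trials_per_type: int = 2
    trial_types: Tuple[str, ...] = TRIAL_TYPES
    trial_spacing: float = 1.5      # s between trial starts
    signal_frequency: float = 20.0  # Hz, ground-truth sinusoid
    signal_amplitude: float = 10.0  # uV
    noise_sd: float = 1.0           # uV
    epoch_pre: float = 0.0          # ms before CUE-OFF
    epoch_post: float = 500.0       # ms after CUE-OFF
    exclude_channels: Tuple[str, ...] = ("chan 2", "chan 4")
    lowpass_frequency: float = 250.0  # Hz
    downsample_factor: int = 60
    frequency_resolution: float = 2.0  # Hz
    psd_window: str = "hann"
    psd_overlap: float = 0.5

    @property
    def n_trials(self) -> int:
        return self.trials_per_type * len(self.trial_types)

    @property
    def duration(self) -> float:
        """Recording length (s): margin + trials + margin."""
        return 1.5 + self.n_trials * self.trial_spacing + 0.5

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "DemoConfig":
        """Read a key-value config file (``key = value`` or ``key: value``
        per line; ``#`` comments); values parsed as Python literals."""
        overrides = {}
        known = {f.name for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            separator = "=" if "=" in line else ":"
            key, _, value = line.partition(separator)
            key = key.strip()
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            try:
                overrides[key] = ast.literal_eval(value.strip())
            except (ValueError, SyntaxError):
                overrides[key] = value.strip()
        return replace(cls(), **overrides)


def generate_recording(config: DemoConfig | None = None,
                       seed: int = 0,
                       subject_name: str = "subject-A") -> Block:
    """Generate one synthetic recording session.

    Returns a :class:`Block` with a single :class:`Segment` holding the
    continuous multichannel signal and the behavioral-event train. A
    fixed seed reproduces the recording exactly.
    """
    config = config or DemoConfig()
    if config.channels <= 0:
        raise ValueError("channels must be positive")
    if config.duration <= 0 or config.n_trials <= 0:
        raise ValueError("recording must contain at least one trial")

    rng = np.random.default_rng(seed)
    n_samples = int(round(config.duration * config.sampling_rate))
    t = np.arange(n_samples, dtype=np.float32) / config.sampling_rate
    tone = (config.signal_amplitude *
            np.sin(2 * np.pi * config.signal_frequency * t))
    data = tone[:, None] + rng.normal(
        0.0, config.noise_sd,
        size=(n_samples, config.channels)).astype(np.float32)

    channel_names = np.array([f"chan {i}" for i in range(config.channels)])
    signal = AnalogSignal(
        data, sampling_rate=config.sampling_rate, t_start=0.0, units="uV",
        annotations={"subject_name": subject_name},
        array_annotations={"channel_names": channel_names})

    # interleave trial types so consecutive trials differ
    order = [trial_type for _ in range(config.trials_per_type)
             for trial_type in config.trial_types]
    times, labels, trial_types, performance = [], [], [], []
    for index, trial_type in enumerate(order):
        start = 1.5 + index * config.trial_spacing
        for event_label, offset in TRIAL_EVENTS:
            time = start + offset
            if not 0.0 <= time < config.duration:
                continue
            times.append(time)
            labels.append(event_label)
            trial_types.append(trial_type)
            performance.append("correct_trial")

    event = Event(
        times, labels,
        annotations={"subject_name": subject_name},
        array_annotations={
            "trial_event_labels": np.array(labels),
            "belongs_to_trialtype": np.array(trial_types),
            "performance_in_trial_str": np.array(performance),
        })

    segment = Segment(t_start=0.0, t_stop=config.duration,
                      annotations={"subject_name": subject_name})
    segment.analogsignals.append(signal)
    segment.events.append(event)
    block = Block(annotations={"subject_name": subject_name})
    block.segments.append(segment)
    return block
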