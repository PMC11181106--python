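"""Run-time file I/O for synthetic recordings and intermediate results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .containers import AnalogSignal, Block, Event, Segment


def save_recording(block: Block, path: Union[str, Path]) -> str:
    """Write a single-segment recording to an ``.npz`` archive."""
    segment = block.segments[0]
    signal = segment.analogsignals[0]
    event = segment.events[0]
    np.savez(
        str(path),
        data=signal.data,
        sampling_rate=signal.sampling_rate,
        t_start=signal.t_start,
        t_stop=segment.t_stop,
        units=signal.units,
        channel_names=signal.array_annotations["channel_names"],
        event_times=event.times,
        event_labels=event.labels,
        event_annotations=json.dumps(
            {k: np.asarray(v).tolist()
             for k, v in event.array_annotations.items()}),
        annotations=json.dumps(block.annotations),
    )
    return str(path)


def load_recording(path: Union[str, Path]) -> Block:
    with np.load(str(path), allow_pickle=False) as archive:
        annotations = json.loads(str(archive["annotations"]))
        signal = AnalogSignal(
            archive["data"],
            sampling_rate=float(archive["sampling_rate"]),
            t_start=float(archive["t_start"]),
            units=str(archive["units"]),
            annotations=annotations,
            array_annotations={"channel_names": archive["channel_names"]})
        event = Event(
            archive["event_times"], archive["event_labels"],
            annotations=annotations,
            array_annotations={
                k: np.asarray(v) for k, v in
                json.loads(str(archive["event_annotations"])).items()})
        segment = Segment(t_start=float(archive["t_start"]),
                          t_stop=float(archive["t_stop"]),
                          annotations=annotations)
        segment.analogsignals.append(signal)
        segment.events.append(event)
        block = Block(annotations=annotations)
        block.segments.append(segment)
    return block
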