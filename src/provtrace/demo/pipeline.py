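"""Tracked PSD analysis pipeline over synthetic recordings.

The pipeline mirrors a typical trial-resolved spectral analysis of a
multielectrode recording session: for each input file, and for each of
the four trial types, the behavioral events are selected by label, 500 ms
epochs after CUE-OFF are defined and cut, bad channels are excluded, the
signal is low-pass filtered (Butterworth, 250 Hz) and downsampled by 60,
a Welch PSD (2 Hz resolution, Hanning window, 50% overlap) is computed
per channel, and channel/trial averages are plotted and saved. Every
stage is a tracked function, so each run leaves a Turtle provenance
sidecar next to the figure.

``run_split_pipeline`` re-runs the same analysis split across several
capture sessions (emulating multi-process and multi-script workflows) to
show that the resulting RDF files merge into one connected graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.signal
import scipy.stats
from matplotlib.figure import Figure

from ..capture import Provenance
from ..serialization import save_provenance
from ..session import activate, deactivate
from ..settings import get_settings
from . import io
from .containers import AnalogSignal, Block, Epoch, Event, Quantity, Segment
from .synthetic import DemoConfig, generate_recording

# --------------------------------------------------------------------
# tracked analysis stages
# --------------------------------------------------------------------


@Provenance(file_input=["path"])
def load_data(path: str) -> Block:
    """Load a recording session from an ``.npz`` dataset file."""
    return io.load_recording(path)


@Provenance(inputs=["segment"])
def get_events(segment: Segment, properties: Dict[str, str]) -> Event:
    """Select the events whose array annotations match *properties*."""
    event = segment.events[0]
    mask = np.ones(len(event), dtype=bool)
    for key, value in properties.items():
        mask &= event.array_annotations[key] == value
    selected = event.select(mask)
    # the selection criteria become whole-object metadata of the result
    selected.annotations.update(properties)
    return selected


@Provenance(inputs=["segment", "event"])
def add_epoch(segment: Segment, event: Event,
              pre: float = 0.0, post: float = 500.0) -> Epoch:
    """Define one epoch per event time, from *pre* to *post* (ms)."""
    times = event.times + pre / 1000.0
    durations = np.full(len(event), (post - pre) / 1000.0)
    return Epoch(times, durations, labels=event.labels,
                 annotations=segment.annotations)


@Provenance(inputs=["segment", "epoch"])
def cut_segment_by_epoch(segment: Segment, epoch: Epoch,
                         reset_time: bool = False) -> List[Segment]:
    """Cut one sub-segment per epoch window."""
    trials = []
    for start, duration in zip(epoch.times, epoch.durations):
        signal = segment.analogsignals[0].time_slice(start, start + duration)
        if reset_time:
            signal.t_start = 0.0
        trial = Segment(t_start=signal.t_start, t_stop=signal.t_stop,
                        annotations=segment.annotations)
        trial.analogsignals.append(signal)
        trials.append(trial)
    return trials


@Provenance(inputs=["signal"])
def select_channels(signal: AnalogSignal,
                    exclude_channels: Sequence[str] = ()) -> AnalogSignal:
    """Drop channels whose name is in *exclude_channels*."""
    names = signal.array_annotations["channel_names"]
    keep = ~np.isin(names, list(exclude_channels))
    return AnalogSignal(signal.data[:, keep], signal.sampling_rate,
                        t_start=signal.t_start, units=signal.units,
                        annotations=signal.annotations,
                        array_annotations={"channel_names": names[keep]})


@Provenance(inputs=["signal"])
def butter(signal: AnalogSignal, lowpass_frequency: float = 250.0,
           order: int = 4) -> AnalogSignal:
    """Zero-phase Butterworth low-pass filter."""
    sos = scipy.signal.butter(order, lowpass_frequency, btype="low",
                              fs=signal.sampling_rate, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, signal.data, axis=0)
    return AnalogSignal(filtered, signal.sampling_rate,
                        t_start=signal.t_start, units=signal.units,
                        annotations=signal.annotations,
                        array_annotations=signal.array_annotations)


@Provenance(inputs=["signal"])
def downsample(signal: AnalogSignal, factor: int = 60) -> AnalogSignal:
    """Keep every *factor*-th sample (the preceding low-pass filter acts
    as the anti-alias filter)."""
    return AnalogSignal(signal.data[::factor],
                        signal.sampling_rate / factor,
                        t_start=signal.t_start, units=signal.units,
                        annotations=signal.annotations,
                        array_annotations=signal.array_annotations)


@Provenance(inputs=["signal"])
def welch_psd(signal: AnalogSignal, frequency_resolution: float = 2.0,
              window: str = "hann",
              overlap: float = 0.5) -> Tuple[Quantity, Quantity]:
    """Per-channel Welch power spectral density.

    The segment length is set from the requested frequency resolution
    (``nperseg = sampling_rate / frequency_resolution``). Returns the
    frequency bins and a (channels, frequencies) PSD array.
    """
    nperseg = int(round(signal.sampling_rate / frequency_resolution))
    frequencies, psd = scipy.signal.welch(
        signal.data, fs=signal.sampling_rate, window=window,
        nperseg=nperseg, noverlap=int(nperseg * overlap), axis=0)
    return (Quantity(frequencies, units="Hz"),
            Quantity(psd.T, units=f"{signal.units}**2/Hz"))


@Provenance(inputs=["psd"])
def mean_psd(psd: Quantity, axis: int = 0) -> Quantity:
    """Average the per-channel PSD across channels."""
    return Quantity(np.mean(np.asarray(psd), axis=axis), units=psd.units)


@Provenance(inputs=["psds"])
def combine_trials(psds: List[Quantity]) -> Quantity:
    """Stack single-trial PSD averages into a (trials, frequencies) array."""
    units = psds[0].units if psds else ""
    return Quantity(np.vstack([np.asarray(p) for p in psds]), units=units)


@Provenance(inputs=["psds"])
def trial_mean(psds: Quantity, axis: int = 0) -> Quantity:
    return Quantity(np.mean(np.asarray(psds), axis=axis), units=psds.units)


@Provenance(inputs=["psds"])
def trial_sem(psds: Quantity, axis: int = 0) -> np.ndarray:
    """Standard error of the mean across trials."""
    return scipy.stats.sem(np.asarray(psds), axis=axis)


@Provenance()
def create_plot(figsize: Tuple[float, float] = (8.0, 5.0)) -> Figure:
    figure = Figure(figsize=figsize)
    axes = figure.add_subplot()
    axes.set_xlabel("Frequency (Hz)")
    axes.set_ylabel("PSD (uV**2/Hz)")
    return figure


@Provenance(inputs=["figure", "frequencies", "mean", "sem"])
def plot_psd(figure: Figure, frequencies: Quantity, mean: Quantity,
             sem: np.ndarray, label: str = "",
             interval_multiplier: float = 1.96) -> Figure:
    """Add one mean-PSD line with its confidence band to the plot."""
    axes = figure.axes[0]
    f = np.asarray(frequencies)
    m = np.asarray(mean)
    axes.plot(f, m, label=label)
    axes.fill_between(f, m - interval_multiplier * np.asarray(sem),
                      m + interval_multiplier * np.asarray(sem), alpha=0.3)
    return figure


@Provenance(inputs=["figure"], file_output=["path"])
def save_plot(figure: Figure, path: str) -> None:
    figure.axes[0].legend(fontsize=6)
    figure.savefig(path)


@Provenance(inputs=["results"], file_output=["path"])
def save_psd_data(results: Dict[str, Quantity], path: str) -> None:
    """Write intermediate PSD summaries (mean/SEM per trial type)."""
    np.savez(path, **{key: np.asarray(value)
                      for key, value in results.items()})


@Provenance(file_input=["path"])
def load_psd_data(path: str) -> Dict[str, Quantity]:
    units = {"freqs": "Hz", "mean": "uV**2/Hz", "sem": ""}
    with np.load(path) as archive:
        return {key: Quantity(archive[key],
                              units=units.get(key.rsplit("_", 1)[-1], ""))
                for key in archive.files}


# --------------------------------------------------------------------
# pipeline drivers
# --------------------------------------------------------------------


@dataclass
class DemoRun:
    """Artifacts of one demo-pipeline execution."""

    plot_path: str
    provenance_paths: List[str]


def _configure_hashing() -> None:
    """Identify plot containers by their builtin hash.

    Figures are mutated by every plotting call and their serialized state
    is not reproducible byte-for-byte, so a content hash would split one
    figure into a long chain of near-identical entities. The builtin-hash
    dispatch keeps one stable entity per figure object.
    """
    get_settings().builtin_hash_packages.add("matplotlib")


def _selection(trial_type: str) -> Dict[str, str]:
    return {"trial_event_labels": "CUE-OFF",
            "performance_in_trial_str": "correct_trial",
            "belongs_to_trialtype": trial_type}


def _analyze_trial_types(block: Block, config: DemoConfig,
                         figure: Optional[Figure]
                         ) -> Dict[str, Quantity]:
    """Inner loops: per trial type, cut trials, compute per-trial PSDs and
    aggregate; plot directly when a figure is given, otherwise collect the
    summaries (used by the split-pipeline compute stages)."""
    summaries: Dict[str, Quantity] = {}
    subject = block.annotations.get("subject_name", "subject")
    for trial_type in config.trial_types:
        events = get_events(block.segments[0],
                            properties=_selection(trial_type))
        epoch = add_epoch(block.segments[0], events,
                          pre=config.epoch_pre, post=config.epoch_post)
        trials = cut_segment_by_epoch(block.segments[0], epoch,
                                      reset_time=False)
        type_psds = []
        frequencies = None
        for trial in trials:
            signal = select_channels(
                trial.analogsignals[0],
                exclude_channels=list(config.exclude_channels))
            filtered = butter(signal,
                              lowpass_frequency=config.lowpass_frequency)
            downsampled = downsample(filtered,
                                     factor=config.downsample_factor)
            frequencies, psd = welch_psd(
                downsampled,
                frequency_resolution=config.frequency_resolution,
                window=config.psd_window, overlap=config.psd_overlap)
            type_psds.append(mean_psd(psd, axis=0))
        combined = combine_trials(type_psds)
        mean = trial_mean(combined, axis=0)
        sem = trial_sem(combined, axis=0)
        if figure is not None:
            figure = plot_psd(figure, frequencies, mean, sem,
                              label=f"{subject} {trial_type}")
        summaries["freqs"] = frequencies
        summaries[f"{trial_type}_mean"] = mean
        summaries[f"{trial_type}_sem"] = Quantity(sem, units="")
    return summaries


def make_recording_files(directory: Union[str, Path],
                         subjects: Sequence[str] = ("subject-A",
                                                    "subject-B"),
                         config: Optional[DemoConfig] = None,
                         seed: int = 0) -> List[str]:
    """Generate and save one synthetic recording file per subject."""
    config = config or DemoConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for index, subject in enumerate(subjects):
        block = generate_recording(config, seed=seed + index,
                                   subject_name=subject)
        paths.append(io.save_recording(
            block, directory / f"recording_{subject}.npz"))
    return paths


def run_demo_pipeline(recording_paths: Sequence[Union[str, Path]],
                      config: Optional[DemoConfig] = None,
                      output_dir: Union[str, Path] = ".",
                      name: str = "demo_psd") -> DemoRun:
    """Run the full analysis under provenance capture.

    Produces ``<name>.png`` and its Turtle sidecar ``<name>.ttl`` in
    *output_dir*.
    """
    config = config or DemoConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    plot_path = str(output_dir / f"{name}.png")
    ttl_path = str(output_dir / f"{name}.ttl")

    _configure_hashing()
    activate()
    try:
        figure = create_plot()
        for file_path in recording_paths:
            block = load_data(str(file_path))
            _analyze_trial_types(block, config, figure)
        save_plot(figure, plot_path)
        save_provenance(ttl_path)
    finally:
        deactivate()
    return DemoRun(plot_path=plot_path, provenance_paths=[ttl_path])


def run_split_pipeline(recording_paths: Sequence[Union[str, Path]],
                       mode: str = "two_stage",
                       config: Optional[DemoConfig] = None,
                       output_dir: Union[str, Path] = ".") -> DemoRun:
    """Run the analysis split across capture sessions.

    ``single`` runs everything in one session (1 RDF file).
    ``two_process`` emulates a two-rank parallel run: one session per
    subject, with the in-memory PSD summaries of the second session
    plotted by the first (2 RDF files; the graphs connect through equal
    object content hashes).
    ``two_stage`` emulates a multi-script workflow: one compute session
    per subject writing intermediate files, plus one plot session reading
    them (3 RDF files; the graphs connect through equal file hashes).
    """
    config = config or DemoConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    plot_path = str(output_dir / f"split_{mode}.png")
    _configure_hashing()

    if mode == "single":
        run = run_demo_pipeline(recording_paths, config, output_dir,
                                name="split_single")
        return run

    if mode == "two_process":
        # "rank 1": compute the PSD summaries of the second subject
        ttl_rank1 = str(output_dir / "split_two_process_rank1.ttl")
        activate()
        try:
            block = load_data(str(recording_paths[1]))
            remote_summaries = _analyze_trial_types(block, config, None)
            save_provenance(ttl_rank1)
        finally:
            deactivate()
        # "rank 0": compute the first subject, then plot both
        ttl_rank0 = str(output_dir / "split_two_process_rank0.ttl")
        activate()
        try:
            figure = create_plot()
            block = load_data(str(recording_paths[0]))
            _analyze_trial_types(block, config, figure)
            for trial_type in config.trial_types:
                figure = plot_psd(figure, remote_summaries["freqs"],
                                  remote_summaries[f"{trial_type}_mean"],
                                  remote_summaries[f"{trial_type}_sem"],
                                  label=f"remote {trial_type}")
            save_plot(figure, plot_path)
            save_provenance(ttl_rank0)
        finally:
            deactivate()
        return DemoRun(plot_path=plot_path,
                       provenance_paths=[ttl_rank0, ttl_rank1])

    if mode == "two_stage":
        ttl_paths = []
        intermediate_paths = []
        for index, file_path in enumerate(recording_paths):
            ttl = str(output_dir / f"split_two_stage_compute{index}.ttl")
            intermediate = str(output_dir / f"psd_summaries_{index}.npz")
            activate()
            try:
                block = load_data(str(file_path))
                summaries = _analyze_trial_types(block, config, None)
                save_psd_data(summaries, intermediate)
                save_provenance(ttl)
            finally:
                deactivate()
            ttl_paths.append(ttl)
            intermediate_paths.append(intermediate)

        ttl_plot = str(output_dir / "split_two_stage_plot.ttl")
        activate()
        try:
            figure = create_plot()
            for index, intermediate in enumerate(intermediate_paths):
                summaries = load_psd_data(intermediate)
                for trial_type in config.trial_types:
                    figure = plot_psd(figure, summaries["freqs"],
                                      summaries[f"{trial_type}_mean"],
                                      summaries[f"{trial_type}_sem"],
                                      label=f"subject{index} {trial_type}")
            save_plot(figure, plot_path)
            save_provenance(ttl_plot)
        finally:
            deactivate()
        ttl_paths.append(ttl_plot)
        return DemoRun(plot_path=plot_path, provenance_paths=ttl_paths)

    raise ValueError(f"unknown mode {mode!r}; "
                     "expected single, two_process or two_stage")
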