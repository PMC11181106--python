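import shutil

import pytest

import provtrace
from provtrace.demo import DemoConfig, make_recording_files
from provtrace.demo.pipeline import run_demo_pipeline, run_split_pipeline
from provtrace.settings import CaptureSettings, _default_annotation_plugin


@pytest.fixture(autouse=True)
def clean_capture_state():
    """Reset global settings and tear down any session left by a test."""
    settings = provtrace.get_settings()
    settings.authority = "my-authority"
    settings.builtin_hash_packages = set()
    settings.metadata_plugins = {"": _default_annotation_plugin}
    provtrace.deactivate()
    yield
    provtrace.deactivate()
    settings.authority = "my-authority"
    settings.builtin_hash_packages = set()
    settings.metadata_plugins = {"": _default_annotation_plugin}


@pytest.fixture(scope="session")
def demo_config():
    """Scaled-down study conditions: full temporal structure (30 kHz,
    500 ms epochs, downsample 60, 2 Hz Welch resolution), few channels."""
    return DemoConfig(channels=4, trials_per_type=2,
                      exclude_channels=("chan 2",))


@pytest.fixture(scope="session")
def demo_artifacts(tmp_path_factory, demo_config):
    """One tracked demo-pipeline run on a single synthetic subject."""
    directory = tmp_path_factory.mktemp("demo_run")
    paths = make_recording_files(directory, subjects=["subject-A"],
                                 config=demo_config, seed=11)
    with provtrace.deterministic_ids(11):
        run = run_demo_pipeline(paths, demo_config, output_dir=directory)
    return {"recordings": paths, "run": run, "config": demo_config,
            "dir": directory}


@pytest.fixture(scope="session")
def split_artifacts(tmp_path_factory, demo_config):
    """Single-session and split (two-stage, two-process) runs over two
    synthetic subjects, for merge-connectivity checks."""
    directory = tmp_path_factory.mktemp("split_runs")
    paths = make_recording_files(directory, config=demo_config, seed=23)
    runs = {}
    for mode in ("single", "two_stage", "two_process"):
        runs[mode] = run_split_pipeline(
            paths, mode=mode, config=demo_config,
            output_dir=directory / mode)
    return {"recordings": paths, "runs": runs, "config": demo_config}
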