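import numpy as np
import pytest

from qeegrecovery import synthgen
from qeegrecovery.pipeline import PipelineConfig, run_detection_cohort


@pytest.fixture(scope="session")
def study_config() -> synthgen.GeneratorConfig:
    """Study-scale cohort at the reduced desk rate (20 per arm, 250 Hz)."""
    return synthgen.GeneratorConfig(n_per_group=20, fs=250.0, seed=1)


@pytest.fixture(scope="session")
def cohort_detection(study_config):
    """Planted-vs-detected table for the full two-arm cohort.

    Session-scoped: this is the expensive end-to-end run (forty 4-h
    recordings through the whole pipeline) shared by the planted-truth and
    acceptance checks.
    """
    return run_detection_cohort(study_config)


@pytest.fixture()
def tiny_pipeline_config() -> PipelineConfig:
    """One animal per arm, short recording: fast end-to-end runs."""
    gen = synthgen.GeneratorConfig(n_per_group=1, fs=250.0, duration_min=50.0,
                                   seed=7)
    return PipelineConfig(generator=gen, seed=7, n_bootstrap=100)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
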