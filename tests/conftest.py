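"""Shared fixtures: simulated datasets and full pipeline runs.

The heavyweight pipeline runs (simulate -> gamma-correct -> HMM -> dwells)
are session-scoped and shared between unit tests and acceptance tests.
All randomness is seeded; hypothesis runs derandomized.
"""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import telofret as tf
from telofret.pipeline import dwell_fits, idealize_dataset

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

#: Master seed for every session fixture, fixed a priori.
SEED = 1

#: Dataset scale: >= 150 binding events with stable dwell statistics.
N_TRACES_U36 = 300
N_TRACES_U63 = 160
N_FRAMES = 800


def run_pipeline(preset: str, scheme: str, n_traces: int, seed: int = SEED):
    model = tf.KINETIC_PRESETS[preset]
    traces = tf.simulate_dataset(model, n_traces, N_FRAMES, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return idealize_dataset(traces, scheme=scheme)


@pytest.fixture(scope="session")
def wt_u36_run():
    return run_pipeline("wt-u36", "u36", N_TRACES_U36)


@pytest.fixture(scope="session")
def l14a_u36_run():
    return run_pipeline("l14a-u36", "u36", N_TRACES_U36)


@pytest.fixture(scope="session")
def wt_u63_run():
    return run_pipeline("wt-u63", "u63", N_TRACES_U63)


@pytest.fixture(scope="session")
def l14a_u63_run():
    return run_pipeline("l14a-u63", "u63", N_TRACES_U63)


@pytest.fixture(scope="session")
def wt_u36_fits(wt_u36_run):
    return dwell_fits(wt_u36_run)


@pytest.fixture(scope="session")
def l14a_u36_fits(l14a_u36_run):
    return dwell_fits(l14a_u36_run)


@pytest.fixture(scope="session")
def wt_u36_traces():
    """Raw simulated traces (with ground truth) for the wild-type preset."""
    return tf.simulate_dataset(tf.KINETIC_PRESETS["wt-u36"], 200, N_FRAMES, SEED)


@pytest.fixture(scope="session")
def small_traces():
    """A small, fast dataset for I/O and CLI tests."""
    return tf.simulate_dataset(tf.KINETIC_PRESETS["l14a-u36"], 12, 300, SEED)
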