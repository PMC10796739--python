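"""Shared fixtures: simulated cohorts at several scales.

All cohorts are generated at test time by the simulator; the expensive
fixtures (full-size LOSO runs over several seeds) are session-scoped so
the detection-quality and downstream checks share them.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pytest

from gdmwear.config import PipelineConfig
from gdmwear.downstream import run_downstream
from gdmwear.evaluation import run_loso
from gdmwear.pipeline import simulate_and_window

logging.getLogger("gdmwear").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size cohort (20 stroke + 10 control), windowed."""
    cfg = PipelineConfig()
    subjects, kinematics, window_sets = simulate_and_window(cfg, seed=0)
    return cfg, subjects, kinematics, window_sets


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast integration tests."""
    cfg = PipelineConfig(n_stroke=6, n_control=4, session_s=60.0, seed=0)
    subjects, kinematics, window_sets = simulate_and_window(cfg, seed=0)
    return cfg, subjects, kinematics, window_sets


@pytest.fixture(scope="session")
def small_loso(small_cohort):
    """LOSO + downstream on the reduced cohort."""
    cfg, subjects, kinematics, window_sets = small_cohort
    loso = run_loso(subjects, window_sets, seed=0, fs=cfg.fs_target)
    downstream = run_downstream(
        subjects, kinematics, window_sets, loso.predictions, seed=0, fs=cfg.fs_target
    )
    return cfg, subjects, kinematics, window_sets, loso, downstream


@pytest.fixture(scope="session")
def loso_runs():
    """Full default-cohort LOSO + downstream runs over five seeds."""
    cfg = PipelineConfig()
    runs = []
    for seed in range(5):
        subjects, kinematics, window_sets = simulate_and_window(cfg, seed=seed)
        loso = run_loso(subjects, window_sets, seed=seed, fs=cfg.fs_target)
        downstream = run_downstream(
            subjects, kinematics, window_sets, loso.predictions,
            seed=seed, fs=cfg.fs_target,
        )
        runs.append({
            "seed": seed, "subjects": subjects, "loso": loso,
            "downstream": downstream,
        })
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
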