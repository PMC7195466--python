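"""Shared fixtures: the calibrated landscape and one full study run.

The full loading study is expensive (about two minutes), so a single
session-scoped run at the default configuration is shared by every test
that inspects the pipeline's output.
"""

import numpy as np
import pytest

import loadpath as lp


@pytest.fixture(scope="session")
def landscape():
    return lp.make_ga2ox_mimetic_landscape()


@pytest.fixture(scope="session")
def analytic_pmf(landscape):
    """The fixture landscape evaluated exactly on the default 60x60 grid."""
    grid = lp.GridSpec(origin=(-3.0, -3.0), spacing=(0.1, 0.1), shape=(60, 60))
    return lp.grid_from_potential(landscape, grid, kT=lp.kt_at(300.0))


@pytest.fixture(scope="session")
def study_report():
    """One full default-configuration loading study (seed 2020)."""
    return lp.run_loading_study(lp.StudyConfig(seed=2020))


@pytest.fixture(scope="session")
def small_reus(landscape):
    """A short 8-window REUS run for estimator and exchange tests."""
    path = lp.init_guiding_path(n=8, radius=2.0, active_index=4, interface_index=0)
    windows = lp.build_windows(path, k=0.48)
    samples = lp.run_reus(
        landscape,
        windows,
        kT=lp.kt_at(300.0),
        dt=2.5e-4,
        friction=0.05,
        n_steps=20000,
        stride=10,
        exchange_interval=100,
        equil_steps=2000,
        seed=11,
    )
    return windows, samples
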