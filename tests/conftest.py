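"""Shared fixtures: model configurations at two resolutions and cached
case-study trajectories (session-scoped; several tests reuse them)."""

import numpy as np
import pytest

import enzfilm as ez


@pytest.fixture(scope="session")
def case_config():
    """Reference thin-film configuration: L=0.25 mm, N=25, BDF at the
    printed tolerances."""
    return ez.case_study_config()


@pytest.fixture(scope="session")
def coarse_config():
    """Coarse, fast configuration for sampling-heavy tests: 7 nodes, LSODA
    fast path, relaxed step cap (accuracy still set by rtol/atol)."""
    return ez.case_study_config(N=7, method="LSODA", max_step=4.0)


@pytest.fixture(scope="session")
def calibrated_theta(case_config):
    return ez.config_to_theta(case_config)


@pytest.fixture(scope="session")
def case_trajectory(case_config):
    cfg = case_config
    return ez.simulate(cfg.kinetics, cfg.transport, cfg.geometry,
                       cfg.initial, cfg.solver)


@pytest.fixture(scope="session")
def dense_trajectory(case_config):
    """Case-study run with half-hourly outputs (for balance diagnostics)."""
    cfg = case_config.replace(solver=ez.SolverSettings(
        t_end=72.0, output_times=tuple(np.arange(0.0, 72.5, 0.5))))
    return ez.simulate(cfg.kinetics, cfg.transport, cfg.geometry,
                       cfg.initial, cfg.solver)


@pytest.fixture(scope="session")
def noise_free_dataset(coarse_config):
    """Noise-free observations at the case-study times, sigma = 2%."""
    t = np.asarray(ez.CASE_STUDY_TIMES)
    wl, xc = ez.model_curves(coarse_config, t, t)
    return ez.DegradationDataset(t, wl, np.full(len(t), 2.0),
                                 t, xc, np.full(len(t), 2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_state(rng, N=9):
    """A physically plausible random state field for property tests."""
    C = rng.uniform(0, 0.4, N)
    A = rng.uniform(0, 0.6, N)
    EC = rng.uniform(0, 0.2, N)
    EA = rng.uniform(0, 0.2, N)
    P = np.clip(1.0 - C - A - EC - EA, 0.0, None)
    E = rng.uniform(0, 1, N)
    return ez.StateField(E=E, C=C, A=A, EC=EC, EA=EA, P=P)
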