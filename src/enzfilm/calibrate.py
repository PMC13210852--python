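"""Joint weighted least-squares calibration of the eight-parameter vector
theta = (k1, k_m1, k3, k_m3, k_conv, k_deg_C, k_deg_A, De0).

The objective is the raw sum of sigma-weighted squared residuals over both
observed series (weight loss and crystallinity), which places the two
datasets on a common dimensionless scale.  The search runs in log10(theta)
space -- the feasible box spans many orders of magnitude -- with a seeded
Latin-hypercube pre-search followed by bound-constrained local least squares
from the most promising starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .config import ModelConfig
from .data import DegradationDataset, model_curves
from .model import (KineticParameters, SimulationError, TransportParameters)

__all__ = ["PARAM_NAMES", "FeasibleBox", "FitResult", "FitError",
           "theta_to_config", "config_to_theta", "objective",
           "weighted_residuals", "fit", "FAILURE_PENALTY"]

PARAM_NAMES = ("k1", "k_m1", "k3", "k_m3", "k_conv", "k_deg_C", "k_deg_A", "De0")

#: loss returned when the forward simulation fails at a parameter point; large
#: enough that any successfully simulated point is preferred, finite so the
#: optimiser can still rank failed probes.
FAILURE_PENALTY = 1e12


class FitError(RuntimeError):
    """All optimisation starts failed."""


@dataclass(frozen=True)
class FeasibleBox:
    """Per-parameter [min, max] bounds; min > 0 so a log-uniform prior over
    the box is proper.  Defaults: rates in [1e-6, 50] 1/h, De0 in [1e-12, 50]."""

    lo: np.ndarray = field(default_factory=lambda: np.array(
        [1e-6] * 7 + [1e-12]))
    hi: np.ndarray = field(default_factory=lambda: np.array([50.0] * 8))

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if lo.shape != (8,) or hi.shape != (8,):
            raise ValueError("bounds must be length-8 vectors")
        if np.any(lo <= 0) or np.any(lo >= hi):
            raise ValueError("bounds require 0 < min < max per parameter")

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lo) and np.all(theta <= self.hi))

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lo, self.hi)

    @property
    def log_lo(self) -> np.ndarray:
        return np.log10(self.lo)

    @property
    def log_hi(self) -> np.ndarray:
        return np.log10(self.hi)


def theta_to_config(theta, base: ModelConfig) -> ModelConfig:
    """Substitute the 8-vector theta into a model configuration."""
    theta = np.asarray(theta, dtype=float)
    kin = KineticParameters(*theta[:7])
    transport = TransportParameters(De0=float(theta[7]),
                                    alpha_e=base.transport.alpha_e)
    return base.replace(kinetics=kin, transport=transport)


def config_to_theta(config: ModelConfig) -> np.ndarray:
    k = config.kinetics
    return np.array([k.k1, k.k_m1, k.k3, k.k_m3, k.k_conv, k.k_deg_C,
                     k.k_deg_A, config.transport.De0])


def weighted_residuals(theta, data: DegradationDataset,
                       config: ModelConfig) -> np.ndarray:
    """Sigma-weighted residual vector (model - data) over both series."""
    cfg = theta_to_config(theta, config)
    wl_hat, xc_hat = model_curves(cfg, data.wl_times, data.xc_times)
    return np.concatenate([
        (wl_hat - data.wl_values) / data.wl_sd,
        (xc_hat - data.xc_values) / data.xc_sd,
    ])


def objective(theta, data: DegradationDataset, config: ModelConfig) -> float:
    """Weighted least-squares loss; FAILURE_PENALTY if simulation fails."""
    try:
        r = weighted_residuals(theta, data, config)
    except (SimulationError, ValueError):
        return FAILURE_PENALTY
    return float(np.dot(r, r))


@dataclass
class FitResult:
    theta: np.ndarray
    loss: float
    r2_wl: float
    r2_xc: float
    residuals_wl: np.ndarray
    residuals_xc: np.ndarray
    n_starts: int
    seed: int | None
    converged: bool
    start_losses: list = field(default_factory=list)

    def params(self) -> dict:
        return dict(zip(PARAM_NAMES, (float(v) for v in self.theta)))


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination on the raw (unweighted) values."""
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit(data: DegradationDataset, box: FeasibleBox, config: ModelConfig,
        n_starts: int = 16, n_local: int = 3, seed: int | None = 0,
        theta0=None, max_nfev: int = 500, diff_step: float = 0.01) -> FitResult:
    """Global-then-local minimisation of the weighted least-squares objective.

    A seeded Latin-hypercube probe of ``n_starts`` points in log10 space
    (optionally augmented with a user start ``theta0``) ranks candidate
    starts by objective value; local bound-constrained least squares (TRF) is
    run from the best ``n_local`` and the overall best solution returned.

    ``diff_step`` is the finite-difference step (in log10 space) for the
    Jacobian; it must stay well above the forward solver's noise floor or
    the optimiser sees a spurious gradient and stalls.
    """
    if data.n == 0:
        raise FitError("dataset has no weight-loss observations")

    starts = []
    if theta0 is not None:
        theta0 = box.clip(theta0)
        starts.append(np.log10(theta0))
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=8, seed=seed)
        u = sampler.random(n_starts)
        lhs = box.log_lo + u * (box.log_hi - box.log_lo)
        starts.extend(lhs)
    if not starts:
        raise FitError("no starting points (n_starts=0 and no theta0)")

    probe = [(objective(10.0 ** s, data, config), s) for s in starts]
    probe.sort(key=lambda p: p[0])
    start_losses = [p[0] for p in probe]
    if start_losses[0] >= FAILURE_PENALTY:
        raise FitError("forward simulation failed at every starting point")

    def res_log(u):
        try:
            return weighted_residuals(10.0 ** u, data, config)
        except (SimulationError, ValueError):
            # finite, huge residuals keep TRF inside the feasible region
            return np.full(data.n + data.m, np.sqrt(FAILURE_PENALTY / (data.n + data.m)))

    best = None
    for loss0, u0 in probe[:max(1, n_local)]:
        try:
            sol = least_squares(res_log, u0, bounds=(box.log_lo, box.log_hi),
                                method="trf", max_nfev=max_nfev,
                                diff_step=diff_step, x_scale="jac",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        cand = (float(2 * sol.cost), sol)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise FitError("all local optimisations failed")

    loss, sol = best
    # keep the raw probe winner if a local run somehow ended worse
    if loss > start_losses[0]:
        theta_hat = 10.0 ** probe[0][1]
        loss = start_losses[0]
        converged = False
    else:
        theta_hat = 10.0 ** sol.x
        converged = bool(sol.success)

    cfg_hat = theta_to_config(theta_hat, config)
    wl_hat, xc_hat = model_curves(cfg_hat, data.wl_times, data.xc_times)
    return FitResult(
        theta=theta_hat, loss=loss,
        r2_wl=_r2(data.wl_values, wl_hat),
        r2_xc=_r2(data.xc_values, xc_hat) if data.m else float("nan"),
        residuals_wl=wl_hat - data.wl_values,
        residuals_xc=xc_hat - data.xc_values,
        n_starts=len(starts), seed=seed, converged=converged,
        start_losses=start_losses[:10],
    )
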