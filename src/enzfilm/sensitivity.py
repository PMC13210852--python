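"""Variance-based (Sobol) global sensitivity analysis of the mass-loss output.

First-order indices S_i measure each parameter's independent share of the
output variance; total-order indices ST_i add all interaction contributions.
Estimation uses Saltelli's paired-matrix design (quasi-random Sobol' points,
n_base * (d + 2) model evaluations) with the Saltelli-2010 first-order
estimator and the Jansen total-order estimator; confidence half-widths come
from a seeded bootstrap over base samples.

Parameter ranges for the degradation model default to [0.5x, 2x] the
calibrated values, sampled uniformly in log10 space; the full feasible box of
the calibration module is available as an alternative preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .calibrate import FeasibleBox, PARAM_NAMES, config_to_theta, theta_to_config
from .config import ModelConfig
from .data import model_curves
from .model import SimulationError

__all__ = ["SobolDesign", "SobolResult", "sobol_indices",
           "time_dependent_indices", "calibrated_ranges", "box_ranges"]


@dataclass(frozen=True)
class SobolDesign:
    """Sampling design: ``n_base`` base points (a power of two for the
    quasi-random Sobol' sequence), per-parameter [lo, hi] ranges, and the
    sampling scale (log10-uniform by default)."""

    n_base: int = 1024
    ranges: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    log_scale: bool = True
    seed: int = 0
    n_bootstrap: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", np.asarray(self.ranges, dtype=float))
        if self.n_base < 2 or (self.n_base & (self.n_base - 1)):
            raise ValueError("n_base must be a power of two >= 2")
        if self.ranges.ndim != 2 or self.ranges.shape[1] != 2:
            raise ValueError("ranges must be a (d, 2) array")
        if np.any(self.ranges[:, 0] >= self.ranges[:, 1]):
            raise ValueError("each range must satisfy lo < hi")
        if self.log_scale and np.any(self.ranges <= 0):
            raise ValueError("log-scale sampling requires positive ranges")

    @property
    def d(self) -> int:
        return self.ranges.shape[0]

    def map_unit(self, u: np.ndarray) -> np.ndarray:
        """Map unit-hypercube samples onto the parameter ranges."""
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        if self.log_scale:
            llo, lhi = np.log10(lo), np.log10(hi)
            return 10.0 ** (llo + u * (lhi - llo))
        return lo + u * (hi - lo)


def calibrated_ranges(config: ModelConfig, factor: float = 2.0) -> np.ndarray:
    """Default SA ranges: [value/factor, value*factor] around the calibrated
    parameter vector of ``config``."""
    theta = config_to_theta(config)
    return np.column_stack([theta / factor, theta * factor])


def box_ranges(box: FeasibleBox | None = None) -> np.ndarray:
    """Alternative preset: the full feasible calibration box."""
    box = box or FeasibleBox()
    return np.column_stack([box.lo, box.hi])


@dataclass
class SobolResult:
    times: np.ndarray            # evaluation grid (h); [0] for scalar outputs
    S1: np.ndarray               # (n_times, d)
    ST: np.ndarray               # (n_times, d)
    S1_conf: np.ndarray
    ST_conf: np.ndarray
    variance: np.ndarray         # total output variance D(t)
    mean: np.ndarray             # output mean f0(t)
    undefined: np.ndarray        # bool mask: zero-variance time points
    param_names: tuple
    n_base: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times):
            for j, name in enumerate(self.param_names):
                rows.append((t, name, self.S1[k, j], self.ST[k, j],
                             self.S1_conf[k, j], self.ST_conf[k, j]))
        return pd.DataFrame(rows, columns=["time_h", "parameter", "S1", "ST",
                                           "S1_conf", "ST_conf"])


def _saltelli_matrices(design: SobolDesign):
    """A, B and the d cross matrices AB_i, on the unit hypercube."""
    sob = qmc.Sobol(d=2 * design.d, scramble=True, seed=design.seed)
    base = sob.random(design.n_base)
    A = base[:, :design.d]
    B = base[:, design.d:]
    ABs = []
    for i in range(design.d):
        AB = A.copy()
        AB[:, i] = B[:, i]
        ABs.append(AB)
    return A, B, ABs


def _estimate(fA, fB, fABs):
    """Saltelli-2010 S1 and Jansen ST estimators for one output column.

    ``fA``/``fB``: (n,), ``fABs``: list of d arrays (n,).  Returns
    (S1, ST, D, f0, undefined)."""
    allf = np.concatenate([fA, fB])
    f0 = allf.mean()
    D = allf.var()
    d = len(fABs)
    S1 = np.full(d, np.nan)
    ST = np.full(d, np.nan)
    if D <= 0:
        return S1, ST, D, f0, True
    for i, fAB in enumerate(fABs):
        S1[i] = np.mean(fB * (fAB - fA)) / D
        ST[i] = 0.5 * np.mean((fA - fAB) ** 2) / D
    return S1, ST, D, f0, False


def sobol_indices(func, design: SobolDesign) -> SobolResult:
    """Estimate time-resolved first/total-order indices of ``func``.

    ``func`` maps an (n, d) matrix of parameter vectors to an (n,) vector or
    (n, n_times) matrix of outputs; rows that fail may be returned as NaN and
    are excluded pairwise (the same base sample is dropped from every
    matrix), with the dropped count reported.
    """
    A, B, ABs = _saltelli_matrices(design)
    XA, XB = design.map_unit(A), design.map_unit(B)
    fA = np.asarray(func(XA), dtype=float)
    if fA.ndim == 1:
        fA = fA[:, None]
    n_t = fA.shape[1]
    fB = np.asarray(func(XB), dtype=float).reshape(design.n_base, n_t)
    fABs = [np.asarray(func(design.map_unit(AB)), dtype=float)
            .reshape(design.n_base, n_t) for AB in ABs]

    ok = np.isfinite(fA).all(axis=1) & np.isfinite(fB).all(axis=1)
    for f in fABs:
        ok &= np.isfinite(f).all(axis=1)
    n_failed = int((~ok).sum())
    fA, fB = fA[ok], fB[ok]
    fABs = [f[ok] for f in fABs]
    n = fA.shape[0]
    if n < 8:
        raise SimulationError("too few successful Sobol evaluations")

    d = design.d
    S1 = np.empty((n_t, d)); ST = np.empty((n_t, d))
    S1c = np.empty((n_t, d)); STc = np.empty((n_t, d))
    Dv = np.empty(n_t); f0 = np.empty(n_t)
    undef = np.zeros(n_t, dtype=bool)
    rng = np.random.default_rng(design.seed + 1)
    boot_ix = rng.integers(0, n, size=(design.n_bootstrap, n))
    for k in range(n_t):
        S1[k], ST[k], Dv[k], f0[k], undef[k] = _estimate(
            fA[:, k], fB[:, k], [f[:, k] for f in fABs])
        if undef[k] or design.n_bootstrap == 0:
            S1c[k] = STc[k] = np.nan
            continue
        bs1 = np.empty((design.n_bootstrap, d))
        bst = np.empty((design.n_bootstrap, d))
        for b, ix in enumerate(boot_ix):
            bs1[b], bst[b], *_ = _estimate(
                fA[ix, k], fB[ix, k], [f[ix, k] for f in fABs])
        S1c[k] = 1.96 * bs1.std(axis=0)
        STc[k] = 1.96 * bst.std(axis=0)

    names = tuple(PARAM_NAMES[:d]) if d <= len(PARAM_NAMES) else \
        tuple(f"x{i+1}" for i in range(d))
    return SobolResult(times=np.arange(n_t, dtype=float), S1=S1, ST=ST,
                       S1_conf=S1c, ST_conf=STc, variance=Dv, mean=f0,
                       undefined=undef, param_names=names,
                       n_base=design.n_base, n_failed=n_failed)


def time_dependent_indices(config: ModelConfig, design: SobolDesign,
                           L: float | None = None,
                           times=None, convention: str = "product",
                           output: str = "weight_loss") -> SobolResult:
    """Time-dependent Sobol indices of the mass-loss output.

    Runs the forward model once per design row (at half-thickness ``L`` if
    given, else the config geometry) and estimates indices of the weight-loss
    value at each time on the grid (defaulting to the config output times,
    excluding t = 0 where the output has no variance).
    """
    from .model import Geometry, grid_points_for

    if L is not None:
        config = config.replace(geometry=Geometry(L=L, N=grid_points_for(
            L, config.geometry.dx)))
    if times is None:
        times = [t for t in config.solver.resolved_output_times() if t > 0]
    times = np.asarray(times, dtype=float)

    def func(X):
        out = np.full((X.shape[0], len(times)), np.nan)
        for r, theta in enumerate(X):
            try:
                cfg = theta_to_config(theta, config)
                wl, xc = model_curves(cfg, times, [], convention=convention)
                out[r] = wl if output == "weight_loss" else xc
            except (SimulationError, ValueError):
                pass
        return out

    res = sobol_indices(func, design)
    res.times = times
    return res
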