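"""Degradation datasets: strict CSV I/O and a seeded synthetic generator.

A dataset holds two observed series -- percent weight loss and percent bulk
crystallinity -- each with per-point measurement standard deviations, as a
delimited table with columns ``observable,time_h,value_pct,sd_pct``.

The synthetic generator emulates the structure of thin-film enzymolysis
experiments (observations over 0-72 h, weight loss rising from 0 toward a
plateau, crystallinity declining from 30.2%) by running the forward model at
the generating parameters and adding independent Gaussian measurement noise,
truncated to the physical [0, 100]% range by resampling (clipping would bias
the noise scale).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (CASE_STUDY_TIMES, ModelConfig, case_study_config)
from .model import SolverSettings, simulate
from .observables import observable_series

__all__ = ["DegradationDataset", "SyntheticSpec", "DatasetError",
           "load_dataset", "write_dataset", "generate_synthetic",
           "case_study_template", "model_curves"]

_OBSERVABLES = ("weight_loss", "crystallinity")


class DatasetError(ValueError):
    """Malformed dataset file or invalid series."""


@dataclass
class DegradationDataset:
    """Observed weight-loss and crystallinity series with their sigmas (%)."""

    wl_times: np.ndarray
    wl_values: np.ndarray
    wl_sd: np.ndarray
    xc_times: np.ndarray
    xc_values: np.ndarray
    xc_sd: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("wl_times", "wl_values", "wl_sd",
                     "xc_times", "xc_values", "xc_sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for prefix in ("wl", "xc"):
            t = getattr(self, f"{prefix}_times")
            v = getattr(self, f"{prefix}_values")
            s = getattr(self, f"{prefix}_sd")
            if not (len(t) == len(v) == len(s)):
                raise DatasetError(f"{prefix} series lengths disagree")
            if len(t) and t.min() < 0:
                raise DatasetError(f"{prefix} series has negative times")
            if len(np.unique(t)) != len(t):
                raise DatasetError(f"duplicate observation times in {prefix} series")
            if len(s) and s.min() <= 0:
                raise DatasetError(f"non-positive sd in {prefix} series")

    @property
    def n(self) -> int:
        return len(self.wl_times)

    @property
    def m(self) -> int:
        return len(self.xc_times)

    @property
    def wl_only(self) -> bool:
        """True when no crystallinity data are present (single-objective fit)."""
        return self.m == 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, v, s in zip(self.wl_times, self.wl_values, self.wl_sd):
            rows.append(("weight_loss", t, v, s))
        for t, v, s in zip(self.xc_times, self.xc_values, self.xc_sd):
            rows.append(("crystallinity", t, v, s))
        return pd.DataFrame(rows, columns=["observable", "time_h",
                                           "value_pct", "sd_pct"])


def load_dataset(path) -> DegradationDataset:
    """Strict parse of a ``observable,time_h,value_pct,sd_pct`` CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise DatasetError(f"cannot read {path}: {exc}") from exc
    required = ["observable", "time_h", "value_pct", "sd_pct"]
    if list(df.columns) != required:
        raise DatasetError(
            f"expected columns {required}, found {list(df.columns)}")
    if df.isna().any().any():
        raise DatasetError("missing values in dataset (sigma is required)")
    bad = set(df["observable"]) - set(_OBSERVABLES)
    if bad:
        raise DatasetError(f"unknown observable(s): {sorted(bad)}")
    for col in ("time_h", "value_pct", "sd_pct"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise DatasetError(f"non-numeric values in column {col}")
    wl = df[df["observable"] == "weight_loss"].sort_values("time_h")
    xc = df[df["observable"] == "crystallinity"].sort_values("time_h")
    if len(wl) == 0:
        raise DatasetError("dataset has no weight_loss rows")
    return DegradationDataset(
        wl_times=wl["time_h"], wl_values=wl["value_pct"], wl_sd=wl["sd_pct"],
        xc_times=xc["time_h"], xc_values=xc["value_pct"], xc_sd=xc["sd_pct"],
        provenance={"path": str(path)},
    )


def write_dataset(ds: DegradationDataset, path) -> None:
    df = ds.to_frame().copy()
    # stable order: observable block, then time
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# synthetic generation
# --------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Generating configuration for a synthetic dataset.

    ``wl_sd`` / ``xc_sd`` may be scalars (same sigma everywhere, %) or
    per-time vectors.  The seed is recorded in the dataset provenance.
    """

    config: ModelConfig
    wl_times: tuple = CASE_STUDY_TIMES
    xc_times: tuple = CASE_STUDY_TIMES
    wl_sd: float | tuple = 2.0
    xc_sd: float | tuple = 2.0
    seed: int = 0

    def sd_arrays(self):
        wl_sd = np.broadcast_to(np.asarray(self.wl_sd, dtype=float),
                                (len(self.wl_times),)).copy()
        xc_sd = np.broadcast_to(np.asarray(self.xc_sd, dtype=float),
                                (len(self.xc_times),)).copy()
        if (len(wl_sd) and wl_sd.min() <= 0) or (len(xc_sd) and xc_sd.min() <= 0):
            raise DatasetError("noise standard deviations must be > 0")
        return wl_sd, xc_sd


def case_study_template(seed: int = 0, N: int | None = None,
                        method: str = "BDF") -> SyntheticSpec:
    """Default spec mirroring the thin-film case study: half-thickness
    0.25 mm, C0 = 0.302, 72 h horizon, observations at the named measurement
    times, 2% Gaussian noise on both observables."""
    return SyntheticSpec(config=case_study_config(N=N, method=method),
                         seed=seed)


def model_curves(config: ModelConfig, wl_times, xc_times,
                 convention: str = "product"):
    """Noise-free model observables at the requested times.

    Returns ``(wl_values, xc_values)`` in percent.  Used by the generator and
    by the calibration/inference objective functions.
    """
    all_times = np.unique(np.concatenate([np.asarray(wl_times, dtype=float),
                                          np.asarray(xc_times, dtype=float)]))
    settings = SolverSettings(
        t_end=max(float(all_times[-1]), 1e-9) if all_times.size else 1.0,
        output_times=tuple(all_times),
        rtol=config.solver.rtol, atol=config.solver.atol,
        max_step=config.solver.max_step, method=config.solver.method)
    traj = simulate(config.kinetics, config.transport, config.geometry,
                    config.initial, settings)
    series = observable_series(traj, config.geometry, config.initial,
                               convention=convention)
    wl = np.interp(np.asarray(wl_times, dtype=float), series.times,
                   series.weight_loss_pct)
    xc = np.interp(np.asarray(xc_times, dtype=float), series.times,
                   series.crystallinity_pct)
    return wl, xc


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray,
                      sd: np.ndarray, lo=0.0, hi=100.0,
                      max_tries: int = 1000) -> np.ndarray:
    """Gaussian draws truncated to [lo, hi] by resampling out-of-range points."""
    out = rng.normal(mean, sd)
    for _ in range(max_tries):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean[bad], sd[bad])
    raise DatasetError("truncated-normal resampling did not converge; "
                       "noise sd is implausibly large for the [0,100]% range")


def generate_synthetic(spec: SyntheticSpec,
                       convention: str = "product") -> DegradationDataset:
    """Simulate the forward model at the spec parameters and sample noisy
    observations; deterministic given the spec seed."""
    wl_sd, xc_sd = spec.sd_arrays()
    wl_mu, xc_mu = model_curves(spec.config, spec.wl_times, spec.xc_times,
                                convention=convention)
    rng = np.random.default_rng(spec.seed)
    wl_obs = _truncated_normal(rng, wl_mu, wl_sd)
    xc_obs = _truncated_normal(rng, xc_mu, xc_sd)
    return DegradationDataset(
        wl_times=np.asarray(spec.wl_times, dtype=float), wl_values=wl_obs,
        wl_sd=wl_sd,
        xc_times=np.asarray(spec.xc_times, dtype=float), xc_values=xc_obs,
        xc_sd=xc_sd,
        provenance={"generator": "enzfilm.generate_synthetic",
                    "seed": spec.seed, "convention": convention,
                    "truth_wl": wl_mu.tolist(), "truth_xc": xc_mu.tolist()},
    )
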