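"""Measurable quantities and regime metrics derived from a trajectory.

Two observables are fitted to experiments: percent weight loss and percent
bulk crystallinity.  Crystallinity counts only the uncomplexed polymer states
C and A, because enzyme, complexes and soluble products are washed out before
a DSC measurement.  The weight-loss convention is configurable (see
:func:`weight_loss_percent`): the default counts cumulative soluble-product
formation, i.e. residual film mass still includes polymer bound in enzyme
complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (Geometry, InitialComposition, KineticParameters,
                    StateField, Trajectory, TransportParameters)

__all__ = [
    "ObservableSeries",
    "RegimeMetrics",
    "FullyDegradedError",
    "bulk_crystallinity",
    "local_crystallinity",
    "weight_loss_percent",
    "damkohler",
    "observable_series",
]

#: denominators below this are treated as a fully degraded film
_DEGRADED_EPS = 1e-12


class FullyDegradedError(ValueError):
    """Crystallinity is undefined once no polymer remains."""


@dataclass
class RegimeMetrics:
    """Damkoehler numbers ``Da = k_deg * L^2 / De0`` for the amorphous and
    crystalline pathways and the diffusion timescale ``tau_diff = L^2 / De0``
    (h) of the half-thickness L."""

    Da_A: float
    Da_C: float
    tau_diff: float


@dataclass
class ObservableSeries:
    times: np.ndarray
    weight_loss_pct: np.ndarray
    crystallinity_pct: np.ndarray
    #: optional (n_times, N) local-crystallinity and porosity profiles (%)
    chi_local_pct: np.ndarray | None = None
    porosity: np.ndarray | None = None
    xi: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            "weight_loss_pct": self.weight_loss_pct,
            "crystallinity_pct": self.crystallinity_pct,
        })

    def profiles_frame(self) -> pd.DataFrame:
        """Tidy local-crystallinity profiles on dimensionless position xi = x/L."""
        if self.chi_local_pct is None:
            raise ValueError("profiles were not recorded for this series")
        t = np.repeat(self.times, len(self.xi))
        xi = np.tile(self.xi, len(self.times))
        return pd.DataFrame({"time_h": t, "xi": xi,
                             "chi_local_pct": self.chi_local_pct.ravel()})


def _trapz(v: np.ndarray, dx: float) -> float:
    return float(np.trapezoid(v, dx=dx))


def bulk_crystallinity(state: StateField, geom: Geometry) -> float:
    """Crystalline fraction of the remaining polymer,
    ``int C dx / int (C + A) dx`` (trapezoidal quadrature)."""
    num = _trapz(np.clip(state.C, 0.0, None), geom.dx)
    den = _trapz(np.clip(state.C, 0.0, None) + np.clip(state.A, 0.0, None), geom.dx)
    if den <= _DEGRADED_EPS * geom.L:
        raise FullyDegradedError("no polymer left: bulk crystallinity undefined")
    return num / den


def local_crystallinity(state: StateField) -> np.ndarray:
    """Per-node crystalline fraction ``C / (C + A)`` of the remaining polymer.

    Nodes where the polymer has fully degraded are returned as NaN (flagged,
    never silently zeroed).
    """
    C = np.clip(state.C, 0.0, None)
    A = np.clip(state.A, 0.0, None)
    den = C + A
    out = np.full(state.N, np.nan)
    ok = den > _DEGRADED_EPS
    out[ok] = C[ok] / den[ok]
    return out


def weight_loss_percent(state: StateField, geom: Geometry,
                        init: InitialComposition,
                        convention: str = "product") -> float:
    """Percent of the initial polymer mass lost from the film.

    ``convention="product"`` (default): mass lost equals cumulative soluble
    product, ``100 * int P dx / ((C0+A0) L)`` -- residual mass includes
    polymer still bound in enzyme complexes, and the observable is
    non-decreasing along any trajectory.  ``convention="polymer"``: residual
    mass counts only the uncomplexed polymer C + A (matches the washing
    convention used for crystallinity).
    """
    total0 = (init.C0 + init.A0) * geom.L
    if convention == "product":
        lost = _trapz(np.clip(state.P, 0.0, None), geom.dx)
    elif convention == "polymer":
        lost = total0 - _trapz(np.clip(state.C, 0.0, None)
                               + np.clip(state.A, 0.0, None), geom.dx)
    else:
        raise ValueError(f"unknown weight-loss convention {convention!r}")
    return 100.0 * lost / total0


def damkohler(kin: KineticParameters, transport: TransportParameters,
              L: float) -> RegimeMetrics:
    """Damkoehler numbers and diffusion timescale for half-thickness L (mm)."""
    tau = L * L / transport.De0
    return RegimeMetrics(Da_A=kin.k_deg_A * tau, Da_C=kin.k_deg_C * tau,
                         tau_diff=tau)


def observable_series(traj: Trajectory, geom: Geometry,
                      init: InitialComposition,
                      convention: str = "product",
                      profiles: bool = False) -> ObservableSeries:
    """Weight-loss and crystallinity series (both in %) over a trajectory."""
    wl = np.array([weight_loss_percent(s, geom, init, convention)
                   for s in traj.states])
    xc = np.array([100.0 * bulk_crystallinity(s, geom) for s in traj.states])
    chi = por = xi = None
    if profiles:
        chi = np.vstack([100.0 * local_crystallinity(s) for s in traj.states])
        por = np.vstack([1.0 - np.clip(s.C, 0, None) - np.clip(s.A, 0, None)
                         for s in traj.states])
        xi = geom.x / geom.L
    return ObservableSeries(times=traj.times.copy(), weight_loss_pct=wl,
                            crystallinity_pct=xc, chi_local_pct=chi,
                            porosity=por, xi=xi)
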