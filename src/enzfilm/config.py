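"""Configuration handling: one YAML schema shared by all commands, plus a run
manifest for provenance.  Unknown keys are errors (fail fast)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import (Geometry, InitialComposition, KineticParameters,
                    SolverSettings, TransportParameters, grid_points_for)

__all__ = ["ModelConfig", "ConfigError", "load_config", "dump_config",
           "case_study_config", "RunManifest", "write_manifest",
           "CALIBRATED_KINETICS", "CALIBRATED_TRANSPORT"]

#: calibrated point estimates of the PCL-lipase case study (rates in 1/h,
#: De0 in mm^2/h)
CALIBRATED_KINETICS = KineticParameters(
    k1=0.65, k_m1=0.47, k3=0.30, k_m3=0.03,
    k_conv=0.58, k_deg_C=0.0012, k_deg_A=0.005)
CALIBRATED_TRANSPORT = TransportParameters(De0=1.66, alpha_e=1.0)

#: default observation grid (h) of the case-study measurements
CASE_STUDY_TIMES = (0.0, 4.0, 8.0, 16.0, 20.0, 24.0, 40.0, 64.0)


class ConfigError(ValueError):
    """Invalid or unknown configuration content; message names the field."""


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to run the forward model."""

    kinetics: KineticParameters
    transport: TransportParameters
    geometry: Geometry
    initial: InitialComposition
    solver: SolverSettings

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


def case_study_config(N: int | None = None, method: str = "BDF",
                      output_times=CASE_STUDY_TIMES, t_end: float = 72.0,
                      max_step: float = 0.5) -> ModelConfig:
    """The thin-film PCL-lipase case study: half-thickness 0.25 mm (full film
    0.5 mm), 30.2% initial crystallinity, 72 h horizon."""
    L = 0.25
    return ModelConfig(
        kinetics=CALIBRATED_KINETICS,
        transport=CALIBRATED_TRANSPORT,
        geometry=Geometry(L=L, N=N if N is not None else grid_points_for(L)),
        initial=InitialComposition(C0=0.302, A0=0.698),
        solver=SolverSettings(t_end=t_end, output_times=tuple(output_times),
                              method=method, max_step=max_step),
    )


# --------------------------------------------------------------------------
# YAML round-trip
# --------------------------------------------------------------------------

_SECTIONS = {
    "kinetics": ("k1", "k_m1", "k3", "k_m3", "k_conv", "k_deg_C", "k_deg_A"),
    "transport": ("De0", "alpha_e"),
    "geometry": ("L_mm", "N"),
    "initial": ("C0", "A0"),
    "solver": ("t_end_h", "output_times_h", "rtol", "atol", "max_step_h",
               "method"),
}


def _check_keys(section: str, given: dict, allowed, required) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': "
                          f"{sorted(unknown)}")
    missing = set(required) - set(given)
    if missing:
        raise ConfigError(f"missing key(s) in section '{section}': "
                          f"{sorted(missing)}")


def load_config(path) -> ModelConfig:
    """Read and validate a model configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")
    missing = {"kinetics", "transport", "geometry", "initial"} - set(raw)
    if missing:
        raise ConfigError(f"missing section(s): {sorted(missing)}")

    kin_d = raw["kinetics"]
    _check_keys("kinetics", kin_d, _SECTIONS["kinetics"], _SECTIONS["kinetics"])
    tr_d = raw["transport"]
    _check_keys("transport", tr_d, _SECTIONS["transport"], ("De0",))
    geo_d = raw["geometry"]
    _check_keys("geometry", geo_d, _SECTIONS["geometry"], ("L_mm",))
    init_d = raw["initial"]
    _check_keys("initial", init_d, _SECTIONS["initial"], ("C0", "A0"))
    sol_d = raw.get("solver", {}) or {}
    _check_keys("solver", sol_d, _SECTIONS["solver"], ())

    try:
        kin = KineticParameters(**kin_d)
        transport = TransportParameters(De0=tr_d["De0"],
                                        alpha_e=tr_d.get("alpha_e", 1.0))
        L = float(geo_d["L_mm"])
        geom = Geometry(L=L, N=int(geo_d.get("N", grid_points_for(L))))
        init = InitialComposition(**init_d)
        solver = SolverSettings(
            t_end=float(sol_d.get("t_end_h", 72.0)),
            output_times=tuple(sol_d.get("output_times_h", ())),
            rtol=float(sol_d.get("rtol", 1e-6)),
            atol=float(sol_d.get("atol", 1e-9)),
            max_step=float(sol_d.get("max_step_h", 0.5)),
            method=sol_d.get("method", "BDF"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return ModelConfig(kin, transport, geom, init, solver)


def dump_config(cfg: ModelConfig, path=None) -> str:
    """Serialise a ModelConfig back to YAML (inverse of load_config)."""
    doc = {
        "kinetics": {k: float(getattr(cfg.kinetics, k))
                     for k in _SECTIONS["kinetics"]},
        "transport": {"De0": float(cfg.transport.De0),
                      "alpha_e": float(cfg.transport.alpha_e)},
        "geometry": {"L_mm": float(cfg.geometry.L), "N": int(cfg.geometry.N)},
        "initial": {"C0": float(cfg.initial.C0), "A0": float(cfg.initial.A0)},
        "solver": {
            "t_end_h": float(cfg.solver.t_end),
            "output_times_h": [float(t) for t in
                               cfg.solver.resolved_output_times()],
            "rtol": float(cfg.solver.rtol),
            "atol": float(cfg.solver.atol),
            "max_step_h": float(cfg.solver.max_step),
            "method": cfg.solver.method,
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict
    input_checksums: dict
    package_version: str
    timestamp: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, command: str, cfg: ModelConfig | None,
                   seeds: dict | None = None, inputs=()) -> Path:
    """Write a JSON manifest alongside output artifacts so the run can be
    reproduced from the recorded config snapshot and seeds."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=yaml.safe_load(dump_config(cfg)) if cfg is not None else {},
        seeds=dict(seeds or {}),
        input_checksums={str(p): _sha256(Path(p)) for p in inputs},
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return path
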