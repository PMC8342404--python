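"""Run configuration and result serialization.

A run is configured by a plain-text key=value file ('#' starts a comment).
Parameter fields are set directly by name (e.g. ``delta_c = 2e-4``); the
remaining keys select the scenario, solver and experiment settings.  Unknown
keys are rejected with a descriptive error, and the merged configuration is
echoed verbatim into every output manifest so a run can be reproduced
byte-for-byte (all pipelines are deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import params as _params
from .params import EquilibriumState, ParameterSet
from .scenarios import PerturbationScenario, WoundScenario
from .solver import SolverConfig


class ConfigError(ValueError):
    pass


_SCENARIO_KEYS = {
    "scenario": str,            # 'wound' | 'perturbation'
    "k": int,
    "domain_length": float,
    "wound_length": float,
    "ramp_length": float,
    "amp_N": float, "amp_rho": float, "amp_v": float, "amp_eps": float,
    "M_low": float, "M_high": float, "c_low": float, "c_high": float,
    "c_w": float, "N_w": float, "rho_w": float,
}
_SOLVER_KEYS = {
    "n_elements": int,
    "dt": float,
    "dt_schedule": str,         # "t0:dt0, t1:dt1, ..."
    "t_end": float,
    "boundary_mode": str,
    "picard_tol": float,
    "picard_max": int,
    "lumping": bool,
    "N_bar": float,
    "eps_bar": float,
    "kmax": int,
    "seed": int,                # reserved; pipelines are deterministic
}


def _parse_bool(s: str) -> bool:
    if s.lower() in ("1", "true", "yes", "on"):
        return True
    if s.lower() in ("0", "false", "no", "off"):
        return False
    raise ConfigError(f"expected a boolean, got {s!r}")


def _parse_schedule(s: str) -> tuple:
    out = []
    for part in s.split(","):
        t0, dt = part.split(":")
        out.append((float(t0), float(dt)))
    return tuple(out)


@dataclass
class RunConfig:
    """Validated configuration of one run."""

    params: ParameterSet
    scenario_kind: str = "perturbation"
    scenario_options: dict = field(default_factory=dict)
    n_elements: int = 500
    dt_schedule: tuple = ((0.0, 0.5),)
    t_end: float = 400.0
    boundary_mode: str = "half"
    picard_tol: float = 1e-8
    picard_max: int = 25
    lumping: bool = True
    N_bar: float = 1.0e4
    eps_bar: float = 0.0
    kmax: int = 10
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def equilibrium(self) -> EquilibriumState:
        return EquilibriumState.from_params(self.params, N_bar=self.N_bar,
                                            eps_bar=self.eps_bar)

    def solver_config(self) -> SolverConfig:
        return SolverConfig(dt_schedule=self.dt_schedule,
                            picard_tol=self.picard_tol,
                            picard_max=self.picard_max,
                            lumping=self.lumping,
                            boundary_mode=self.boundary_mode)

    def scenario(self):
        if self.scenario_kind == "wound":
            keys = ("domain_length", "wound_length", "ramp_length",
                    "c_w", "N_w", "rho_w")
            return WoundScenario(**{k: v for k, v in
                                    self.scenario_options.items() if k in keys})
        keys = ("k", "amp_N", "amp_rho", "amp_v", "amp_eps",
                "M_low", "M_high", "c_low", "c_high", "domain_length")
        return PerturbationScenario(**{k: v for k, v in
                                       self.scenario_options.items()
                                       if k in keys})

    def to_dict(self) -> dict:
        d = {"params": self.params.to_dict(),
             "scenario": self.scenario_kind,
             **self.scenario_options}
        for k in ("n_elements", "t_end", "boundary_mode", "picard_tol",
                  "picard_max", "lumping", "N_bar", "eps_bar", "kmax", "seed"):
            d[k] = getattr(self, k)
        d["dt_schedule"] = list(map(list, self.dt_schedule))
        return d


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a run configuration.

    An empty (or absent) file yields the full defaults: the packaged
    parameter set, dt = 0.5 day, n = 500 elements on the half-domain.
    """
    mapping: dict[str, str] = {}
    if path is not None:
        mapping = _params.parse_kv_text(Path(path).read_text())
    if overrides:
        mapping.update({k: str(v) for k, v in overrides.items()})

    param_names = set(f.name for f in dataclasses.fields(ParameterSet))
    unknown = sorted(set(mapping) - param_names - set(_SCENARIO_KEYS)
                     - set(_SOLVER_KEYS))
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")

    p = _params.default_params()
    overridden = {k: float(v) for k, v in mapping.items() if k in param_names}
    if overridden:
        p = p.replace(**overridden).validate()

    cfg = RunConfig(params=p, raw=dict(mapping))
    scen_opts = {}
    for key, typ in _SCENARIO_KEYS.items():
        if key not in mapping:
            continue
        if key == "scenario":
            val = mapping[key]
            if val not in ("wound", "perturbation"):
                raise ConfigError(f"unknown scenario {val!r}")
            cfg.scenario_kind = val
        else:
            try:
                scen_opts[key] = typ(mapping[key])
            except ValueError as exc:
                raise ConfigError(f"key {key}: {exc}") from exc
    cfg.scenario_options = scen_opts
    for key, typ in _SOLVER_KEYS.items():
        if key not in mapping or key in ("dt", "dt_schedule"):
            continue
        try:
            val = _parse_bool(mapping[key]) if typ is bool else typ(mapping[key])
        except ValueError as exc:
            raise ConfigError(f"key {key}: {exc}") from exc
        setattr(cfg, key, val)
    if "dt_schedule" in mapping:
        cfg.dt_schedule = _parse_schedule(mapping["dt_schedule"])
    elif "dt" in mapping:
        cfg.dt_schedule = ((0.0, float(mapping["dt"])),)
    cfg.solver_config()      # validate
    cfg.scenario()
    cfg.equilibrium()
    return cfg


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

#: fixed decimal formatting keeps the CSV tables bit-stable across runs
CSV_FLOAT_FORMAT = "%.12e"


def write_outputs(summary: dict, tables: dict, outdir: str | Path,
                  config: RunConfig | dict | None = None) -> dict:
    """Write a JSON summary plus CSV tables and return the manifest.

    The manifest lists each file with its SHA-256 hash and echoes the
    configuration; it is itself written as manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _register(path: Path):
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    if summary:
        path = outdir / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                   default=_json_default) + "\n")
        _register(path)
    for name, frame in (tables or {}).items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, float_format=CSV_FLOAT_FORMAT)
        _register(path)
    echoed = (config.to_dict() if isinstance(config, RunConfig) else config) or {}
    manifest = {"files": files, "config": echoed}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default)
        + "\n")
    return manifest


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
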