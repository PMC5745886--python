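"""Configuration parsing/validation and run manifests.

Scenario configurations are plain YAML mappings; unknown keys, unit
violations and conflicting oxygen settings are rejected with messages
naming the offending field.  Every run can write a manifest capturing
the configuration snapshot, the parameter set after unit conversion,
solver tolerances and checksums of the produced files, from which the
(deterministic) run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biofilm_pde import ParameterSet
from .media import SPECIES
from .scenarios import DIET_C6, O_MAX, ScenarioConfig

_CONFIG_KEYS = {
    "diet", "O_b", "feedback", "O_pert", "antibiotic_level",
    "kill_constants", "shuttle_enabled", "grid_N", "t_max", "tol",
    "atpm", "initial_biomass", "parameters",
}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ParameterSet)}


class ConfigError(ValueError):
    """Raised for invalid scenario configurations."""


def validate_config(raw: dict | None) -> ScenarioConfig:
    """Build a validated :class:`ScenarioConfig` from a raw mapping.

    An empty mapping yields the documented defaults (nominal parameter
    values, high-CHO diet, anaerobic, N = 20).
    """
    raw = dict(raw or {})
    errors: list[str] = []
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        errors.append(f"unknown keys: {', '.join(unknown)}")

    params = None
    if "parameters" in raw:
        praw = raw.pop("parameters") or {}
        bad = sorted(set(praw) - _PARAM_KEYS)
        if bad:
            errors.append(f"unknown parameter fields: {', '.join(bad)}")
        else:
            try:
                params = ParameterSet(**praw)
            except (TypeError, ValueError) as exc:
                errors.append(f"parameters: {exc}")

    for key in ("O_b", "O_pert", "antibiotic_level", "t_max", "tol",
                "initial_biomass"):
        if key in raw and (not isinstance(raw[key], (int, float))
                           or raw[key] < 0):
            errors.append(f"{key} must be a non-negative number")
    if raw.get("feedback") and raw.get("O_b"):
        errors.append("feedback and a fixed O_b are mutually exclusive")
    if "diet" in raw and raw["diet"] not in DIET_C6:
        errors.append(f"unknown diet {raw['diet']!r}")
    if "atpm" in raw:
        atpm = raw["atpm"]
        if not isinstance(atpm, dict) or set(atpm) - set(SPECIES):
            errors.append("atpm must map species in {Bt, Fp, Ec}")
        elif any(v < 0 for v in atpm.values()):
            errors.append("atpm values must be non-negative")
    if errors:
        raise ConfigError("; ".join(errors))

    warnings = []
    if raw.get("O_b", 0) > O_MAX or raw.get("O_pert", 0) > O_MAX:
        warnings.append(
            f"bulk oxygen above the studied range (O_b <= {O_MAX} mM)")

    if "atpm" in raw:
        base = dict(ScenarioConfig().atpm)
        base.update(raw["atpm"])
        raw["atpm"] = base
    cfg = ScenarioConfig(params=params, **raw)
    cfg.warnings = warnings  # type: ignore[attr-defined]
    return cfg


def load_config(path) -> ScenarioConfig:
    """Parse and validate a YAML scenario configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    return validate_config(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Machine-readable record of one run (reproducibility contract)."""

    subcommand: str
    config: dict
    parameters_internal: dict
    code_version: str
    tolerances: dict
    wall_time_s: float
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    extra: dict = field(default_factory=dict)

    @classmethod
    def create(cls, subcommand: str, config: ScenarioConfig,
               wall_time_s: float, extra: dict | None = None) -> "RunManifest":
        from . import __version__

        params = config.parameter_set()
        ip = params.internal()
        return cls(
            subcommand=subcommand,
            config=_as_jsonable(dataclasses.asdict(config)),
            parameters_internal={
                "L_cm": ip.L, "D_X": ip.D_X, "k_X": ip.k_X,
                "D": ip.D.tolist(), "k": ip.k.tolist(),
                "v_max": ip.v_max.tolist(), "K_m": ip.K_m.tolist(),
                "atpm": ip.atpm,
            },
            code_version=__version__,
            tolerances={"steady_tol": config.tol, "t_max": config.t_max},
            wall_time_s=wall_time_s,
            extra=extra or {},
        )

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


class Timer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0
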