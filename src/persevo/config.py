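"""Configuration loading, validation, hashing, and tidy-CSV writers.

A run configuration is a YAML mapping with three optional blocks —
``engine``, ``regimen``, ``grid`` — plus a base ``seed``.  Every default
equals the model's standard parameterization (K = 1e6, m = 1e-4, psi_max =
0.6, psi_min = -10, kappa = 1, b_max = 0.1/h, dt = 0.5 h, inoculum 1e3 + 1,
10 cycles, 1:100 post-treatment dilution), so an empty file is a complete,
valid configuration.  Unknown keys are rejected with their key path, and a
canonical-JSON SHA-256 hash of the fully resolved configuration is logged so
runs can be matched to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .engine import Engine
from .errors import ConfigError, InvalidParameterError
from .experiments import DEFAULT_DOSES, DEFAULT_NUTRIENTS, GridSpec
from .genotypes import build_mutation_kernel
from .pharmacodynamics import PharmacodynamicParams
from .protocol import TreatmentRegimen

__all__ = ["RunConfig", "load_config", "write_results"]

_ENGINE_DEFAULTS = {
    "K": 10**6,
    "m": 1e-4,
    "psi_max": 0.6,
    "psi_min": -10.0,
    "kappa_ab": 1.0,
    "kappa_n": 1.0,
    "n_half": 0.5,
    "b_max": 0.1,
    "dt": 0.5,
    "allow_persistence": True,
    "allow_resistance": True,
    "kernel_normalization": "row",
}
_REGIMEN_DEFAULTS = {
    "ab_dose": 100.0,
    "n0": 0.5,
    "treatment_hours": 5.0,
    "cycle_hours": 24.0,
    "n_cycles": 10,
    "post_dilution": 0.01,
    "fixed_bottleneck": None,
    "initial_growth": True,
}
_GRID_DEFAULTS = {
    "doses": list(DEFAULT_DOSES),
    "nutrient_levels": list(DEFAULT_NUTRIENTS),
    "replicates": 1000,
    "no_persistence_evolution": False,
    "fixed_bottleneck": None,
    "n_cycles": 10,
}


def _merge(defaults: dict, given: dict, path: str) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration key(s) at {path}: {sorted(unknown)}")
    return {**defaults, **given}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run configuration."""

    engine: dict = field(default_factory=dict)
    regimen: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"engine": self.engine, "regimen": self.regimen, "grid": self.grid, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def build_engine(self) -> Engine:
        e = self.engine
        pd_params = PharmacodynamicParams(
            psi_max=e["psi_max"],
            psi_min=e["psi_min"],
            kappa_ab=e["kappa_ab"],
            kappa_n=e["kappa_n"],
            n_half=e["n_half"],
            b_max=e["b_max"],
            dt=e["dt"],
        )
        kernel = build_mutation_kernel(
            m=e["m"],
            allow_persistence=e["allow_persistence"],
            allow_resistance=e["allow_resistance"],
            normalization=e["kernel_normalization"],
        )
        return Engine(K=e["K"], pd_params=pd_params, kernel=kernel)

    def build_regimen(self, **overrides) -> TreatmentRegimen:
        return TreatmentRegimen(**{**self.regimen, **overrides})

    def build_grid(self, **overrides) -> GridSpec:
        g = {**self.grid, **overrides}
        return GridSpec(
            doses=tuple(g["doses"]),
            nutrient_levels=tuple(g["nutrient_levels"]),
            replicates=g["replicates"],
            no_persistence_evolution=g["no_persistence_evolution"],
            fixed_bottleneck=g["fixed_bottleneck"],
            base_seed=g.get("base_seed", self.seed),
            n_cycles=g["n_cycles"],
        )


def _from_mapping(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    unknown = set(raw) - {"engine", "regimen", "grid", "seed"}
    if unknown:
        raise ConfigError(f"unknown top-level configuration key(s): {sorted(unknown)}")
    cfg = RunConfig(
        engine=_merge(_ENGINE_DEFAULTS, raw.get("engine") or {}, "engine"),
        regimen=_merge(_REGIMEN_DEFAULTS, raw.get("regimen") or {}, "regimen"),
        grid=_merge(_GRID_DEFAULTS, raw.get("grid") or {}, "grid"),
        seed=int(raw.get("seed", 0)),
    )
    # validate eagerly so errors carry the offending key path
    try:
        cfg.build_engine()
    except InvalidParameterError as exc:
        raise ConfigError(f"invalid engine configuration: {exc}") from exc
    try:
        cfg.build_regimen()
    except InvalidParameterError as exc:
        raise ConfigError(f"invalid regimen configuration (key n0/ab_dose/...): {exc}") from exc
    try:
        cfg.build_grid(replicates=max(cfg.grid["replicates"], 1))
    except InvalidParameterError as exc:
        raise ConfigError(f"invalid grid configuration: {exc}") from exc
    return cfg


def load_config(path: str | None = None) -> RunConfig:
    """Load and validate a YAML configuration; ``None`` means all defaults."""
    if path is None:
        return _from_mapping({})
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _from_mapping(raw)


def write_results(records, path, fmt: str = "csv") -> None:
    """Write schema-consistent records as CSV/TSV with a stable column order."""
    if isinstance(records, pd.DataFrame):
        frame = records
        if frame.empty:
            raise InvalidParameterError("records must be non-empty")
    else:
        records = list(records)
        if not records:
            raise InvalidParameterError("records must be non-empty")
        columns = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != columns:
                raise InvalidParameterError(
                    f"record {i} schema {list(rec.keys())} != {columns}"
                )
        frame = pd.DataFrame(records, columns=columns)
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise InvalidParameterError(f"unknown format {fmt!r}")
    frame.to_csv(path, sep=sep, index=False)
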