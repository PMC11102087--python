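"""Grid experiments over antibiotic dose x nutrient level.

Replicated populations are simulated over a dose x nutrient grid, classified
as having evolved resistance and/or persistence (a population counts as
evolved when at least 30% of its live cells sit in classes with an elevated
level), and summarized per condition.  The persistence-evolution ablation
re-runs the grid with a mutation kernel restricted to resistance targets and
compares surviving-population totals over the harsh-condition subset
(dose > 25 ug/ml, nutrient > 0.3).

Replicate r of condition c always uses the seed derivation
``SeedSequence(base_seed, spawn_key=(c, r))``, so results are independent of
execution order and bit-reproducible given the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Engine, PopulationState
from .errors import ExtinctPopulationError, InvalidParameterError
from .genotypes import N_CLASSES, build_classes, build_mutation_kernel
from .protocol import SimulationResult, TreatmentRegimen, run_simulation

__all__ = [
    "GridSpec",
    "ConditionSummary",
    "classify_population",
    "summarize_levels",
    "run_grid",
    "run_persistence_ablation",
    "population_rng",
]

DEFAULT_DOSES = (12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
DEFAULT_NUTRIENTS = tuple(round(0.1 * i, 1) for i in range(1, 10))

_CLASSES = build_classes()
_L_RES = np.array([c.l_res for c in _CLASSES])
_L_PER = np.array([c.l_per for c in _CLASSES])
_LABELS = [c.label for c in _CLASSES]


@dataclass(frozen=True)
class GridSpec:
    """A dose x nutrient experimental grid with replication and ablations."""

    doses: tuple[float, ...] = DEFAULT_DOSES
    nutrient_levels: tuple[float, ...] = DEFAULT_NUTRIENTS
    replicates: int = 1000
    no_persistence_evolution: bool = False
    fixed_bottleneck: float | None = None
    base_seed: int = 0
    n_cycles: int = 10

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise InvalidParameterError("doses must be > 0")
        if any(not (0 < n < 1) for n in self.nutrient_levels):
            raise InvalidParameterError("nutrient levels must lie in (0, 1)")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")

    @property
    def conditions(self) -> list[tuple[float, float]]:
        """(dose, nutrient) pairs in a fixed, dose-major order."""
        return [(d, n) for d in self.doses for n in self.nutrient_levels]


@dataclass
class ConditionSummary:
    """Per-condition outcome counts and mean evolved levels of survivors."""

    dose: float
    nutrient: float
    replicates: int
    n_surviving: int
    n_extinct: int
    n_only_resistance: int
    n_only_persistence: int
    n_both: int
    n_neither: int
    mean_l_res: float
    mean_l_per: float


def population_rng(base_seed: int, condition_index: int, replicate: int) -> np.random.Generator:
    """Deterministic per-population generator (stable under any run order)."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(base_seed, spawn_key=(condition_index, replicate)))
    )


def _live_state(obj: SimulationResult | PopulationState) -> PopulationState:
    state = obj.final_state if isinstance(obj, SimulationResult) else obj
    if state.is_extinct:
        raise ExtinctPopulationError("classification is undefined for extinct populations")
    return state


def classify_population(
    result: SimulationResult | PopulationState, threshold: float = 0.30
) -> tuple[bool, bool]:
    """Flag evolved resistance / persistence in a surviving population.

    A phenotype counts as evolved when the fraction of live cells (regular
    plus persister) in classes with an elevated level is at least
    ``threshold``.
    """
    state = _live_state(result)
    live = state.live_counts()
    total = live.sum()
    frac_res = live[_L_RES > 0].sum() / total
    frac_per = live[_L_PER > 0].sum() / total
    return bool(frac_res >= threshold), bool(frac_per >= threshold)


def summarize_levels(result: SimulationResult | PopulationState) -> tuple[float, float]:
    """Abundance-weighted mean resistance (log2 FC) and persistence (log10 FC)
    levels over the live cells of a surviving population."""
    state = _live_state(result)
    live = state.live_counts()
    total = live.sum()
    return float(live @ _L_RES / total), float(live @ _L_PER / total)


def _grid_engine(grid: GridSpec, engine: Engine | None) -> Engine:
    if engine is None:
        engine = Engine()
    if grid.no_persistence_evolution:
        engine = engine.with_kernel(
            build_mutation_kernel(m=engine.kernel.m, allow_persistence=False)
        )
    return engine


def run_grid(
    grid: GridSpec,
    engine: Engine | None = None,
    regimen_template: dict | None = None,
    conditions: list[tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every replicate of every grid condition.

    Returns ``(populations, summaries)``: one row per population (with the
    final live-class occupancy vector, enough to re-derive classifications
    without re-simulation) and one row per condition.

    ``conditions`` restricts the run to a subset of ``grid.conditions``
    without changing seed derivations.
    """
    engine = _grid_engine(grid, engine)
    regimen_kwargs = dict(regimen_template or {})
    regimen_kwargs.setdefault("n_cycles", grid.n_cycles)
    if grid.fixed_bottleneck is not None:
        regimen_kwargs.setdefault("fixed_bottleneck", grid.fixed_bottleneck)

    all_conditions = grid.conditions
    wanted = all_conditions if conditions is None else list(conditions)
    rows = []
    for ci, (dose, nutrient) in enumerate(all_conditions):
        if (dose, nutrient) not in wanted:
            continue
        regimen = TreatmentRegimen(ab_dose=dose, n0=nutrient, **regimen_kwargs)
        for rep in range(grid.replicates):
            rng = population_rng(grid.base_seed, ci, rep)
            result = run_simulation(regimen, engine, rng)
            row = {
                "dose": dose,
                "nutrient": nutrient,
                "replicate": rep,
                "extinct": result.extinct,
                "cycles_survived": result.cycles_survived,
            }
            if result.extinct:
                row.update(
                    resistance_evolved=pd.NA, persistence_evolved=pd.NA,
                    mean_l_res=np.nan, mean_l_per=np.nan,
                )
                occupancy = np.zeros(N_CLASSES, dtype=np.int64)
            else:
                res_ev, per_ev = classify_population(result)
                mean_r, mean_p = summarize_levels(result)
                row.update(
                    resistance_evolved=res_ev, persistence_evolved=per_ev,
                    mean_l_res=mean_r, mean_l_per=mean_p,
                )
                occupancy = result.final_state.live_counts()
            row.update({f"live_{lab}": int(c) for lab, c in zip(_LABELS, occupancy)})
            rows.append(row)
    populations = pd.DataFrame(rows)
    summaries = summarize_grid(populations)
    return populations, summaries


def summarize_grid(populations: pd.DataFrame) -> pd.DataFrame:
    """Condition-level summaries from a per-population table."""
    out = []
    for (dose, nutrient), grp in populations.groupby(["dose", "nutrient"], sort=True):
        surv = grp[~grp["extinct"]]
        res = surv["resistance_evolved"].astype(bool) if len(surv) else pd.Series(dtype=bool)
        per = surv["persistence_evolved"].astype(bool) if len(surv) else pd.Series(dtype=bool)
        out.append(
            ConditionSummary(
                dose=dose,
                nutrient=nutrient,
                replicates=len(grp),
                n_surviving=len(surv),
                n_extinct=int(grp["extinct"].sum()),
                n_only_resistance=int((res & ~per).sum()),
                n_only_persistence=int((~res & per).sum()),
                n_both=int((res & per).sum()),
                n_neither=int((~res & ~per).sum()),
                mean_l_res=float(surv["mean_l_res"].mean()) if len(surv) else np.nan,
                mean_l_per=float(surv["mean_l_per"].mean()) if len(surv) else np.nan,
            ).__dict__
        )
    return pd.DataFrame(out)


def run_persistence_ablation(
    grid: GridSpec,
    engine: Engine | None = None,
    dose_min: float = 25.0,
    nutrient_min: float = 0.3,
) -> dict:
    """Surviving-population totals, full model vs no-persistence-evolution.

    Only conditions with dose > ``dose_min`` and nutrient > ``nutrient_min``
    are simulated (populations are independent, so the totals over this
    subset do not depend on the rest of the grid).  Both kernels reuse the
    same per-population seeds, pairing the comparison across replicates.
    """
    subset = [
        (d, n) for (d, n) in grid.conditions if d > dose_min and n > nutrient_min
    ]
    full_grid = GridSpec(**{**grid.__dict__, "no_persistence_evolution": False})
    ablated_grid = GridSpec(**{**grid.__dict__, "no_persistence_evolution": True})
    pops_full, summ_full = run_grid(full_grid, engine, conditions=subset)
    pops_abl, summ_abl = run_grid(ablated_grid, engine, conditions=subset)
    table = summ_full[["dose", "nutrient", "n_surviving"]].merge(
        summ_abl[["dose", "nutrient", "n_surviving"]],
        on=["dose", "nutrient"],
        suffixes=("_full", "_ablated"),
    )
    return {
        "conditions": subset,
        "surviving_full": int(summ_full["n_surviving"].sum()),
        "surviving_ablated": int(summ_abl["n_surviving"].sum()),
        "table": table,
        "populations_full": pops_full,
        "populations_ablated": pops_abl,
    }
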