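"""The intermittent-treatment protocol.

One evolutionary cycle mirrors the serial-passage experiment:

1. a stationary culture is diluted into fresh medium so that the nutrient
   level at treatment initiation equals ``n0`` (keep fraction ``1 - n0``,
   the culture-to-total volume ratio);
2. 5 h of antibiotic exposure at the treatment dose;
3. wash and 1:100 transfer into fresh medium (nutrient level reset to 1,
   antibiotic removed instantaneously);
4. 19 h of drug-free regrowth.

A simulation starts from the ancestral inoculum (10^3 regular cells plus one
persister in fresh medium), grows for one drug-free phase, and then runs a
fixed number of cycles, recording per-cycle survival fractions and
extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Engine, PopulationState, TrajectoryRecorder, dilute, step
from .errors import InvalidParameterError
from .genotypes import MutantClass, build_mutation_kernel, class_index

__all__ = [
    "TreatmentRegimen",
    "SimulationResult",
    "run_cycle",
    "run_simulation",
    "simulate_single_mutant_survival",
]


@dataclass(frozen=True)
class TreatmentRegimen:
    """Timing, dosing and dilution structure of the daily treatment cycle."""

    ab_dose: float
    n0: float
    treatment_hours: float = 5.0
    cycle_hours: float = 24.0
    n_cycles: int = 10
    post_dilution: float = 0.01
    pre_treatment_keep_fraction: float | None = None
    fixed_bottleneck: float | None = None
    initial_growth: bool = True

    def __post_init__(self) -> None:
        if self.ab_dose < 0:
            raise InvalidParameterError("ab_dose must be >= 0")
        if not (0.0 < self.n0 < 1.0):
            raise InvalidParameterError("n0 must lie in (0, 1)")
        if not (0.0 < self.treatment_hours < self.cycle_hours):
            raise InvalidParameterError("need 0 < treatment_hours < cycle_hours")
        if self.n_cycles < 0:
            raise InvalidParameterError("n_cycles must be >= 0")
        if not (0.0 < self.post_dilution <= 1.0):
            raise InvalidParameterError("post_dilution must lie in (0, 1]")

    @property
    def bottleneck(self) -> float:
        """Pre-treatment keep fraction: 1 - n0 unless explicitly overridden."""
        if self.fixed_bottleneck is not None:
            return self.fixed_bottleneck
        if self.pre_treatment_keep_fraction is not None:
            return self.pre_treatment_keep_fraction
        return 1.0 - self.n0

    @property
    def growth_hours(self) -> float:
        return self.cycle_hours - self.treatment_hours


@dataclass
class SimulationResult:
    """Outcome of one simulated population."""

    survival_fractions: list[float]
    extinct: bool
    cycles_survived: int
    final_state: PopulationState
    trajectory: pd.DataFrame | None = field(default=None, repr=False)


def _run_phase(
    state: PopulationState,
    hours: float,
    ab: float,
    engine: Engine,
    rng: np.random.Generator,
    recorder: TrajectoryRecorder | None,
) -> None:
    n_steps = int(round(hours / engine.pd.dt))
    for i in range(n_steps):
        if state.is_extinct:
            state.t += (n_steps - i) * engine.pd.dt  # clock only; extinction absorbs
            break
        step(state, ab, engine, rng)
        if recorder is not None:
            recorder.record(state)


def run_cycle(
    state: PopulationState,
    regimen: TreatmentRegimen,
    engine: Engine,
    rng: np.random.Generator,
    recorder: TrajectoryRecorder | None = None,
) -> float:
    """Run one full treatment cycle in place; returns the survival fraction.

    The survival fraction is live cells at the end of treatment over live
    cells at treatment initiation (clipped at 1, mirroring a CFU ratio).
    """
    dilute(state, regimen.bottleneck, regimen.n0, rng)
    before = state.total_live
    _run_phase(state, regimen.treatment_hours, regimen.ab_dose, engine, rng, recorder)
    after = state.total_live
    survival = min(after / before, 1.0) if before > 0 else 0.0
    dilute(state, regimen.post_dilution, 1.0, rng)
    _run_phase(state, regimen.growth_hours, 0.0, engine, rng, recorder)
    return survival


def run_simulation(
    regimen: TreatmentRegimen,
    engine: Engine,
    rng: np.random.Generator,
    initial_state: PopulationState | None = None,
    record_trajectory: bool = False,
    record_every_h: float = 0.5,
    stop_on_extinction: bool = True,
) -> SimulationResult:
    """Simulate one population through the full treatment schedule."""
    state = initial_state.copy() if initial_state is not None else PopulationState.ancestral()
    recorder = TrajectoryRecorder(record_every_h) if record_trajectory else None
    if recorder is not None:
        recorder.record(state, force=True)
    if regimen.initial_growth:
        _run_phase(state, regimen.growth_hours, 0.0, engine, rng, recorder)
    survival: list[float] = []
    cycles_survived = 0
    for _ in range(regimen.n_cycles):
        survival.append(run_cycle(state, regimen, engine, rng, recorder))
        if state.is_extinct:
            if stop_on_extinction:
                break
        else:
            cycles_survived += 1
    if recorder is not None:
        recorder.record(state, force=True)
    return SimulationResult(
        survival_fractions=survival,
        extinct=state.is_extinct,
        cycles_survived=cycles_survived,
        final_state=state,
        trajectory=recorder.to_frame() if recorder is not None else None,
    )


_ZERO_KERNEL_CACHE: dict[int, Engine] = {}


def _mutation_free(engine: Engine) -> Engine:
    if engine.kernel.m == 0:
        return engine
    key = id(engine)
    cached = _ZERO_KERNEL_CACHE.get(key)
    if cached is None:
        cached = engine.with_kernel(build_mutation_kernel(m=0.0))
        _ZERO_KERNEL_CACHE[key] = cached
    return cached


def simulate_single_mutant_survival(
    mutant: MutantClass | tuple[int, int],
    ab_dose: float,
    n0: float,
    engine: Engine,
    replicates: int = 20,
    seed: int = 0,
    n_regular: int = 1000,
    n_persister: int = 1,
) -> float:
    """Survival fraction of an isogenic mutant population after one cycle.

    The population grows drug-free for 19 h from a small inoculum, is diluted
    to nutrient level ``n0``, and treated for 5 h; de novo mutation is
    disabled.  Returns the mean over replicates of (live cells after
    treatment) / (live cells before treatment), clipped at 1.
    """
    if isinstance(mutant, tuple):
        mutant = MutantClass(*mutant)
    eng = _mutation_free(engine)
    regimen = TreatmentRegimen(ab_dose=ab_dose, n0=n0, n_cycles=1)
    idx = class_index(mutant.l_res, mutant.l_per)
    fractions = []
    for r in range(replicates):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(idx, r)))
        )
        state = PopulationState.isogenic(idx, n_regular, n_persister)
        _run_phase(state, regimen.growth_hours, 0.0, eng, rng, None)
        dilute(state, regimen.bottleneck, n0, rng)
        before = state.total_live
        _run_phase(state, regimen.treatment_hours, ab_dose, eng, rng, None)
        after = state.total_live
        fractions.append(min(after / before, 1.0) if before > 0 else 0.0)
    return float(np.mean(fractions))
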