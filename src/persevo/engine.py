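"""Binomial tau-leap stochastic engine.

Population dynamics are advanced in fixed 30-min intervals.  Within one
interval, for each genotype class:

1. growth — classes with psi > 0 draw divisions ~ Binomial(regular, g) with
   g = log2(10**(psi*dt)) * n; daughters may mutate (multinomial over the
   kernel row) and may not divide again within the step;
2. killing — classes with psi < 0 draw deaths ~ Binomial(regular, 1 -
   10**(psi*eta(n)*dt)); dead cells join a bookkeeping pool used by dilution;
3. switching — regular -> persister with probability 1 - exp(-a(n)*dt) and
   persister -> regular with 1 - exp(-b(n)*dt); persisters never divide, die
   or mutate;
4. nutrients — n decreases by the net population increase divided by the
   carrying capacity K, clamped to [0, 1] (killing does not replenish).

Dilutions (medium transfers) draw a multinomial sample over all regular and
persister compartments plus the dead-cell pool, at the current frequencies,
mirroring pipetting from a well that contains live and dead cells alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genotypes import (
    N_CLASSES,
    MutationKernel,
    build_classes,
    build_mutation_kernel,
)
from .pharmacodynamics import (
    PharmacodynamicParams,
    net_growth_rate,
    nutrient_kill_modifier,
)

__all__ = [
    "PopulationState",
    "Engine",
    "step",
    "deplete_nutrients",
    "dilute",
    "TrajectoryRecorder",
]

_LOG2_10 = math.log2(10.0)


@dataclass
class PopulationState:
    """Counts of regular and persister cells per class, plus nutrient and clock."""

    regular: np.ndarray
    persister: np.ndarray
    n: float = 1.0
    t: float = 0.0
    cumulative_dead: int = 0

    @classmethod
    def ancestral(
        cls, n_regular: int = 1000, n_persister: int = 1, n: float = 1.0
    ) -> "PopulationState":
        """The standard initial condition: ancestor-only, fresh medium."""
        regular = np.zeros(N_CLASSES, dtype=np.int64)
        persister = np.zeros(N_CLASSES, dtype=np.int64)
        regular[0] = n_regular
        persister[0] = n_persister
        return cls(regular=regular, persister=persister, n=n)

    @classmethod
    def isogenic(
        cls, index: int, n_regular: int = 1000, n_persister: int = 1, n: float = 1.0
    ) -> "PopulationState":
        regular = np.zeros(N_CLASSES, dtype=np.int64)
        persister = np.zeros(N_CLASSES, dtype=np.int64)
        regular[index] = n_regular
        persister[index] = n_persister
        return cls(regular=regular, persister=persister, n=n)

    @property
    def total_live(self) -> int:
        return int(self.regular.sum() + self.persister.sum())

    @property
    def is_extinct(self) -> bool:
        return self.total_live == 0

    def live_counts(self) -> np.ndarray:
        return self.regular + self.persister

    def copy(self) -> "PopulationState":
        return PopulationState(
            regular=self.regular.copy(),
            persister=self.persister.copy(),
            n=self.n,
            t=self.t,
            cumulative_dead=self.cumulative_dead,
        )


class Engine:
    """Immutable bundle of model parameters plus per-dose caches.

    Parameters
    ----------
    K : int
        Carrying capacity in cells.
    pd_params : PharmacodynamicParams
        Rate-function parameters.
    kernel : MutationKernel, optional
        Beneficial-mutation kernel; defaults to the full kernel at m = 1e-4.
    """

    def __init__(
        self,
        K: int = 10**6,
        pd_params: PharmacodynamicParams | None = None,
        kernel: MutationKernel | None = None,
    ) -> None:
        if K <= 0:
            raise InvalidParameterError("K must be > 0")
        self.K = int(K)
        self.pd = pd_params if pd_params is not None else PharmacodynamicParams()
        self.classes = build_classes()
        self.kernel = kernel if kernel is not None else build_mutation_kernel()
        self.mics = np.array([c.mic for c in self.classes])
        self.a_max = np.array([c.a_max for c in self.classes])
        self._psi_cache: dict[float, np.ndarray] = {}

    def with_kernel(self, kernel: MutationKernel) -> "Engine":
        return Engine(K=self.K, pd_params=self.pd, kernel=kernel)

    def psi(self, ab: float) -> np.ndarray:
        """Net growth rate per class at dose ``ab`` (cached per dose)."""
        cached = self._psi_cache.get(ab)
        if cached is None:
            cached = np.array(
                [net_growth_rate(ab, mic, self.pd) for mic in self.mics]
            )
            self._psi_cache[ab] = cached
        return cached


def deplete_nutrients(state: PopulationState, delta_n_tot: int, K: int) -> PopulationState:
    """Lower the nutrient level by the net population increase over K.

    Only net growth consumes nutrients; a net decrease (killing) does not
    replenish them.  The level is clamped to [0, 1].
    """
    if delta_n_tot > 0:
        state.n = min(max(state.n - delta_n_tot / K, 0.0), 1.0)
    return state


def step(
    state: PopulationState,
    ab: float,
    engine: Engine,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population by one time interval at dose ``ab`` (in place).

    Extinct states pass through unchanged except for the clock.
    """
    pdp = engine.pd
    dt = pdp.dt
    if state.is_extinct:
        state.t += dt
        return state

    R = state.regular
    P = state.persister
    n = state.n
    psi = engine.psi(ab)

    births = np.zeros(N_CLASSES, dtype=np.int64)
    deaths = np.zeros(N_CLASSES, dtype=np.int64)
    kernel = engine.kernel

    occupied = np.flatnonzero(R)
    if occupied.size:
        psi_occ = psi[occupied]
        if n > 0.0:
            grow = occupied[psi_occ > 0]
            if grow.size:
                g = np.minimum(psi[grow] * dt * _LOG2_10 * n, 1.0)
                divs = rng.binomial(R[grow], g)
                for idx, nd in zip(grow, divs):
                    if nd == 0:
                        continue
                    p_mut = kernel.row_total[idx]
                    n_mut = rng.binomial(nd, p_mut) if p_mut > 0 else 0
                    births[idx] += nd - n_mut
                    if n_mut:
                        births += rng.multinomial(n_mut, kernel.target_probs[idx])
            kill = occupied[psi_occ < 0]
            if kill.size:
                eta = nutrient_kill_modifier(n, pdp)
                if eta > 0.0:
                    p_death = 1.0 - 10.0 ** (psi[kill] * eta * dt)
                    deaths[kill] = rng.binomial(R[kill], p_death)

    R = R + births - deaths
    n_dead = int(deaths.sum())
    state.cumulative_dead += n_dead

    # switching acts on post-growth/post-death regular cells and on persisters
    p_fwd = -np.expm1(-engine.a_max * (1.0 - n) * dt)
    fwd = rng.binomial(R, p_fwd)
    p_bwd = -math.expm1(-pdp.b_max * n * dt)
    bwd = rng.binomial(P, p_bwd) if p_bwd > 0 else np.zeros(N_CLASSES, dtype=np.int64)

    state.regular = R - fwd + bwd
    state.persister = P + fwd - bwd

    deplete_nutrients(state, int(births.sum()) - n_dead, engine.K)
    state.t += dt
    return state


def dilute(
    state: PopulationState,
    keep_fraction: float,
    fresh_nutrient_level: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Transfer a fraction of the culture into fresh medium (in place).

    A multinomial sample of size ``round(keep_fraction * (live + dead))`` is
    drawn over all class x {regular, persister} compartments and the dead
    pool, at their current frequencies.  Sampled dead cells remain inert
    bookkeeping; the nutrient level is set to ``fresh_nutrient_level``.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise InvalidParameterError("keep_fraction must lie in (0, 1]")
    if not (0.0 <= fresh_nutrient_level <= 1.0):
        raise InvalidParameterError("fresh_nutrient_level must lie in [0, 1]")
    total = state.total_live + state.cumulative_dead
    if keep_fraction < 1.0 and total > 0:
        size = int(round(keep_fraction * total))
        counts = np.concatenate(
            (state.regular, state.persister, [state.cumulative_dead])
        ).astype(float)
        sample = rng.multinomial(size, counts / total)
        state.regular = sample[:N_CLASSES].astype(np.int64)
        state.persister = sample[N_CLASSES : 2 * N_CLASSES].astype(np.int64)
        state.cumulative_dead = int(sample[-1])
    state.n = fresh_nutrient_level
    return state


class TrajectoryRecorder:
    """Collects long-format trajectory rows, optionally down-sampled.

    Rows are (time_h, class_label, compartment, count, nutrient); only
    occupied compartments are written (absent rows mean zero).
    """

    def __init__(self, every_h: float = 0.5) -> None:
        self.every_h = every_h
        self._labels = [c.label for c in build_classes()]
        self._rows: list[tuple] = []
        self._next_t = -math.inf

    def record(self, state: PopulationState, force: bool = False) -> None:
        if not force and state.t < self._next_t:
            return
        self._next_t = state.t + self.every_h - 1e-9
        for name, counts in (("regular", state.regular), ("persister", state.persister)):
            for idx in np.flatnonzero(counts):
                self._rows.append(
                    (state.t, self._labels[idx], name, int(counts[idx]), state.n)
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._rows,
            columns=["time_h", "class_label", "compartment", "count", "nutrient"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
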