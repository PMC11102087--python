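"""Tests for the binomial tau-leap engine: step, nutrients, dilution."""

import numpy as np
import pytest

from persevo import (
    Engine,
    InvalidParameterError,
    PharmacodynamicParams,
    PopulationState,
    build_mutation_kernel,
    dilute,
    step,
)
from persevo.engine import deplete_nutrients

from .oracles import logistic_recursion


def test_extinction_is_absorbing(engine, rng):
    state = PopulationState(
        regular=np.zeros(30, dtype=np.int64),
        persister=np.zeros(30, dtype=np.int64),
        n=0.7,
    )
    step(state, 100.0, engine, rng)
    assert state.is_extinct and state.total_live == 0
    assert state.n == 0.7 and state.t == pytest.approx(0.5)


def test_no_growth_without_nutrients(engine_m0, rng):
    state = PopulationState.ancestral(n_regular=10_000, n_persister=0, n=0.0)
    step(state, 0.0, engine_m0, rng)
    # no divisions, no deaths; only switching at the stationary-phase maximum
    assert state.total_live == 10_000
    switched = int(state.persister.sum())
    p = 1 - np.exp(-(10**-4.5) * 0.5)
    assert abs(switched - 10_000 * p) < 5 * np.sqrt(10_000 * p) + 1


def test_one_step_growth_expectation(engine_m0):
    """Mean one-step growth matches the binomial expectation N*(1+g)."""
    n0, reps = 10_000, 300
    finals = []
    for s in range(reps):
        rng = np.random.default_rng(s)
        state = PopulationState.ancestral(n_regular=n0, n_persister=0, n=1.0)
        step(state, 0.0, engine_m0, rng)
        finals.append(state.regular.sum())
    g = 0.3 * np.log2(10.0)
    expected = n0 * (1 + g)
    se = np.sqrt(n0 * g * (1 - g) / reps)
    assert abs(np.mean(finals) - expected) < 4 * se + 1


def test_drug_free_trajectory_matches_logistic_recursion(engine_m0, rng):
    """With ab=0, m=0: mean trajectory follows the deterministic logistic
    recursion, plateauing near N0 + n0*K."""
    state = PopulationState.ancestral(n_regular=10_000, n_persister=0, n=0.5)
    for _ in range(60):
        step(state, 0.0, engine_m0, rng)
    expected = logistic_recursion(10_000, 0.5, 10**6, 0.6, 0.5, 60)
    assert state.total_live == pytest.approx(expected, rel=0.02)
    assert state.total_live == pytest.approx(10_000 + 0.5 * 10**6, rel=0.05)
    assert state.n == pytest.approx(0.0, abs=0.01)


def test_persisters_untouched_by_antibiotic_when_switching_off(rng):
    eng = Engine(
        pd_params=PharmacodynamicParams(b_max=0.0),
        kernel=build_mutation_kernel(m=0.0),
    )
    state = PopulationState.ancestral(n_regular=0, n_persister=500, n=1.0)
    for _ in range(20):
        step(state, 400.0, eng, rng)
    assert state.persister[0] == 500  # a(n=1)=0, b_max=0: nothing can move them


def test_counts_stay_nonnegative_and_nutrient_in_bounds(engine, rng):
    state = PopulationState.ancestral(n_regular=50_000, n_persister=10, n=0.9)
    for i in range(100):
        step(state, 8.0 if i % 3 else 0.0, engine, rng)
        assert (state.regular >= 0).all() and (state.persister >= 0).all()
        assert 0.0 <= state.n <= 1.0


def test_deplete_nutrients_arithmetic():
    state = PopulationState.ancestral(n=0.5)
    deplete_nutrients(state, 0, 10**6)
    assert state.n == 0.5
    deplete_nutrients(state, 10**5, 10**6)
    assert state.n == pytest.approx(0.4)
    deplete_nutrients(state, -10**5, 10**6)  # killing does not replenish
    assert state.n == pytest.approx(0.4)
    state.n = 1.0
    deplete_nutrients(state, 10**6, 10**6)
    assert state.n == 0.0


def test_dilute_identity_and_validation(rng):
    state = PopulationState.ancestral(n_regular=1234, n_persister=7, n=0.2)
    dilute(state, 1.0, 0.8, rng)
    assert state.regular[0] == 1234 and state.persister[0] == 7
    assert state.n == 0.8
    with pytest.raises(InvalidParameterError):
        dilute(state, 0.0, 1.0, rng)
    with pytest.raises(InvalidParameterError):
        dilute(state, 1.2, 1.0, rng)


def test_dilute_sampling_expectation():
    kept = []
    for s in range(200):
        rng = np.random.default_rng(s)
        state = PopulationState.ancestral(n_regular=10**6, n_persister=0, n=0.0)
        dilute(state, 0.01, 1.0, rng)
        kept.append(state.total_live)
    mean = np.mean(kept)
    se = np.sqrt(10**4 * 0.99 / 200)
    assert abs(mean - 10**4) < 4 * se


def test_dilute_discards_dead_cells_proportionally(rng):
    state = PopulationState.ancestral(n_regular=10**5, n_persister=0, n=0.0)
    state.cumulative_dead = 9 * 10**5
    dilute(state, 0.1, 1.0, rng)
    total_kept = state.total_live + state.cumulative_dead
    assert total_kept == 10**5  # round(0.1 * 1e6)
    assert state.total_live == pytest.approx(10**4, rel=0.1)


def test_determinism_identical_seed_identical_trajectory(engine):
    def run(seed):
        rng = np.random.default_rng(seed)
        state = PopulationState.ancestral(n_regular=5000, n_persister=3, n=1.0)
        for i in range(50):
            step(state, 8.0 if i > 25 else 0.0, engine, rng)
        return state

    a, b = run(42), run(42)
    np.testing.assert_array_equal(a.regular, b.regular)
    np.testing.assert_array_equal(a.persister, b.persister)
    assert a.n == b.n and a.cumulative_dead == b.cumulative_dead
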