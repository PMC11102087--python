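"""Tests for the biphasic time-kill model, generator, and fitter."""

import math

import numpy as np
import pytest

from persevo import (
    InvalidParameterError,
    biphasic_survival,
    derive_engine_parameters,
    fit_biphasic,
    generate_synthetic_timekill,
)
from persevo.timekill import fits_to_frame


def test_biphasic_survival_reference_values():
    assert biphasic_survival(0.0, 1e-4, 13.8, 0.1) == 1.0
    assert biphasic_survival(3.0, 1.0, 5.0, 0.1) == pytest.approx(math.exp(-0.3))
    # high dose, 5 h: the fast phase is extinct, only persisters remain
    assert biphasic_survival(5.0, 1e-4, 13.8, 0.1) == pytest.approx(
        1e-4 * math.exp(-0.5), rel=1e-6
    )


def test_biphasic_survival_monotone_and_validated():
    taus = np.linspace(0, 10, 50)
    vals = biphasic_survival(taus, 1e-3, 6.0, 0.2)
    assert (np.diff(vals) < 0).all()
    # large-tau limit is the persister exponential
    assert biphasic_survival(40.0, 1e-3, 6.0, 0.2) == pytest.approx(
        1e-3 * math.exp(-8.0), rel=1e-6
    )
    with pytest.raises(InvalidParameterError):
        biphasic_survival(1.0, 2.0, 6.0, 0.2)
    with pytest.raises(InvalidParameterError):
        biphasic_survival(1.0, 0.5, 0.1, 6.0)  # kn < kp
    with pytest.raises(InvalidParameterError):
        biphasic_survival(-1.0, 0.5, 6.0, 0.2)


def test_generator_shapes_and_determinism():
    truth = {"c1": (1e-3, 6.0, 0.2), "c2": (1e-4, 10.0, 0.1)}
    d1 = generate_synthetic_timekill(truth, replicates=3, noise_sd=0.2, seed=5)
    d2 = generate_synthetic_timekill(truth, replicates=3, noise_sd=0.2, seed=5)
    assert d1.equals(d2)
    assert len(d1) == 2 * 3 * 6
    # the tau = 0 normalization point is exact
    assert (d1.loc[d1["time_h"] == 0, "surviving_fraction"] == 1.0).all()


def test_generator_noiseless_matches_model():
    truth = {"c": (1e-3, 6.0, 0.2)}
    data = generate_synthetic_timekill(truth, replicates=1, noise_sd=0.0, seed=0)
    expected = biphasic_survival(data["time_h"].to_numpy(), *truth["c"])
    np.testing.assert_allclose(data["surviving_fraction"], expected, rtol=1e-12)


def test_fit_recovers_noiseless_truth_exactly():
    truth = {"c": (1e-3, 6.0, 0.2)}
    data = generate_synthetic_timekill(truth, replicates=1, noise_sd=0.0, seed=0)
    fit = fit_biphasic(data)["c"]
    assert fit.converged
    assert fit.p0 == pytest.approx(1e-3, rel=1e-6)
    assert fit.kn == pytest.approx(6.0, rel=1e-6)
    assert fit.kp == pytest.approx(0.2, rel=1e-6)


def test_fit_flags_single_phase_data():
    data = generate_synthetic_timekill({"c": (1.0, 5.0, 0.3)}, replicates=1, seed=0)
    fit = fit_biphasic(data)["c"]
    assert not fit.kn_identifiable  # no fast phase to estimate
    assert fit.kp == pytest.approx(0.3, rel=1e-4)


def test_fit_input_validation():
    data = generate_synthetic_timekill({"c": (1e-3, 6.0, 0.2)}, times=(0, 1, 2), seed=0)
    with pytest.raises(InvalidParameterError):
        fit_biphasic(data)  # < 4 distinct time points
    bad = data.copy()
    bad.loc[0, "surviving_fraction"] = -0.1
    with pytest.raises(InvalidParameterError):
        fit_biphasic(bad)


def test_fit_excludes_zero_fractions():
    data = generate_synthetic_timekill({"c": (1e-3, 6.0, 0.2)}, replicates=1, seed=0)
    data.loc[data["time_h"] == 8.0, "surviving_fraction"] = 0.0
    fit = fit_biphasic(data)["c"]
    assert fit.n_excluded == 1
    assert fit.converged


def test_fit_with_replicate_offsets_absorbs_replicate_shifts():
    truth = {"c": (1e-3, 6.0, 0.2)}
    data = generate_synthetic_timekill(
        truth, replicates=3, noise_sd=0.0, replicate_offset_sd=0.3, seed=11
    )
    with_off = fit_biphasic(data, replicate_offsets=True)["c"]
    without = fit_biphasic(data, replicate_offsets=False)["c"]
    # the relative (sum-to-zero) component of the shifts is fully absorbed;
    # only the unidentifiable common shift remains, so the residual drops by
    # orders of magnitude and parameters land near truth
    assert with_off.rss < without.rss / 100
    assert with_off.kp == pytest.approx(0.2, rel=0.05)
    assert with_off.kn == pytest.approx(6.0, rel=0.25)
    assert 1e-3 / 3 < with_off.p0 < 3e-3  # common shift bounds the P0 bias


def test_derive_engine_parameters_mapping():
    data = generate_synthetic_timekill({"c": (1e-4, 13.8, 0.1)}, replicates=1, seed=0)
    fit = fit_biphasic(data)["c"]
    derived = derive_engine_parameters(fit, dose=400.0, nutrient=1.0)
    assert derived["log10_kill_rate"] == pytest.approx(13.8 / math.log(10), rel=1e-4)
    assert derived["log10_kill_rate"] == pytest.approx(5.99, abs=0.01)
    # the model's own first-phase rate at 400 ug/ml, fresh medium: ~6.12
    assert derived["model_log10_kill_rate"] == pytest.approx(6.123, abs=0.001)
    assert derived["persister_exit_rate"] == pytest.approx(0.1, rel=1e-4)
    assert derived["model_backward_switch_rate"] == pytest.approx(0.1)


def test_fits_to_frame_schema():
    data = generate_synthetic_timekill({"a": (1e-3, 6.0, 0.2)}, replicates=1, seed=0)
    frame = fits_to_frame(fit_biphasic(data))
    assert list(frame["condition"]) == ["a"]
    assert {"P0", "kn", "kp", "converged", "rss"} <= set(frame.columns)
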