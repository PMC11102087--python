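"""Biphasic time-kill curves: forward model, synthetic data, and fitting.

Survival of a population containing a small persister subpopulation under a
bactericidal antibiotic follows a biphasic decay,

    S(tau) = (1 - P0) * exp(-kn * tau) + P0 * exp(-kp * tau),

with ``P0`` the initial persister fraction, ``kn`` the kill rate of regular
cells (fast first phase) and ``kp`` the residual kill rate of persisters
(slow second phase, limited by persister awakening).  Fitting the
log10-transformed surviving fraction against treatment time recovers
(P0, kn, kp); the fast-phase rate calibrates the pharmacodynamic floor
psi_min (through kn / ln 10) and the slow phase the persister exit rate b.

The mixed-model treatment of replicates is approximated by per-replicate
additive offsets on the log10 scale with a sum-to-zero constraint.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InvalidParameterError
from .pharmacodynamics import (
    PharmacodynamicParams,
    backward_switch_rate,
    net_growth_rate,
    nutrient_kill_modifier,
)

__all__ = [
    "BiphasicFit",
    "biphasic_survival",
    "generate_synthetic_timekill",
    "fit_biphasic",
    "derive_engine_parameters",
    "fits_to_frame",
]

_LN10 = math.log(10.0)

REQUIRED_COLUMNS = ("condition", "replicate", "time_h", "surviving_fraction")


@dataclass
class BiphasicFit:
    """Fitted biphasic kill-curve parameters for one condition."""

    p0: float
    kn: float
    kp: float
    rss: float
    converged: bool
    kn_identifiable: bool = True
    n_obs: int = 0
    n_excluded: int = 0


def biphasic_survival(tau, p0: float, kn: float, kp: float):
    """Surviving fraction S(tau) of the two-subpopulation decay model."""
    if not (0.0 <= p0 <= 1.0):
        raise InvalidParameterError("P0 must lie in [0, 1]")
    if not (kn >= kp >= 0.0):
        raise InvalidParameterError("rates must satisfy kn >= kp >= 0")
    tau = np.asarray(tau, dtype=float)
    if (tau < 0).any():
        raise InvalidParameterError("tau must be >= 0")
    out = (1.0 - p0) * np.exp(-kn * tau) + p0 * np.exp(-kp * tau)
    return float(out) if out.ndim == 0 else out


def generate_synthetic_timekill(
    truth: dict[str, tuple[float, float, float]],
    times=(0.0, 1.0, 2.0, 3.0, 5.0, 8.0),
    replicates: int = 3,
    noise_sd: float = 0.0,
    replicate_offset_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic kill-curve measurements for testing the fitter.

    ``truth`` maps condition labels to (P0, kn, kp).  Observed log10 survival
    is the model value plus a per-replicate offset (N(0, replicate_offset_sd))
    plus Gaussian noise (N(0, noise_sd)); the tau = 0 row is the normalization
    point and is exactly 1.  Deterministic given ``seed``.
    """
    if noise_sd < 0 or replicate_offset_sd < 0:
        raise InvalidParameterError("noise scales must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, (p0, kn, kp) in truth.items():
        for rep in range(replicates):
            offset = rng.normal(0.0, replicate_offset_sd) if replicate_offset_sd else 0.0
            for t in times:
                s = biphasic_survival(t, p0, kn, kp)
                if t > 0:
                    log_s = math.log10(s) + offset
                    if noise_sd:
                        log_s += rng.normal(0.0, noise_sd)
                    s = 10.0**log_s
                rows.append((condition, rep, float(t), s))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


_START_LOG10_P0 = (-1.5, -3.0, -4.5)
_START_KN = (2.0, 10.0)
_START_KP = (0.05, 0.5)


def _fit_condition(
    grp: pd.DataFrame, replicate_offsets: bool
) -> BiphasicFit:
    n_excluded = int((grp["surviving_fraction"] == 0).sum())
    grp = grp[grp["surviving_fraction"] > 0]
    t = grp["time_h"].to_numpy(float)
    y = np.log10(grp["surviving_fraction"].to_numpy(float))
    if np.unique(t).size < 4:
        raise InvalidParameterError("need >= 4 distinct time points per condition")
    reps = grp["replicate"].to_numpy()
    rep_ids = np.unique(reps)
    use_offsets = replicate_offsets and rep_ids.size > 1
    # offsets apply to post-baseline observations; sum-to-zero via last = -sum(rest)
    n_off = rep_ids.size - 1 if use_offsets else 0
    rep_pos = np.searchsorted(rep_ids, reps)
    post = t > 0

    def residuals(theta):
        log10_p0, log_kn, log_kp = theta[:3]
        p0 = min(10.0**log10_p0, 1.0)
        kn = math.exp(log_kn)
        kp = math.exp(log_kp)
        model = (1.0 - p0) * np.exp(-kn * t) + p0 * np.exp(-kp * t)
        pred = np.log10(np.maximum(model, 1e-300))
        if n_off:
            offs = np.append(theta[3:], -theta[3:].sum())
            pred = pred + np.where(post, offs[rep_pos], 0.0)
        return pred - y

    best = None
    for lp0, kn0, kp0 in itertools.product(_START_LOG10_P0, _START_KN, _START_KP):
        theta0 = np.concatenate(([lp0, math.log(kn0), math.log(kp0)], np.zeros(n_off)))
        sol = least_squares(residuals, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol

    log10_p0, log_kn, log_kp = best.x[:3]
    p0 = min(10.0**log10_p0, 1.0)
    kn, kp = math.exp(log_kn), math.exp(log_kp)
    if kp > kn:  # phases are exchangeable in the model; report fast phase as kn
        kn, kp = kp, kn
        p0 = 1.0 - p0
    rss = float(2.0 * best.cost)
    kn_identifiable = (1.0 - p0) > 1e-6
    return BiphasicFit(
        p0=p0,
        kn=kn,
        kp=kp,
        rss=rss,
        converged=bool(best.success and np.isfinite(best.x).all()),
        kn_identifiable=kn_identifiable,
        n_obs=len(grp),
        n_excluded=n_excluded,
    )


def fit_biphasic(
    dataset: pd.DataFrame, replicate_offsets: bool = True
) -> dict[str, BiphasicFit]:
    """Least-squares biphasic fits on the log10 scale, one per condition.

    Multi-start (12 starting points over a log-spaced grid) with positivity
    enforced through a (log10 P0, log kn, log kp) parameterization.  Rows
    with surviving fraction exactly 0 (below plating detection) are excluded
    and counted; negative fractions are input errors.  Non-convergence is
    reported through the ``converged`` flag, not raised.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in dataset.columns]
    if missing:
        raise InvalidParameterError(f"dataset missing columns: {missing}")
    if (dataset["surviving_fraction"] < 0).any():
        raise InvalidParameterError("surviving fractions must be >= 0")
    return {
        str(cond): _fit_condition(grp, replicate_offsets)
        for cond, grp in dataset.groupby("condition", sort=True)
    }


def fits_to_frame(fits: dict[str, BiphasicFit]) -> pd.DataFrame:
    """Fit results as a tidy table (condition, P0, kn, kp, converged, rss)."""
    return pd.DataFrame(
        [
            {
                "condition": cond,
                "P0": f.p0,
                "kn": f.kn,
                "kp": f.kp,
                "converged": f.converged,
                "kn_identifiable": f.kn_identifiable,
                "rss": f.rss,
                "n_obs": f.n_obs,
                "n_excluded": f.n_excluded,
            }
            for cond, f in fits.items()
        ]
    )


def derive_engine_parameters(
    fit: BiphasicFit,
    dose: float,
    nutrient: float,
    params: PharmacodynamicParams | None = None,
    mic: float = 2.0,
) -> dict[str, float]:
    """Map a biphasic fit onto the simulator's rate scales.

    The fast-phase rate ``kn`` (natural-log scale) corresponds to a log10
    kill rate ``kn / ln 10``, directly comparable with ``-psi(dose) *
    eta(nutrient)``; the slow-phase rate ``kp`` is the persister-exit-limited
    residual kill rate, comparable with the backward switching rate
    ``b(nutrient)``.
    """
    if not fit.converged:
        raise InvalidParameterError("cannot derive parameters from an unconverged fit")
    params = params if params is not None else PharmacodynamicParams()
    psi = net_growth_rate(dose, mic, params)
    eta = nutrient_kill_modifier(nutrient, params)
    return {
        "log10_kill_rate": fit.kn / _LN10,
        "model_log10_kill_rate": -psi * eta,
        "persister_exit_rate": fit.kp,
        "model_backward_switch_rate": backward_switch_rate(nutrient, params),
    }
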