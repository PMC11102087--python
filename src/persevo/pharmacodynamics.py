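"""Closed-form pharmacodynamic rate functions.

The net growth rate of a bacterial population exposed to a bactericidal
antibiotic is described by a four-parameter Hill-type dose-response curve

    psi(AB) = psi_max - (psi_max - psi_min) * r / (r - psi_min/psi_max),
    r = (AB / MIC)**kappa_AB

where ``psi`` is the change in log10(cell count) per hour, ``psi_max`` the
drug-free growth rate, ``psi_min`` the maximal kill rate at saturating drug,
and ``MIC`` the minimum inhibitory concentration (the zero crossing of the
curve: growth below the MIC, killing above it).

Killing is further attenuated at low nutrient levels — aminoglycosides kill
metabolically active cells — through a Hill modifier

    eta(n) = 1 / (1 + (n_half / n)**kappa_n),  eta(0) = 0,

with ``n`` the nutrient level on a 0 (spent medium) to 1 (fresh medium)
scale.  Per-interval division and death probabilities used by the stochastic
engine, and the nutrient-dependent persister switching rates

    a(n) = a_max * (1 - n)   (regular -> persister, peaks in stationary phase)
    b(n) = b_max * n         (persister -> regular, peaks in fresh medium)

are all derived from these forms.  Every function here is pure and
deterministic; randomness lives in :mod:`persevo.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ContractViolationError, InvalidParameterError

__all__ = [
    "PharmacodynamicParams",
    "net_growth_rate",
    "nutrient_kill_modifier",
    "division_probability",
    "death_probability",
    "forward_switch_rate",
    "backward_switch_rate",
]

_LOG2_10 = math.log2(10.0)


@dataclass(frozen=True)
class PharmacodynamicParams:
    """Parameters of the pharmacodynamic and switching-rate functions.

    Attributes
    ----------
    psi_max : float
        Maximum net growth rate, log10 cells/h (drug-free, fresh medium).
    psi_min : float
        Minimum net growth rate (maximal killing), log10 cells/h; negative.
    kappa_ab : float
        Hill coefficient of the antibiotic dose response.
    kappa_n : float
        Hill coefficient of the nutrient dependence of killing.
    n_half : float
        Nutrient level at which killing is half-maximal.
    b_max : float
        Maximum persister-to-regular switching rate, 1/h (fresh medium).
    dt : float
        Time step of the discrete stochastic update, hours.
    """

    psi_max: float = 0.6
    psi_min: float = -10.0
    kappa_ab: float = 1.0
    kappa_n: float = 1.0
    n_half: float = 0.5
    b_max: float = 0.1
    dt: float = 0.5

    def __post_init__(self) -> None:
        if not (self.psi_max > 0):
            raise InvalidParameterError("psi_max must be > 0")
        if not (self.psi_min < 0):
            raise InvalidParameterError("psi_min must be < 0")
        if not (self.kappa_ab > 0 and self.kappa_n > 0):
            raise InvalidParameterError("Hill coefficients must be > 0")
        if not (0 < self.n_half <= 1):
            raise InvalidParameterError("n_half must lie in (0, 1]")
        if self.b_max < 0:
            raise InvalidParameterError("b_max must be >= 0")
        if not (self.dt > 0):
            raise InvalidParameterError("dt must be > 0")


DEFAULT_PARAMS = PharmacodynamicParams()


def _check_nutrient(n: float) -> None:
    if not (0.0 <= n <= 1.0):
        raise InvalidParameterError(f"nutrient level must lie in [0, 1], got {n}")


def net_growth_rate(
    ab: float, mic: float, params: PharmacodynamicParams = DEFAULT_PARAMS
) -> float:
    """Net growth rate psi(AB) in log10 cells/h for a class with the given MIC.

    Positive below the MIC, zero exactly at ``ab == mic``, negative above,
    saturating at ``psi_min`` as ``ab`` grows.
    """
    if not math.isfinite(ab) or ab < 0:
        raise InvalidParameterError(f"antibiotic concentration must be finite and >= 0, got {ab}")
    if not math.isfinite(mic) or mic <= 0:
        raise InvalidParameterError(f"MIC must be finite and > 0, got {mic}")
    if ab == 0.0:
        return params.psi_max
    r = (ab / mic) ** params.kappa_ab
    return params.psi_max - (params.psi_max - params.psi_min) * r / (
        r - params.psi_min / params.psi_max
    )


def nutrient_kill_modifier(
    n: float, params: PharmacodynamicParams = DEFAULT_PARAMS
) -> float:
    """Hill modifier eta(n) in [0, 1) scaling the kill rate by nutrient level.

    ``eta(0)`` is defined as the limit value 0: without nutrients cells are
    dormant and the drug does not kill.
    """
    _check_nutrient(n)
    if n == 0.0:
        return 0.0
    return 1.0 / (1.0 + (params.n_half / n) ** params.kappa_n)


def division_probability(
    ab: float, mic: float, n: float, params: PharmacodynamicParams = DEFAULT_PARAMS
) -> float:
    """Per-cell probability of dividing within one time step.

    ``log2(10**(psi*dt)) * n``: the expected number of doublings in ``dt``,
    damped by the logistic nutrient factor ``n`` and capped at 1 so it can be
    used as a binomial probability.  Requires psi(ab) >= 0; returns 0 exactly
    at the MIC (psi == 0).
    """
    _check_nutrient(n)
    psi = net_growth_rate(ab, mic, params)
    if psi < 0:
        raise ContractViolationError(
            "division_probability called in the killing regime (psi < 0)"
        )
    return min(psi * params.dt * _LOG2_10 * n, 1.0)


def death_probability(
    ab: float, mic: float, n: float, params: PharmacodynamicParams = DEFAULT_PARAMS
) -> float:
    """Per-cell probability of dying within one time step.

    ``1 - 10**(psi * eta(n) * dt)`` for psi < 0, i.e. exponential decay of the
    population at the nutrient-modulated kill rate.
    """
    _check_nutrient(n)
    psi = net_growth_rate(ab, mic, params)
    if psi >= 0:
        raise ContractViolationError(
            "death_probability called in the growth regime (psi >= 0)"
        )
    eta = nutrient_kill_modifier(n, params)
    return 1.0 - 10.0 ** (psi * eta * params.dt)


def forward_switch_rate(n: float, a_max: float) -> float:
    """Regular-to-persister switching rate a(n) = a_max * (1 - n), 1/h."""
    _check_nutrient(n)
    if a_max < 0:
        raise InvalidParameterError("a_max must be >= 0")
    return a_max * (1.0 - n)


def backward_switch_rate(
    n: float, params: PharmacodynamicParams = DEFAULT_PARAMS
) -> float:
    """Persister-to-regular switching rate b(n) = b_max * n, 1/h."""
    _check_nutrient(n)
    return params.b_max * n
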