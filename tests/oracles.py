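"""Independent reference implementations used as test oracles.

These deliberately share no code with the production engine: the SSA oracle
is an exact event-driven (Gillespie) simulation of the per-cell
continuous-time chain for death and persister switching, and the kernel
oracle enumerates mutation weights by brute force.
"""

from __future__ import annotations

import math

import numpy as np

LN10 = math.log(10.0)


def exact_ssa_death_switching(
    regular: list[int],
    persister: list[int],
    death_rates: list[float],
    forward_rates: list[float],
    backward_rate: float,
    t_end: float,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Exact stochastic simulation of death + two-way switching, no growth.

    Per class c, each regular cell dies at ``death_rates[c]`` and switches to
    the persister state at ``forward_rates[c]``; each persister switches back
    at ``backward_rate``.  Returns final (regular, persister) counts.
    """
    R = list(regular)
    P = list(persister)
    k = len(R)
    t = 0.0
    while True:
        rates = []
        for c in range(k):
            rates.append(R[c] * death_rates[c])
            rates.append(R[c] * forward_rates[c])
            rates.append(P[c] * backward_rate)
        total = sum(rates)
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        acc = 0.0
        for idx, r in enumerate(rates):
            acc += r
            if u < acc:
                c, event = divmod(idx, 3)
                if event == 0:
                    R[c] -= 1
                elif event == 1:
                    R[c] -= 1
                    P[c] += 1
                else:
                    P[c] -= 1
                    R[c] += 1
                break
    return R, P


def enumerate_kernel_weights() -> dict[tuple[int, int, int, int], float]:
    """Brute-force beneficial-mutation weights 10**-(dR+dP) over the lattice."""
    weights = {}
    for r1 in range(6):
        for p1 in range(5):
            for r2 in range(6):
                for p2 in range(5):
                    if (r2, p2) == (r1, p1) or r2 < r1 or p2 < p1:
                        continue
                    weights[(r1, p1, r2, p2)] = 10.0 ** -((r2 - r1) + (p2 - p1))
    return weights


def logistic_recursion(n0_cells: float, nutrient: float, K: float, psi_max: float, dt: float, n_steps: int) -> float:
    """Deterministic expectation of drug-free growth with nutrient depletion."""
    N = n0_cells
    n = nutrient
    for _ in range(n_steps):
        births = N * min(psi_max * dt * math.log2(10.0) * n, 1.0)
        N += births
        n = max(n - births / K, 0.0)
    return N
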