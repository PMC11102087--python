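"""The 30-class genotype lattice and the beneficial-mutation kernel.

Each mutant class pairs a resistance level ``l_res`` (log2 fold change of the
MIC relative to the ancestor, 0..5) with a persistence level ``l_per``
(log10 fold change of the maximum regular->persister switching rate, 0..4).
The ancestor is (0, 0) with MIC 2 ug/ml and a_max = 10^-4.5 /h.

Mutations act only on newly produced daughter cells and are strictly
beneficial (levels never decrease).  The relative weight of a jump from class
i to class j decays tenfold per lattice unit,

    w_ij = 10**-((l_res_j - l_res_i) + (l_per_j - l_per_i)),

an exponential distribution of fitness effects over the discrete level grid.
Weights are scaled so that the total per-division mutation probability of a
class with at least one beneficial target equals ``m`` (row normalization,
the default) or so that the ancestor row equals ``m`` with one global
constant shared by all rows (``normalization="global"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "MutantClass",
    "MutationKernel",
    "N_RES_LEVELS",
    "N_PER_LEVELS",
    "N_CLASSES",
    "ANCESTOR_MIC",
    "ANCESTOR_LOG10_A_MAX",
    "build_classes",
    "class_index",
    "build_mutation_kernel",
    "sample_daughter_mutations",
    "kernel_to_dataframe",
]

N_RES_LEVELS = 6
N_PER_LEVELS = 5
N_CLASSES = N_RES_LEVELS * N_PER_LEVELS
ANCESTOR_MIC = 2.0
ANCESTOR_LOG10_A_MAX = -4.5
DEFAULT_MUTATION_RATE = 1e-4


@dataclass(frozen=True)
class MutantClass:
    """One genotype class: a (resistance level, persistence level) pair."""

    l_res: int
    l_per: int

    def __post_init__(self) -> None:
        if not (0 <= self.l_res < N_RES_LEVELS):
            raise InvalidParameterError(f"l_res must lie in 0..{N_RES_LEVELS - 1}")
        if not (0 <= self.l_per < N_PER_LEVELS):
            raise InvalidParameterError(f"l_per must lie in 0..{N_PER_LEVELS - 1}")

    @property
    def mic(self) -> float:
        """MIC in ug/ml: ancestral 2 ug/ml doubled per resistance level."""
        return ANCESTOR_MIC * 2.0**self.l_res

    @property
    def a_max(self) -> float:
        """Maximum forward switching rate, 1/h: tenfold per persistence level."""
        return 10.0 ** (ANCESTOR_LOG10_A_MAX + self.l_per)

    @property
    def label(self) -> str:
        return f"R{self.l_res}P{self.l_per}"


def build_classes() -> tuple[MutantClass, ...]:
    """All 30 classes in a fixed order: l_res-major, l_per-minor.

    Index 0 is the ancestor (0, 0); the index of (r, p) is ``r*5 + p``.
    """
    return tuple(
        MutantClass(r, p) for r in range(N_RES_LEVELS) for p in range(N_PER_LEVELS)
    )


def class_index(l_res: int, l_per: int) -> int:
    """Index of class (l_res, l_per) in the :func:`build_classes` ordering."""
    MutantClass(l_res, l_per)  # domain check
    return l_res * N_PER_LEVELS + l_per


@dataclass(frozen=True)
class MutationKernel:
    """Per-division mutation probabilities between classes.

    ``rates[i, j]`` is the probability that a daughter born in class i is
    assigned to class j != i.  Rows of the terminal class (and, under
    ablations, of classes with no permitted targets) are all zero.
    """

    rates: np.ndarray
    m: float
    row_total: np.ndarray = field(init=False, repr=False)
    target_probs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (N_CLASSES, N_CLASSES):
            raise InvalidParameterError("kernel must be 30x30")
        if (rates < 0).any():
            raise InvalidParameterError("kernel entries must be >= 0")
        totals = rates.sum(axis=1)
        cond = np.zeros_like(rates)
        nz = totals > 0
        cond[nz] = rates[nz] / totals[nz, None]
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "row_total", totals)
        object.__setattr__(self, "target_probs", cond)


def _beneficial_weights(
    allow_persistence: bool, allow_resistance: bool
) -> np.ndarray:
    classes = build_classes()
    w = np.zeros((N_CLASSES, N_CLASSES))
    for i, src in enumerate(classes):
        for j, dst in enumerate(classes):
            dr = dst.l_res - src.l_res
            dp = dst.l_per - src.l_per
            if i == j or dr < 0 or dp < 0:
                continue
            if dp > 0 and not allow_persistence:
                continue
            if dr > 0 and not allow_resistance:
                continue
            w[i, j] = 10.0 ** -(dr + dp)
    return w


def build_mutation_kernel(
    m: float = DEFAULT_MUTATION_RATE,
    allow_persistence: bool = True,
    allow_resistance: bool = True,
    normalization: str = "row",
) -> MutationKernel:
    """Build the beneficial-mutation kernel at overall per-division rate ``m``.

    Parameters
    ----------
    m : float
        Overall mutation probability per cell division.
    allow_persistence, allow_resistance : bool
        Ablation switches: with ``allow_persistence=False`` mutations may only
        raise the resistance level (persistence held at the ancestral level),
        and symmetrically.  Both off is an invalid configuration.
    normalization : {"row", "global"}
        "row": every row with at least one permitted target sums to ``m``
        (the per-division mutation probability is the same for all non-terminal
        genotypes).  "global": one shared scale constant, anchored so the
        ancestor row sums to ``m``.
    """
    if m < 0:
        raise InvalidParameterError("m must be >= 0")
    if not (allow_persistence or allow_resistance):
        raise InvalidParameterError(
            "at least one of allow_persistence / allow_resistance must be set"
        )
    w = _beneficial_weights(allow_persistence, allow_resistance)
    totals = w.sum(axis=1)
    if normalization == "row":
        nz = totals > 0
        w[nz] *= m / totals[nz, None]
    elif normalization == "global":
        w *= m / totals[0]
    else:
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    return MutationKernel(rates=w, m=m)


def sample_daughter_mutations(
    n_divisions: int,
    source_index: int,
    kernel: MutationKernel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign ``n_divisions`` daughters of one class to classes, with mutation.

    Returns a length-30 integer vector of daughter counts per class whose sum
    equals ``n_divisions`` (non-mutants stay in the source class).
    """
    if n_divisions < 0:
        raise InvalidParameterError("n_divisions must be >= 0")
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    if n_divisions == 0:
        return counts
    p_mut = kernel.row_total[source_index]
    n_mut = rng.binomial(n_divisions, p_mut) if p_mut > 0 else 0
    counts[source_index] = n_divisions - n_mut
    if n_mut:
        counts += rng.multinomial(n_mut, kernel.target_probs[source_index])
    return counts


def kernel_to_dataframe(kernel: MutationKernel) -> pd.DataFrame:
    """Kernel as a 30x30 table with class labels (for CSV export)."""
    labels = [c.label for c in build_classes()]
    return pd.DataFrame(kernel.rates, index=labels, columns=labels)
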