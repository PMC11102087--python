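"""Multivariable linear regressions on simulation and kill-curve outputs.

The analyses are ordinary least-squares fits of transformed responses on the
antibiotic dose and nutrient level as continuous covariates:

- log10(survival after 8 h) ~ dose + nutrient + dose:nutrient  (time-kill)
- log10(surviving fraction) ~ dose + nutrient
- proportion of extinct populations ~ dose + nutrient
- log2(MIC fold change) ~ dose + nutrient
- log10(persistence fold change) ~ dose + nutrient

Transform conventions: MIC fold changes are log2, persistence fold changes
log10, survival log10.  The extinction model is fitted linearly on
proportions (not logistic), and p-values are classical two-sided t tests
without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidParameterError

__all__ = ["RegressionSpec", "fit_linear_model"]


@dataclass(frozen=True)
class RegressionSpec:
    """Response column, covariate columns, and optional interaction term."""

    response: str
    covariates: tuple[str, ...] = ("dose", "nutrient")
    interaction: bool = False


def _design(table: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(table))}, index=table.index)
    for cov in spec.covariates:
        X[cov] = table[cov].astype(float)
    if spec.interaction:
        if len(spec.covariates) != 2:
            raise InvalidParameterError("interaction requires exactly two covariates")
        a, b = spec.covariates
        X[f"{a}:{b}"] = X[a] * X[b]
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    bad = []
    for col in X.columns:
        reduced = X.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(col)
    return bad


def fit_linear_model(table: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """OLS fit; returns a tidy table (term, estimate, se, t, p).

    Raises an explicit error naming the collinear columns on rank-deficient
    designs, and on missing responses.
    """
    missing = [c for c in (spec.response, *spec.covariates) if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"table missing columns: {missing}")
    y = table[spec.response].astype(float)
    if y.isna().any():
        raise InvalidParameterError(f"missing values in response {spec.response!r}")
    X = _design(table, spec)
    if len(table) < X.shape[1] + 2:
        raise InvalidParameterError("too few rows for the requested model")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise InvalidParameterError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X)}"
        )
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    return pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
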