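"""Covariate-balance diagnostics: per-covariate SMD and Mahalanobis balance.

Weighting moves only the group mean differences: SMD denominators and the
Mahalanobis covariance matrix are computed unweighted over the included
sample, so crude and weighted values share one scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import BalanceError
from .propensity import model_columns
from .weighting import WeightAssignment, crude_weights


@dataclass
class BalanceReport:
    """Balance metrics for one weighted sample."""

    smd_by_covariate: pd.Series  # reported x100
    mb: float
    n_used: int


def smd(values: np.ndarray, exposure: np.ndarray, weights: np.ndarray | None = None,
        name: str = "covariate") -> float:
    """Standardized mean difference x100, exposed minus unexposed.

    Numerator: weighted group means.  Denominator: unweighted SD (ddof=1)
    of the covariate over the whole sample passed in.
    """
    x = np.asarray(values, dtype=float)
    z = np.asarray(exposure).astype(bool)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w[z].sum() <= 0 or w[~z].sum() <= 0:
        raise BalanceError("both groups need positive total weight")
    sd = x.std(ddof=1)
    if sd == 0:
        raise BalanceError(f"SMD undefined: covariate {name!r} is constant")
    mean_exp = np.average(x[z], weights=w[z])
    mean_unexp = np.average(x[~z], weights=w[~z])
    return float(100.0 * (mean_exp - mean_unexp) / sd)


def weighted_smd(cohort: Cohort, wa: WeightAssignment, covariate: str) -> float:
    """SMD x100 for one covariate under an assignment's weights, included subjects only."""
    mask = wa.included
    return smd(
        cohort.data[covariate].to_numpy(dtype=float)[mask],
        cohort.exposure[mask],
        wa.weights[mask],
        name=covariate,
    )


def smd_table(cohort: Cohort, wa: WeightAssignment) -> pd.Series:
    """SMD x100 per covariate; NaN where a covariate is constant in the included sample."""
    values = {}
    for name in cohort.covariate_names:
        try:
            values[name] = weighted_smd(cohort, wa, name)
        except BalanceError:
            values[name] = np.nan
    return pd.Series(values, name=wa.method_label)


def mahalanobis_balance(
    cohort: Cohort, wa: WeightAssignment, covariate_names: list[str] | None = None
) -> float:
    """Quadratic form d' S^-1 d over the model covariate columns.

    d is the vector of weighted group mean differences; S the unweighted
    covariance matrix over the included sample.  One level per exhaustive
    indicator block is dropped to keep S invertible; a singular S falls back
    to the pseudo-inverse with a warning.
    """
    names = covariate_names if covariate_names is not None else cohort.covariate_names
    cols = model_columns(list(names))
    mask = wa.included
    cols = [c for c in cols if cohort.data.loc[mask, c].nunique() > 1]
    if not cols:
        raise BalanceError("no non-constant covariate columns for MB")
    x = cohort.data.loc[mask, cols].to_numpy(dtype=float)
    z = cohort.exposure[mask].astype(bool)
    w = wa.weights[mask]
    if w[z].sum() <= 0 or w[~z].sum() <= 0:
        raise BalanceError("both groups need positive total weight")
    d = np.average(x[z], axis=0, weights=w[z]) - np.average(x[~z], axis=0, weights=w[~z])
    s = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    # np.linalg.solve happily "solves" a numerically singular system, so gate
    # on the condition number instead of waiting for LinAlgError
    if np.linalg.cond(s) > 1e12:
        warnings.warn("singular covariance matrix in MB; using pseudo-inverse", RuntimeWarning,
                      stacklevel=2)
        sol = np.linalg.pinv(s) @ d
    else:
        sol = np.linalg.solve(s, d)
    return float(d @ sol)


def balance_report(cohort: Cohort, wa: WeightAssignment) -> BalanceReport:
    return BalanceReport(
        smd_by_covariate=smd_table(cohort, wa),
        mb=mahalanobis_balance(cohort, wa),
        n_used=wa.n_used,
    )


def balance_table(cohort: Cohort, assignments: list[WeightAssignment]) -> pd.DataFrame:
    """Covariate rows x method columns of SMD x100, with MB and N-used footer rows."""
    columns = {}
    for wa in assignments:
        col = smd_table(cohort, wa)
        col["MB"] = mahalanobis_balance(cohort, wa)
        col["N used"] = wa.n_used
        columns[wa.method_label] = col
    return pd.DataFrame(columns)


def crude_balance(cohort: Cohort) -> BalanceReport:
    return balance_report(cohort, crude_weights(cohort))
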