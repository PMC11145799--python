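"""Propensity-score estimation: main-effects MLE logistic regression.

One indicator is dropped from each exhaustive block (race; the
complementary eligibility pair) before fitting so the design matrix is
full rank; the score space is unchanged by the choice of reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import Cohort, ELIG_PAIR, RACE_BLOCK
from .exceptions import EstimationError

SCORE_CLIP = (1e-12, 1.0 - 1e-12)


@dataclass
class PSFit:
    """Fitted propensity model: coefficients, per-subject scores, convergence."""

    coefficients: pd.Series
    scores: np.ndarray
    converged: bool
    n_iterations: int
    separation: bool
    design_columns: list[str]


def model_columns(covariate_names: list[str]) -> list[str]:
    """Covariate columns entering the model: reference levels of exhaustive blocks dropped."""
    cols = list(covariate_names)
    if all(name in cols for name in RACE_BLOCK):
        cols.remove(RACE_BLOCK[0])
    if all(name in cols for name in ELIG_PAIR):
        cols.remove(ELIG_PAIR[1])
    return cols


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    # QR with pivoting is not exposed by numpy; flag near-zero R diagonal instead
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    return [names[i] for i in np.where(diag / scale < 1e-10)[0]]


def fit_propensity(cohort: Cohort, covariate_names: list[str] | None = None) -> PSFit:
    """MLE logistic regression of exposure on all covariates (main effects).

    Returns scores for every subject, clipped to the open unit interval.
    ``converged`` is False on iteration cap, detected separation, or a
    score-equation gradient above 1e-6.
    """
    names = covariate_names if covariate_names is not None else cohort.covariate_names
    z = cohort.exposure.astype(float)
    if z.sum() == 0 or z.sum() == len(z):
        raise EstimationError("both exposure groups must be non-empty to fit a propensity model")

    cols = model_columns(names)
    # constant columns (e.g. a rare indicator absent from a resample) carry no
    # information and would only break the rank check — drop them for this fit
    cols = [c for c in cols if cohort.data[c].nunique() > 1]
    x = np.column_stack([np.ones(cohort.n), cohort.data[cols].to_numpy(dtype=float)])
    design_names = ["intercept"] + cols
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, design_names)
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {bad}")

    separation = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.GLM(z, x, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        separation = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    except PerfectSeparationError as exc:  # pragma: no cover - statsmodels warns by default
        raise EstimationError(f"perfect separation in propensity model: {exc}") from exc

    params = np.asarray(res.params, dtype=float)
    probs = np.clip(res.fittedvalues, *SCORE_CLIP)
    gradient = x.T @ (z - probs)
    converged = bool(res.converged) and not separation and np.abs(gradient).max() < 1e-6
    return PSFit(
        coefficients=pd.Series(params, index=design_names),
        scores=np.asarray(probs, dtype=float),
        converged=converged,
        n_iterations=int(res.fit_history["iteration"]),
        separation=separation,
        design_columns=design_names,
    )


def scores_to_csv(fit: PSFit, cohort: Cohort, path) -> None:
    pd.DataFrame({"subject_id": cohort.subject_id, "score": fit.scores}).to_csv(path, index=False)
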