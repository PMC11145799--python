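"""Effect estimation: weighted log-link GLM with cluster-robust errors.

On balanced (weighted) data the outcome is regressed on exposure alone —
intercept plus exposure, no covariate adjustment — with a binomial
log-link family, so the coefficient is a log relative risk.  Weights are
probability weights; standard errors are sandwich estimates clustered on
source_id, so plasmode duplicates of one base row share a cluster.  A
Poisson log-link fit is the fallback when the log-binomial does not
converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import DomainWarning

from .balance import BalanceReport
from .cohort import Cohort
from .exceptions import EstimationError
from .plasmode import SimulatedDataset
from .weighting import WeightAssignment

Z_975 = 1.959964


@dataclass
class EstimateRecord:
    """One replicate x method effect estimate with its diagnostics."""

    method_label: str
    replicate_index: int
    estimate: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    converged: bool
    separation_flag: bool = False
    family_used: str = "binomial"
    balance: BalanceReport | None = None
    scenario_id: str | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "scenario_id",
                "method_label",
                "replicate_index",
                "estimate",
                "robust_se",
                "ci_low",
                "ci_high",
                "p_value",
                "n_used",
                "converged",
                "separation_flag",
                "family_used",
                "error",
            )
        }
        out["mb"] = self.balance.mb if self.balance is not None else np.nan
        return out


def _extract(data) -> Cohort:
    return data.cohort if isinstance(data, SimulatedDataset) else data


def _fit_log_link(y, x, w, groups, family) -> tuple:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        # cov_type with var_weights triggers a SpecificationWarning; the
        # clustered sandwich was verified against a hand-coded oracle.
        warnings.simplefilter("ignore", UserWarning)
        model = sm.GLM(y, x, family=family, var_weights=w)
        p1 = np.average(y[x[:, 1] == 1], weights=w[x[:, 1] == 1])
        p0 = np.average(y[x[:, 1] == 0], weights=w[x[:, 1] == 0])
        p1, p0 = np.clip([p1, p0], 1e-10, 1 - 1e-10)
        start = np.array([np.log(p0), np.log(p1) - np.log(p0)])
        res = model.fit(
            start_params=start,
            maxiter=200,
            cov_type="cluster",
            cov_kwds={"groups": groups},
        )
    return res


def estimate_effect(
    data,
    wa: WeightAssignment,
    replicate_index: int = 0,
    balance: BalanceReport | None = None,
    scenario_id: str | None = None,
) -> EstimateRecord:
    """Fit outcome ~ intercept + exposure by weighted log-link GLM.

    Raises EstimationError when the included sample is single-group or has
    no events.  Nonconvergence of the log-binomial triggers a Poisson-family
    retry; if that also fails the record carries NaN estimate/SE with
    converged=False.
    """
    cohort = _extract(data)
    mask = wa.included & (wa.weights > 0)
    y = cohort.outcome[mask].astype(float)
    z = cohort.exposure[mask].astype(float)
    w = wa.weights[mask]
    groups = cohort.source_id[mask]
    n_used = wa.n_used
    if z.sum() == 0 or z.sum() == len(z):
        raise EstimationError("included subjects must contain both exposure groups")
    if y.sum() == 0:
        raise EstimationError("no events among included subjects")
    x = np.column_stack([np.ones(len(y)), z])

    estimate = robust_se = np.nan
    converged = False
    family_used = "binomial"
    for family_used, family in (
        ("binomial", sm.families.Binomial(link=sm.families.links.Log())),
        ("poisson", sm.families.Poisson(link=sm.families.links.Log())),
    ):
        try:
            res = _fit_log_link(y, x, w, groups, family)
        except Exception:  # noqa: BLE001 - any optimizer failure falls through
            continue
        if res.converged and np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)):
            estimate = float(res.params[1])
            robust_se = float(res.bse[1])
            converged = True
            break

    if converged:
        ci_low = estimate - Z_975 * robust_se
        ci_high = estimate + Z_975 * robust_se
        p_value = float(2.0 * stats.norm.sf(abs(estimate / robust_se))) if robust_se > 0 else 0.0
    else:
        ci_low = ci_high = p_value = np.nan

    record = EstimateRecord(
        method_label=wa.method_label,
        replicate_index=replicate_index,
        estimate=estimate,
        robust_se=robust_se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        n_used=n_used,
        converged=converged,
        family_used=family_used,
        balance=balance,
        scenario_id=scenario_id,
    )
    record.separation_flag = detect_separation(record, data, wa)
    return record


def detect_separation(record: EstimateRecord, data, wa: WeightAssignment) -> bool:
    """Flag unstable replicates: nonconvergence, runaway estimate/SE, empty margin.

    Flagged records stay in primary summaries; the sensitivity summary can
    exclude them.
    """
    if not record.converged:
        return True
    if abs(record.estimate) > 10.0 or record.robust_se > 50.0:
        return True
    cohort = _extract(data)
    mask = wa.included & (wa.weights > 0)
    y = cohort.outcome[mask]
    z = cohort.exposure[mask]
    for zv in (0, 1):
        for yv in (0, 1):
            if not np.any((z == zv) & (y == yv)):
                return True
    return False
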