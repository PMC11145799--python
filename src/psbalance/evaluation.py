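"""Scenario orchestration and evaluation criteria.

Runs scenarios x methods x replicates and condenses each method's records
into the criteria battery: mean MB, mean and SD of percent relative bias,
rMSE, mean SE, coverage, coverageT, significance, mean N used, and Monte
Carlo errors for the mean MB and mean rbias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import balance_report
from .cohort import Cohort
from .estimation import EstimateRecord, estimate_effect
from .exceptions import ConfigurationError, PsbalanceError
from .plasmode import OBSERVED, ScenarioConfig, bind_base, generate_replicate, resolve_truth
from .propensity import fit_propensity
from .weighting import (
    METHODS,
    crude_weights,
    fine_stratify,
    fs_weights,
    overlap_weights,
    prune_unmatched,
)


@dataclass
class ScenarioResult:
    """Records plus the provenance needed to summarize them."""

    scenario: ScenarioConfig
    truth: float
    records: list[EstimateRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.records])


@dataclass
class CriteriaSummary:
    """One method x scenario row of the evaluation criteria (percent scale)."""

    scenario_id: str
    method_label: str
    mean_mb: float
    mean_rbias: float
    sd_rbias: float
    rmse: float
    mean_se: float
    coverage: float
    coverageT: float
    significance: float
    mean_n_used: float
    mce_rbias: float
    mce_mb: float
    n_replicates_used: int
    flagged_excluded: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _failed_record(method: str, r: int, scenario_id: str, exc: Exception) -> EstimateRecord:
    return EstimateRecord(
        method_label=method,
        replicate_index=r,
        estimate=np.nan,
        robust_se=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p_value=np.nan,
        n_used=0,
        converged=False,
        separation_flag=True,
        scenario_id=scenario_id,
        error=f"{type(exc).__name__}: {exc}",
    )


def analyze_dataset(
    data,
    methods: tuple[str, ...] = METHODS,
    k_strata: int = 20,
    replicate_index: int = 0,
    scenario_id: str | None = None,
    compute_balance: bool = True,
) -> list[EstimateRecord]:
    """Apply the requested methods to one (simulated or real) dataset.

    The 'X' methods refit the propensity model on the pruned dataset.
    Per-method failures become failed records instead of aborting.
    """
    cohort = data.cohort if hasattr(data, "cohort") else data
    records: list[EstimateRecord] = []

    def run(method: str, target: Cohort, wa) -> None:
        try:
            bal = balance_report(target, wa) if compute_balance else None
            records.append(
                estimate_effect(target, wa, replicate_index, balance=bal, scenario_id=scenario_id)
            )
        except PsbalanceError as exc:
            records.append(_failed_record(method, replicate_index, scenario_id, exc))

    datasets: dict[str, Cohort] = {"F": cohort}
    fits: dict[str, object] = {}

    def dataset(tag: str) -> Cohort:
        if tag == "X" and "X" not in datasets:
            datasets["X"] = prune_unmatched(cohort)
        return datasets[tag]

    def ps_fit(tag: str):
        if tag not in fits:
            fits[tag] = fit_propensity(dataset(tag))
        return fits[tag]

    for method in methods:
        if method == "crude":
            run(method, cohort, crude_weights(cohort))
            continue
        tag = "F" if method.endswith("_F") or "_F_" in method else "X"
        try:
            target = dataset(tag)
            fit = ps_fit(tag)
            if method.startswith("OW"):
                wa = overlap_weights(fit, target, label=method)
            else:
                strat = fine_stratify(fit, target, k_strata=k_strata)
                scheme = "unequ" if method.endswith("unequ") else "equ"
                wa = fs_weights(strat, target, scheme, label=method)
        except PsbalanceError as exc:
            records.append(_failed_record(method, replicate_index, scenario_id, exc))
            continue
        run(method, target, wa)
    return records


def run_scenario(
    scenario: ScenarioConfig,
    base: Cohort,
    methods: tuple[str, ...] = METHODS,
    n_replicates: int | None = None,
    k_strata: int = 20,
    compute_balance: bool = True,
) -> ScenarioResult:
    """Simulate and analyze every replicate of a scenario.

    Replicate r's random stream is derived deterministically from
    (master_seed, r), so identical configs reproduce identical records.
    """
    bound = bind_base(scenario, base)
    truth = resolve_truth(bound)
    n_reps = n_replicates if n_replicates is not None else bound.n_replicates
    records: list[EstimateRecord] = []
    for r in range(n_reps):
        sim = generate_replicate(base, bound, r)
        records.extend(
            analyze_dataset(
                sim,
                methods=methods,
                k_strata=k_strata,
                replicate_index=r,
                scenario_id=bound.scenario_id,
                compute_balance=compute_balance,
            )
        )
    return ScenarioResult(scenario=bound, truth=truth, records=records)


def monte_carlo_error(values, stat: str = "mean") -> float:
    """Monte Carlo standard error of the mean: SD(values)/sqrt(count)."""
    if stat != "mean":
        raise ValueError(f"unsupported statistic {stat!r}")
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("MCE undefined for fewer than 2 values")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def summarize(
    records: list[EstimateRecord],
    truth: float,
    exclude_flagged: bool = False,
    method_label: str | None = None,
    scenario_id: str | None = None,
) -> CriteriaSummary:
    """Condense one method's records into a criteria row.

    rbias = 100 (estimate - truth)/truth; rMSE combines squared bias on the
    raw (log) scale with its variance; coverage counts CIs containing the
    truth, coverageT those containing the truth while excluding zero.
    Failed records never contribute; flagged ones are dropped only when
    exclude_flagged.
    """
    if truth == 0:
        raise ConfigurationError("rbias-based criteria are undefined at truth 0; supply an override")
    recs = list(records)
    if method_label is not None:
        recs = [r for r in recs if r.method_label == method_label]
    if not recs:
        raise ValueError("no records to summarize")
    labels = {r.method_label for r in recs}
    if len(labels) > 1:
        raise ValueError(f"records mix methods {sorted(labels)}; pass method_label")
    usable = [r for r in recs if r.converged and np.isfinite(r.estimate)]
    if exclude_flagged:
        usable = [r for r in usable if not r.separation_flag]
    if not usable:
        raise ValueError("no usable records after filtering")

    est = np.array([r.estimate for r in usable])
    se = np.array([r.robust_se for r in usable])
    lo = np.array([r.ci_low for r in usable])
    hi = np.array([r.ci_high for r in usable])
    p = np.array([r.p_value for r in usable])
    mb = np.array([r.balance.mb for r in usable if r.balance is not None], dtype=float)
    n_used = np.array([r.n_used for r in usable], dtype=float)

    rbias = 100.0 * (est - truth) / truth
    covers = (lo <= truth) & (truth <= hi)
    excludes_zero = (lo > 0) | (hi < 0)
    return CriteriaSummary(
        scenario_id=scenario_id or (recs[0].scenario_id or ""),
        method_label=recs[0].method_label,
        mean_mb=float(mb.mean()) if mb.size else np.nan,
        mean_rbias=float(rbias.mean()),
        sd_rbias=float(rbias.std(ddof=1)) if rbias.size > 1 else np.nan,
        rmse=float(np.sqrt(np.mean((est - truth) ** 2))),
        mean_se=float(se.mean()),
        coverage=float(100.0 * covers.mean()),
        coverageT=float(100.0 * (covers & excludes_zero).mean()),
        significance=float(100.0 * (p < 0.05).mean()),
        mean_n_used=float(n_used.mean()),
        mce_rbias=monte_carlo_error(rbias) if rbias.size > 1 else np.nan,
        mce_mb=monte_carlo_error(mb) if mb.size > 1 else np.nan,
        n_replicates_used=len(usable),
        flagged_excluded=exclude_flagged,
    )


def summarize_result(
    result: ScenarioResult, exclude_flagged: bool = False, methods: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """One criteria row per method for a scenario run."""
    labels = methods or tuple(dict.fromkeys(r.method_label for r in result.records))
    rows = []
    for label in labels:
        try:
            rows.append(
                summarize(
                    result.records,
                    result.truth,
                    exclude_flagged=exclude_flagged,
                    method_label=label,
                    scenario_id=result.scenario.scenario_id,
                ).to_dict()
            )
        except ValueError:
            continue
    return pd.DataFrame(rows)


def default_scenario_grid(
    effect_types: tuple[str, ...] = ("homogeneous", "heterogeneous_binary"),
    n_per_replicate: int = 4000,
    n_replicates: int = 500,
    master_seed: int = 0,
    include_disabled: bool = False,
) -> list[ScenarioConfig]:
    """The shipped scenario grid.

    Outcome risk in {1%, 10%, 30%} crossed with observed or 2.5% exposure,
    and exposure prevalence in {2.5%, 10%, 30%} crossed with observed or 1%
    outcome risk, for homogeneous and sex-moderated effects.  The rare-rare
    heterogeneous cell (1% outcome x 2.5% exposure) ships disabled.
    """
    cells: list[tuple[float | str, float | str]] = []
    for outcome in (0.01, 0.10, 0.30):
        for exposure in (OBSERVED, 0.025):
            cells.append((outcome, exposure))
    for exposure in (0.025, 0.10, 0.30):
        for outcome in (OBSERVED, 0.01):
            if (outcome, exposure) not in cells:
                cells.append((outcome, exposure))

    def fmt(v) -> str:
        return "obs" if v == OBSERVED else f"{100 * v:g}pct"

    scenarios = []
    for effect_type in effect_types:
        for outcome, exposure in cells:
            enabled = not (
                effect_type != "homogeneous" and outcome == 0.01 and exposure == 0.025
            )
            if not enabled and not include_disabled:
                continue
            scenarios.append(
                ScenarioConfig(
                    scenario_id=f"{effect_type}_out{fmt(outcome)}_exp{fmt(exposure)}",
                    n_per_replicate=n_per_replicate,
                    n_replicates=n_replicates,
                    outcome_risk=outcome,
                    exposure_prevalence=exposure,
                    effect_type=effect_type,
                    moderator_name="female",
                    master_seed=master_seed,
                    enabled=enabled,
                )
            )
    return scenarios
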