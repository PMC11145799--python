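"""Plasmode-style simulation of exposures and outcomes.

Replicates are built by resampling base-cohort covariate rows with
replacement (preserving their joint distribution) and then drawing
exposure and/or outcome from logistic models whose intercepts are
calibrated per replicate so the realized marginal rates match the
scenario targets.  A constant or moderator-dependent treatment term is
injected into the outcome model.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import Cohort, DEFAULT_EXPOSURE_COEFFICIENTS, DEFAULT_OUTCOME_COEFFICIENTS, _is_binary
from .exceptions import CalibrationError, ConfigurationError

OBSERVED = "observed"

EFFECT_TYPES = ("homogeneous", "heterogeneous_binary", "heterogeneous_continuous")


@dataclass
class ScenarioConfig:
    """One simulation scenario: target rates, effect shape, model coefficients.

    ``outcome_risk`` / ``exposure_prevalence`` are probabilities or the token
    ``"observed"``.  Observed exposure keeps the resampled base labels;
    observed outcome risk calibrates to the base cohort's realized risk.
    The fields after ``master_seed`` are bookkeeping filled in by
    :func:`bind_base` and are not meant to be set by hand.
    """

    scenario_id: str = "scenario"
    n_per_replicate: int = 4000
    n_replicates: int = 500
    outcome_risk: float | str = OBSERVED
    exposure_prevalence: float | str = OBSERVED
    effect_type: str = "homogeneous"
    effect_coefficient: float = 1.0
    moderator_name: str = "female"
    exposure_model_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_COEFFICIENTS)
    )
    outcome_model_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    master_seed: int = 0
    truth_override: float | None = None
    enabled: bool = True
    # filled by bind_base
    scale_stats: dict[str, tuple[float, float]] | None = None
    moderator_mean: float | None = None
    resolved_outcome_risk: float | None = None
    resolved_exposure_prevalence: float | None = None

    def validate(self) -> None:
        if self.n_per_replicate <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("replicate counts must be positive")
        for value, label in [
            (self.outcome_risk, "outcome_risk"),
            (self.exposure_prevalence, "exposure_prevalence"),
        ]:
            if value != OBSERVED and not (isinstance(value, (int, float)) and 0 < value < 1):
                raise ConfigurationError(f"{label} must be in (0,1) or {OBSERVED!r}, got {value!r}")
        if self.effect_type not in EFFECT_TYPES:
            raise ConfigurationError(
                f"effect_type must be one of {EFFECT_TYPES}, got {self.effect_type!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SimulatedDataset:
    """One simulation replicate with its provenance and truth bookkeeping."""

    cohort: Cohort
    scenario: ScenarioConfig
    replicate_index: int
    realized_prevalence: float
    realized_risk: float
    true_marginal_effect: float


def compute_scale_stats(cohort: Cohort) -> dict[str, tuple[float, float]]:
    """Mean/SD of every non-binary covariate, used to standardize model scores."""
    stats = {}
    for name in cohort.covariate_names:
        col = cohort.data[name]
        if not _is_binary(col):
            sd = float(col.std(ddof=1))
            stats[name] = (float(col.mean()), sd if sd > 0 else 1.0)
    return stats


def linear_scores(
    covariates: pd.DataFrame,
    coefficients: dict[str, float],
    scale_stats: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Linear predictor sum(beta * x) with continuous covariates standardized.

    When ``scale_stats`` is given (from the base cohort) those means/SDs are
    used, keeping replicate scores on the base scale; otherwise stats are
    computed from the frame at hand.  Binary columns enter raw.
    """
    scores = np.zeros(len(covariates))
    for name, beta in coefficients.items():
        if name not in covariates.columns:
            raise ConfigurationError(f"coefficient refers to unknown covariate {name!r}")
        x = covariates[name].to_numpy(dtype=float)
        if scale_stats is not None and name in scale_stats:
            mean, sd = scale_stats[name]
            x = (x - mean) / sd
        elif scale_stats is None and not _is_binary(covariates[name]):
            sd = x.std(ddof=1)
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        scores += beta * x
    return scores


def calibrate_intercept(linear_scores: np.ndarray, target: float, tol: float = 1e-8) -> float:
    """Solve for c with mean(expit(c + scores)) = target by bisection on [-50, 50]."""
    scores = np.asarray(linear_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise CalibrationError("linear scores must be finite")
    if not 0.0 < target < 1.0:
        raise CalibrationError(f"target must be in (0, 1), got {target}")

    def f(c: float) -> float:
        return float(expit(c + scores).mean()) - target

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(f"target {target} not bracketed by intercepts in [-50, 50]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    c = 0.5 * (lo + hi)
    if abs(f(c)) > tol:
        raise CalibrationError(f"calibration for target {target} stalled at residual {f(c):.3g}")
    return c


def resample_covariates(base: Cohort, n: int, seed) -> Cohort:
    """Draw n rows uniformly with replacement; source_id records the base row."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if base.n == 0:
        raise ConfigurationError("base cohort is empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, base.n, size=n)
    data = base.data.iloc[idx].reset_index(drop=True)
    data["source_id"] = base.subject_id[idx]
    data["subject_id"] = np.arange(n)
    return Cohort(data, list(base.covariate_names))


def simulate_exposure(cohort: Cohort, scenario: ScenarioConfig, seed) -> Cohort:
    """Replace exposure labels with draws from the calibrated logistic model."""
    target = scenario.exposure_prevalence
    if target == OBSERVED:
        raise ConfigurationError(
            "exposure_prevalence is 'observed': keep resampled labels instead of simulating"
        )
    rng = np.random.default_rng(seed)
    scores = linear_scores(cohort.covariates, scenario.exposure_model_coefficients,
                           scenario.scale_stats)
    c = calibrate_intercept(scores, float(target))
    exposure = rng.binomial(1, expit(c + scores))
    if exposure.sum() == 0 or exposure.sum() == len(exposure):
        warnings.warn(
            f"degenerate replicate: all subjects in one exposure group (target {target})",
            RuntimeWarning,
            stacklevel=2,
        )
    return cohort.replace_column("exposure", exposure)


def _treatment_term(cohort: Cohort, scenario: ScenarioConfig) -> np.ndarray:
    z = cohort.exposure.astype(float)
    beta = scenario.effect_coefficient
    if scenario.effect_type == "homogeneous":
        return beta * z
    name = scenario.moderator_name
    if name not in cohort.covariate_names:
        raise ConfigurationError(f"unknown moderator {name!r}")
    m = cohort.data[name].to_numpy(dtype=float)
    if scenario.effect_type == "heterogeneous_continuous":
        if scenario.scale_stats and name in scenario.scale_stats:
            mean, sd = scenario.scale_stats[name]
        else:
            mean, sd = m.mean(), m.std(ddof=1)
        m = (m - mean) / (sd if sd > 0 else 1.0)
    return beta * z * m


def resolve_truth(scenario: ScenarioConfig, base: Cohort | None = None) -> float:
    """Marginal true effect shared by all replicates of a scenario.

    Homogeneous: the effect coefficient itself.  Binary moderator: the
    coefficient times the BASE cohort's moderator mean.  Standardized
    continuous moderator: mean zero makes relative bias degenerate, so an
    explicit truth_override is required.
    """
    if scenario.truth_override is not None:
        return float(scenario.truth_override)
    if scenario.effect_type == "homogeneous":
        return float(scenario.effect_coefficient)
    if scenario.effect_type == "heterogeneous_continuous":
        raise ConfigurationError(
            "truth for a standardized continuous moderator is degenerate (mean 0); "
            "set truth_override explicitly"
        )
    if scenario.moderator_mean is not None:
        return float(scenario.effect_coefficient * scenario.moderator_mean)
    if base is None:
        raise ConfigurationError("binary-moderator truth needs the base cohort; call bind_base")
    return float(scenario.effect_coefficient * base.data[scenario.moderator_name].mean())


def bind_base(scenario: ScenarioConfig, base: Cohort) -> ScenarioConfig:
    """Return a copy of the scenario with base-cohort bookkeeping resolved.

    Fixes the standardization stats, the moderator mean (truth is defined on
    the base cohort, not per replicate) and the numeric targets behind
    'observed' tokens.
    """
    scenario.validate()
    out = dataclasses.replace(scenario)
    out.scale_stats = compute_scale_stats(base)
    if scenario.effect_type != "homogeneous":
        if scenario.moderator_name not in base.covariate_names:
            raise ConfigurationError(f"unknown moderator {scenario.moderator_name!r}")
        m = base.data[scenario.moderator_name].to_numpy(dtype=float)
        if scenario.effect_type == "heterogeneous_continuous":
            mean, sd = out.scale_stats.get(scenario.moderator_name, (m.mean(), m.std(ddof=1)))
            out.moderator_mean = float((m - mean).mean() / (sd if sd > 0 else 1.0))
        else:
            out.moderator_mean = float(m.mean())
    out.resolved_outcome_risk = (
        float(base.outcome.mean()) if scenario.outcome_risk == OBSERVED else float(scenario.outcome_risk)
    )
    out.resolved_exposure_prevalence = (
        float(base.exposure.mean())
        if scenario.exposure_prevalence == OBSERVED
        else float(scenario.exposure_prevalence)
    )
    return out


def simulate_outcome(
    cohort: Cohort, scenario: ScenarioConfig, seed, replicate_index: int = 0,
) -> SimulatedDataset:
    """Draw outcomes from the calibrated logistic model with the injected effect."""
    rng = np.random.default_rng(seed)
    target = scenario.resolved_outcome_risk
    if target is None:
        if scenario.outcome_risk == OBSERVED:
            raise ConfigurationError("outcome_risk is 'observed' but scenario is not bound; call bind_base")
        target = float(scenario.outcome_risk)
    scores = linear_scores(cohort.covariates, scenario.outcome_model_coefficients,
                           scenario.scale_stats)
    t = _treatment_term(cohort, scenario)
    c = calibrate_intercept(scores + t, target)
    outcome = rng.binomial(1, expit(c + scores + t))
    sim_cohort = cohort.replace_column("outcome", outcome)
    return SimulatedDataset(
        cohort=sim_cohort,
        scenario=scenario,
        replicate_index=replicate_index,
        realized_prevalence=float(sim_cohort.exposure.mean()),
        realized_risk=float(outcome.mean()),
        true_marginal_effect=resolve_truth(scenario),
    )


def replicate_seed(master_seed: int, replicate_index: int) -> np.random.SeedSequence:
    """Deterministic child seed for one replicate of one master seed."""
    return np.random.SeedSequence(entropy=(int(master_seed), int(replicate_index)))


def generate_replicate(base: Cohort, scenario: ScenarioConfig, replicate_index: int) -> SimulatedDataset:
    """Resample covariates and simulate exposure/outcome for one replicate.

    The scenario must already be bound to the base (see :func:`bind_base`).
    Observed exposure keeps the resampled base labels.
    """
    seeds = replicate_seed(scenario.master_seed, replicate_index).spawn(3)
    cohort = resample_covariates(base, scenario.n_per_replicate, seeds[0])
    if scenario.exposure_prevalence != OBSERVED:
        cohort = simulate_exposure(cohort, scenario, seeds[1])
    return simulate_outcome(cohort, scenario, seeds[2], replicate_index)


def export_replicates(base: Cohort, scenario: ScenarioConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write one CSV per replicate plus a manifest of seeds and realized rates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bound = bind_base(scenario, base)
    rows = []
    for r in range(bound.n_replicates):
        sim = generate_replicate(base, bound, r)
        path = out_dir / f"{bound.scenario_id}_rep{r:04d}.csv"
        sim.cohort.data.to_csv(path, index=False)
        rows.append(
            {
                "scenario_id": bound.scenario_id,
                "replicate": r,
                "master_seed": bound.master_seed,
                "realized_prevalence": sim.realized_prevalence,
                "realized_risk": sim.realized_risk,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / f"{bound.scenario_id}_manifest.csv", index=False)
    return manifest
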