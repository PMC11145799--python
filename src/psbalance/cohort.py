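"""Synthetic claims-style base cohort.

Generates a subject-level table shaped like a large administrative claims
sample: 5 continuous covariates, 12 binary indicators — including a
mutually exclusive 6-level race block and a complementary eligibility
pair — correlated through a Gaussian copula, plus binary exposure and
outcome labels drawn from logistic mechanisms whose intercepts are
calibrated to target marginal rates.

The defaults target a cohort of 42,628 subjects with 10.55% exposure
prevalence, 27.75% outcome risk and 63.59% female proportion.  All
marginals and coefficients are configuration, not data: the generator is
a stand-in, not a fit to any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigurationError

CONTINUOUS_NAMES = ["age", "distance", "elig_months", "mc_months", "elixhauser"]
RACE_BLOCK = [
    "race_white",
    "race_black",
    "race_amind",
    "race_asian",
    "race_hispanic",
    "race_unknown",
]
ELIG_PAIR = ("elig_blind_disabled", "elig_adult")
BINARY_NAMES = ["female"] + RACE_BLOCK + list(ELIG_PAIR) + ["tanf", "urban", "insulin"]
COVARIATE_NAMES = CONTINUOUS_NAMES + BINARY_NAMES
RESERVED_COLUMNS = ("subject_id", "source_id", "exposure", "outcome")

# Log-odds contributions of the exposure / outcome mechanisms; continuous
# covariates enter standardized.  Eleven covariates appear in both vectors,
# so most covariates act as confounders.  Placeholder values — overridable.
DEFAULT_EXPOSURE_COEFFICIENTS: dict[str, float] = {
    "age": 0.15,
    "distance": -0.40,
    "elig_months": -0.35,
    "mc_months": -0.30,
    "elixhauser": -0.30,
    "female": -0.25,
    "race_black": 0.30,
    "race_hispanic": -0.10,
    "elig_blind_disabled": -0.20,
    "tanf": 0.15,
    "urban": 0.25,
    "insulin": -0.15,
}
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, float] = {
    "age": 0.30,
    "distance": 0.10,
    "elig_months": -0.20,
    "mc_months": -0.15,
    "elixhauser": 0.45,
    "female": -0.20,
    "race_black": 0.20,
    "race_white": -0.10,
    "elig_blind_disabled": 0.30,
    "tanf": 0.15,
    "urban": -0.10,
    "insulin": 0.35,
}

# Target marginal probabilities for the 12 indicators.  The race block sums
# to one and the eligibility pair is complementary.  Placeholders: the real
# cohort's indicator prevalences are not public, only its balance table is.
DEFAULT_BINARY_PREVALENCES: dict[str, float] = {
    "female": 0.6359,
    "race_white": 0.25,
    "race_black": 0.20,
    "race_amind": 0.01,
    "race_asian": 0.03,
    "race_hispanic": 0.40,
    "race_unknown": 0.11,
    "elig_blind_disabled": 0.35,
    "elig_adult": 0.65,
    "tanf": 0.20,
    "urban": 0.80,
    "insulin": 0.25,
}


@dataclass(frozen=True)
class ContinuousSpec:
    """Marginal specification for one continuous covariate.

    family is one of ``truncnorm`` (location/scale normal truncated to
    [lower, upper]) or ``lognormal`` (scale = sigma of log, loc = mean of
    log).  ``discrete`` rounds the draw to the nearest integer, used for
    month counts and comorbidity scores.
    """

    name: str
    family: str = "truncnorm"
    loc: float = 0.0
    scale: float = 1.0
    lower: float | None = None
    upper: float | None = None
    discrete: bool = False

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "truncnorm":
            a = -np.inf if self.lower is None else (self.lower - self.loc) / self.scale
            b = np.inf if self.upper is None else (self.upper - self.loc) / self.scale
            x = stats.truncnorm.ppf(u, a, b, loc=self.loc, scale=self.scale)
        elif self.family == "lognormal":
            x = stats.lognorm.ppf(u, s=self.scale, scale=np.exp(self.loc))
        else:
            raise ConfigurationError(f"unknown marginal family {self.family!r}")
        if self.discrete:
            x = np.rint(x)
            if self.lower is not None:
                x = np.clip(x, self.lower, self.upper)
        return x


def default_continuous_specs() -> list[ContinuousSpec]:
    return [
        ContinuousSpec("age", "truncnorm", loc=40.0, scale=12.0, lower=18, upper=64),
        ContinuousSpec("distance", "lognormal", loc=1.5, scale=0.8),
        ContinuousSpec("elig_months", "truncnorm", loc=10.0, scale=3.0, lower=0, upper=12, discrete=True),
        ContinuousSpec("mc_months", "truncnorm", loc=8.0, scale=4.0, lower=0, upper=12, discrete=True),
        ContinuousSpec("elixhauser", "lognormal", loc=0.5, scale=0.7, discrete=True),
    ]


def default_latent_correlation() -> np.ndarray:
    """Exchangeable baseline correlation with a few stronger pairs.

    The matrix is indexed by COVARIATE_NAMES.  Race levels beyond the first
    and the second member of the eligibility pair are generated from shared
    latent dimensions, so their rows are effectively unused.
    """
    k = len(COVARIATE_NAMES)
    r = np.full((k, k), 0.15)
    np.fill_diagonal(r, 1.0)
    idx = {name: i for i, name in enumerate(COVARIATE_NAMES)}

    def set_pair(a: str, b: str, rho: float) -> None:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho

    set_pair("elig_months", "mc_months", 0.50)
    set_pair("age", "elixhauser", 0.35)
    set_pair("elixhauser", "elig_blind_disabled", 0.30)
    set_pair("distance", "urban", -0.30)
    return r


@dataclass
class CohortConfig:
    """Configuration of the synthetic base cohort generator."""

    n_subjects: int = 42_628
    continuous_specs: list[ContinuousSpec] = field(default_factory=default_continuous_specs)
    binary_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_PREVALENCES)
    )
    latent_correlation: np.ndarray = field(default_factory=default_latent_correlation)
    exposure_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_COEFFICIENTS)
    )
    outcome_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    target_exposure_prevalence: float = 0.1055
    target_outcome_risk: float = 0.2775
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        for name, p in self.binary_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"prevalence of {name!r} must be in (0, 1), got {p}")
        for target, label in [
            (self.target_exposure_prevalence, "target_exposure_prevalence"),
            (self.target_outcome_risk, "target_outcome_risk"),
        ]:
            if not 0.0 < target < 1.0:
                raise ConfigurationError(f"{label} must be in (0, 1), got {target}")
        race_total = sum(self.binary_prevalences[n] for n in RACE_BLOCK)
        if abs(race_total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"race-block prevalences must sum to 1 (mutually exclusive block), got {race_total}"
            )
        p_bd = self.binary_prevalences[ELIG_PAIR[0]]
        p_ad = self.binary_prevalences[ELIG_PAIR[1]]
        if abs(p_bd + p_ad - 1.0) > 1e-6:
            raise ConfigurationError(
                f"{ELIG_PAIR[0]!r} and {ELIG_PAIR[1]!r} must be complementary, got {p_bd} + {p_ad}"
            )
        r = np.asarray(self.latent_correlation, dtype=float)
        k = len(COVARIATE_NAMES)
        if r.shape != (k, k):
            raise ConfigurationError(f"latent_correlation must be {k}x{k}, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ConfigurationError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ConfigurationError("latent_correlation must have unit diagonal")
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("latent_correlation is not positive definite") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Read a config from a YAML/JSON key-value file; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in (
            "n_subjects",
            "binary_prevalences",
            "exposure_coefficients",
            "outcome_coefficients",
            "target_exposure_prevalence",
            "target_outcome_risk",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "continuous_specs" in raw:
            kwargs["continuous_specs"] = [ContinuousSpec(**spec) for spec in raw["continuous_specs"]]
        if "latent_correlation" in raw:
            kwargs["latent_correlation"] = np.asarray(raw["latent_correlation"], dtype=float)
        return cls(**kwargs)


@dataclass
class Cohort:
    """Subject-level table: covariates plus exposure/outcome labels.

    ``source_id`` records which base-cohort row a record descends from; in a
    base cohort it equals ``subject_id``.
    """

    data: pd.DataFrame
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_names]

    @property
    def exposure(self) -> np.ndarray:
        return self.data["exposure"].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy()

    @property
    def subject_id(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def source_id(self) -> np.ndarray:
        return self.data["source_id"].to_numpy()

    @property
    def binary_names(self) -> list[str]:
        return [c for c in self.covariate_names if c in BINARY_NAMES or _is_binary(self.data[c])]

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
                      list(self.covariate_names))

    def replace_column(self, name: str, values: np.ndarray) -> "Cohort":
        data = self.data.copy()
        data[name] = values
        return Cohort(data, list(self.covariate_names))

    def validate(self) -> None:
        if self.data.isna().any().any():
            raise ConfigurationError("cohort contains missing values")
        for col in ("subject_id", "source_id", "exposure", "outcome"):
            if col not in self.data.columns:
                raise ConfigurationError(f"cohort is missing column {col!r}")
        if self.data["subject_id"].duplicated().any():
            raise ConfigurationError("subject_id values are not unique")
        for col in ("exposure", "outcome"):
            if not set(np.unique(self.data[col])) <= {0, 1}:
                raise ConfigurationError(f"{col} must be 0/1")
        race_cols = [c for c in RACE_BLOCK if c in self.data.columns]
        if len(race_cols) == len(RACE_BLOCK):
            sums = self.data[race_cols].sum(axis=1)
            if not (sums == 1).all():
                raise ConfigurationError("race block is not mutually exclusive/exhaustive")

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta = {"covariate_names": self.covariate_names, "n": self.n}
        if metadata:
            meta.update(metadata)
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            names = json.loads(meta_path.read_text())["covariate_names"]
        else:
            names = [c for c in data.columns if c not in RESERVED_COLUMNS]
        return cls(data, list(names))


def _is_binary(col: pd.Series) -> bool:
    return set(np.unique(col)) <= {0, 1}


def generate_base_cohort(config: CohortConfig) -> Cohort:
    """Draw a base cohort from the Gaussian-copula generator.

    Binary indicators are thresholded latent normals; the race block is cut
    from a single latent dimension at cumulative category quantiles so
    exactly one level is set per subject; the second eligibility indicator
    is the complement of the first.  Exposure and outcome are Bernoulli
    draws from logistic mechanisms with intercepts calibrated so realized
    marginal rates hit the configured targets.
    """
    from .plasmode import calibrate_intercept, linear_scores  # local import: avoids cycle

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects
    idx = {name: i for i, name in enumerate(COVARIATE_NAMES)}

    chol = np.linalg.cholesky(np.asarray(config.latent_correlation, dtype=float))
    z = rng.standard_normal((n, len(COVARIATE_NAMES))) @ chol.T
    u = stats.norm.cdf(z)

    data = pd.DataFrame({"subject_id": np.arange(n), "source_id": np.arange(n)})
    spec_by_name = {s.name: s for s in config.continuous_specs}
    if set(spec_by_name) != set(CONTINUOUS_NAMES):
        raise ConfigurationError(
            f"continuous_specs must cover exactly {CONTINUOUS_NAMES}, got {sorted(spec_by_name)}"
        )
    for name in CONTINUOUS_NAMES:
        data[name] = spec_by_name[name].ppf(u[:, idx[name]])

    # race block: one latent dimension cut at cumulative category quantiles
    race_p = np.array([config.binary_prevalences[name] for name in RACE_BLOCK])
    cum = np.cumsum(race_p)
    race_cat = np.searchsorted(cum[:-1], u[:, idx[RACE_BLOCK[0]]], side="right")
    for j, name in enumerate(RACE_BLOCK):
        data[name] = (race_cat == j).astype(int)

    bd_name, adult_name = ELIG_PAIR
    data[bd_name] = (u[:, idx[bd_name]] < config.binary_prevalences[bd_name]).astype(int)
    data[adult_name] = 1 - data[bd_name]

    for name in BINARY_NAMES:
        if name in RACE_BLOCK or name in ELIG_PAIR:
            continue
        data[name] = (u[:, idx[name]] < config.binary_prevalences[name]).astype(int)

    cohort = Cohort(data.assign(exposure=0, outcome=0), list(COVARIATE_NAMES))

    exp_scores = linear_scores(cohort.covariates, config.exposure_coefficients)
    c_exp = calibrate_intercept(exp_scores, config.target_exposure_prevalence)
    exposure = rng.binomial(1, _expit(c_exp + exp_scores))

    out_scores = linear_scores(cohort.covariates, config.outcome_coefficients)
    c_out = calibrate_intercept(out_scores, config.target_outcome_risk)
    outcome = rng.binomial(1, _expit(c_out + out_scores))

    data["exposure"] = exposure
    data["outcome"] = outcome
    cohort = Cohort(data, list(COVARIATE_NAMES))
    cohort.validate()
    return cohort


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


@dataclass
class CohortSummary:
    """Crude description of a cohort: group means, crude SMDs, marginal rates."""

    table: pd.DataFrame  # index: covariate; columns: mean_exposed, mean_unexposed, smd
    exposure_prevalence: float
    outcome_risk: float
    n: int


def describe_cohort(cohort: Cohort) -> CohortSummary:
    """Per-covariate group means and crude SMD (x100), plus marginal rates.

    SMD sign convention is exposed minus unexposed.
    """
    from .balance import smd  # local import: avoids cycle

    if cohort.n == 0:
        raise ConfigurationError("cannot describe an empty cohort")
    z = cohort.exposure.astype(bool)
    rows = {}
    for name in cohort.covariate_names:
        x = cohort.data[name].to_numpy(dtype=float)
        rows[name] = {
            "mean_exposed": x[z].mean() if z.any() else np.nan,
            "mean_unexposed": x[~z].mean() if (~z).any() else np.nan,
            "smd": smd(x, cohort.exposure) if z.any() and (~z).any() else np.nan,
        }
    return CohortSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        exposure_prevalence=float(cohort.exposure.mean()),
        outcome_risk=float(cohort.outcome.mean()),
        n=cohort.n,
    )


def exposure_prevalence_percent(cohort: Cohort, decimals: int = 2) -> float:
    """Exposure prevalence as a rounded percentage."""
    return float(np.round(100.0 * cohort.exposure.mean(), decimals))
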