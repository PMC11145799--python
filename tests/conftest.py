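import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import psbalance as pb
from psbalance.cohort import Cohort


def make_cohort(
    covariates: dict[str, np.ndarray],
    exposure: np.ndarray,
    outcome: np.ndarray | None = None,
    source_id: np.ndarray | None = None,
) -> Cohort:
    """Assemble a Cohort from raw arrays (generic covariate names allowed)."""
    n = len(exposure)
    data = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "source_id": np.arange(n) if source_id is None else source_id,
        }
    )
    for name, values in covariates.items():
        data[name] = values
    data["exposure"] = np.asarray(exposure, dtype=int)
    data["outcome"] = np.zeros(n, dtype=int) if outcome is None else np.asarray(outcome, dtype=int)
    return Cohort(data, list(covariates))


def random_logistic_cohort(rng: np.random.Generator, n: int = 300, k: int = 4,
                           prevalence: float = 0.35) -> Cohort:
    """Small confounded cohort with a logistic exposure mechanism."""
    x = rng.normal(size=(n, k))
    beta = rng.uniform(-0.8, 0.8, size=k)
    scores = x @ beta
    c = pb.calibrate_intercept(scores, prevalence)
    z = rng.binomial(1, expit(c + scores))
    if z.sum() == 0 or z.sum() == n:  # pragma: no cover - vanishing probability
        z[0], z[1] = 1, 0
    y = rng.binomial(1, 0.3, size=n)
    return make_cohort({f"x{i}": x[:, i] for i in range(k)}, z, y)


@pytest.fixture(scope="session")
def base_cohort() -> Cohort:
    """Moderate synthetic base reused across module tests."""
    return pb.generate_base_cohort(pb.CohortConfig(n_subjects=6000, seed=11))


@pytest.fixture(scope="session")
def full_base_cohort() -> Cohort:
    """Default-size base cohort (42,628 subjects)."""
    return pb.generate_base_cohort(pb.CohortConfig(seed=5))


@pytest.fixture(scope="session")
def base_fit(base_cohort) -> pb.PSFit:
    fit = pb.fit_propensity(base_cohort)
    assert fit.converged
    return fit
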