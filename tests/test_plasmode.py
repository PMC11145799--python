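import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import psbalance as pb
from psbalance.exceptions import CalibrationError, ConfigurationError
from psbalance.plasmode import (
    OBSERVED,
    ScenarioConfig,
    bind_base,
    calibrate_intercept,
    compute_scale_stats,
    generate_replicate,
    replicate_seed,
    resample_covariates,
    resolve_truth,
    simulate_exposure,
    simulate_outcome,
)

from conftest import make_cohort


class TestCalibrateIntercept:
    def test_zero_scores_half(self):
        assert calibrate_intercept(np.zeros(50), 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_zero_scores_closed_form_logit(self):
        assert calibrate_intercept(np.zeros(50), 0.1055) == pytest.approx(
            logit(0.1055), abs=1e-7
        )

    def test_heterogeneous_scores_rare_target(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(scale=2.0, size=5000)
        c = calibrate_intercept(scores, 0.01)
        assert expit(c + scores).mean() == pytest.approx(0.01, abs=1e-8)

    @pytest.mark.parametrize("target", [0.01, 0.1055, 0.2775, 0.5, 0.9])
    def test_mean_probability_hits_target(self, target):
        scores = np.random.default_rng(1).normal(size=1000)
        c = calibrate_intercept(scores, target)
        assert expit(c + scores).mean() == pytest.approx(target, abs=1e-8)

    def test_unbracketed_target_errors(self):
        with pytest.raises(CalibrationError, match="bracket"):
            calibrate_intercept(np.full(10, -200.0), 0.5)

    def test_invalid_target_errors(self):
        with pytest.raises(CalibrationError):
            calibrate_intercept(np.zeros(5), 1.5)

    def test_nonfinite_scores_error(self):
        with pytest.raises(CalibrationError):
            calibrate_intercept(np.array([0.0, np.inf]), 0.5)


class TestResampleCovariates:
    def test_single_row_base(self):
        base = make_cohort({"a": np.array([3.5])}, np.array([1]))
        out = resample_covariates(base, 5, seed=0)
        assert out.n == 5
        assert (out.data["a"] == 3.5).all()
        assert (out.source_id == base.subject_id[0]).all()
        assert len(set(out.subject_id)) == 5

    def test_nonpositive_n_errors(self, base_cohort):
        with pytest.raises(ValueError):
            resample_covariates(base_cohort, 0, seed=0)

    def test_occupancy_oracle(self):
        # expected distinct source rows: B(1 - (1 - 1/B)^n)
        rng = np.random.default_rng(7)
        b, n, reps = 500, 200, 200
        base = make_cohort({"a": rng.normal(size=b)}, rng.binomial(1, 0.5, b))
        expected = b * (1 - (1 - 1 / b) ** n)
        distinct = [
            len(np.unique(resample_covariates(base, n, seed=s).source_id)) for s in range(reps)
        ]
        mc_se = np.std(distinct, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(distinct) - expected) < 3 * mc_se + 0.5

    def test_resampled_means_near_base_clt(self, base_cohort):
        n = 4000
        for seed in range(10):
            out = resample_covariates(base_cohort, n, seed=seed)
            for name in ("age", "distance", "elixhauser"):
                base_col = base_cohort.data[name]
                bound = 4 * base_col.std(ddof=1) / np.sqrt(n)
                assert abs(out.data[name].mean() - base_col.mean()) < bound

    def test_rows_copied_verbatim(self, base_cohort):
        out = resample_covariates(base_cohort, 50, seed=3)
        lookup = base_cohort.data.set_index("subject_id")
        for _, row in out.data.iterrows():
            src = lookup.loc[row["source_id"]]
            for name in base_cohort.covariate_names:
                assert row[name] == src[name]


class TestSimulateExposure:
    def test_no_confounding_hits_target(self, base_cohort):
        sc = ScenarioConfig(exposure_prevalence=0.30, exposure_model_coefficients={})
        out = simulate_exposure(base_cohort, sc, seed=0)
        p = out.exposure.mean()
        assert abs(p - 0.30) < 3 * np.sqrt(0.3 * 0.7 / base_cohort.n)
        # independence: near-zero correlation with a strong base confounder
        r = np.corrcoef(out.exposure, out.data["mc_months"])[0, 1]
        assert abs(r) < 4 / np.sqrt(base_cohort.n)

    def test_rare_target_expected_count(self, base_cohort):
        sc = ScenarioConfig(exposure_prevalence=0.025)
        bound = bind_base(sc, base_cohort)
        sub = resample_covariates(base_cohort, 4000, seed=1)
        counts = [
            simulate_exposure(sub, bound, seed=s).exposure.sum() for s in range(50)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 100) < 3 * se + 1

    def test_monotone_in_linear_score(self, base_cohort):
        sc = ScenarioConfig(exposure_prevalence=0.30)
        bound = bind_base(sc, base_cohort)
        out = simulate_exposure(base_cohort, bound, seed=2)
        scores = pb.plasmode.linear_scores(
            out.covariates, bound.exposure_model_coefficients, bound.scale_stats
        )
        deciles = pd.qcut(scores, 10, labels=False)
        rates = pd.Series(out.exposure).groupby(deciles).mean()
        assert rates.iloc[-1] > rates.iloc[0]

    def test_observed_token_rejected(self, base_cohort):
        sc = ScenarioConfig(exposure_prevalence=OBSERVED)
        with pytest.raises(ConfigurationError, match="observed"):
            simulate_exposure(base_cohort, sc, seed=0)

    def test_degenerate_replicate_warns(self):
        rng = np.random.default_rng(0)
        tiny = make_cohort({"a": rng.normal(size=20)}, rng.binomial(1, 0.5, 20))
        sc = ScenarioConfig(exposure_prevalence=0.001, exposure_model_coefficients={})
        with pytest.warns(RuntimeWarning, match="degenerate"):
            simulate_exposure(tiny, sc, seed=0)


class TestSimulateOutcome:
    def test_null_effect_outcome_independent(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(outcome_risk=0.30, effect_coefficient=0.0), base_cohort
        )
        risks = {0: [], 1: []}
        for s in range(20):
            sim = simulate_outcome(base_cohort, sc, seed=s)
            y, z = sim.cohort.outcome, sim.cohort.exposure
            risks[0].append(y[z == 0].mean())
            risks[1].append(y[z == 1].mean())
        assert np.mean(risks[1]) == pytest.approx(np.mean(risks[0]), abs=0.02)

    def test_truth_binary_moderator(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(effect_type="heterogeneous_binary", moderator_name="female"),
            base_cohort,
        )
        sim = simulate_outcome(base_cohort, sc, seed=0)
        assert sim.true_marginal_effect == pytest.approx(
            base_cohort.data["female"].mean()
        )

    def test_truth_is_63_59_percent_at_footnote_proportion(self):
        # moderator mean fixed to the printed female proportion
        rng = np.random.default_rng(0)
        n = 10_000
        female = np.zeros(n)
        female[: int(round(0.6359 * n))] = 1
        base = make_cohort({"female": female}, rng.binomial(1, 0.1, n))
        sc = bind_base(
            ScenarioConfig(effect_type="heterogeneous_binary", moderator_name="female"),
            base,
        )
        assert resolve_truth(sc) == pytest.approx(0.6359)

    def test_truth_continuous_requires_override(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(effect_type="heterogeneous_continuous", moderator_name="age"),
            base_cohort,
        )
        with pytest.raises(ConfigurationError, match="override"):
            resolve_truth(sc)
        sc.truth_override = 0.5
        assert resolve_truth(sc) == 0.5

    def test_unknown_moderator_errors(self, base_cohort):
        sc = ScenarioConfig(effect_type="heterogeneous_binary", moderator_name="nope")
        with pytest.raises(ConfigurationError, match="moderator"):
            bind_base(sc, base_cohort)

    def test_rare_outcome_event_count(self, base_cohort):
        sc = bind_base(ScenarioConfig(outcome_risk=0.01), base_cohort)
        sub = resample_covariates(base_cohort, 4000, seed=0)
        counts = [simulate_outcome(sub, sc, seed=s).cohort.outcome.sum() for s in range(100)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 40) < 3 * se + 0.5

    def test_calibration_grand_mean_over_replicates(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(
                outcome_risk=0.10, exposure_prevalence=0.10, n_per_replicate=500,
                master_seed=4,
            ),
            base_cohort,
        )
        outcomes = []
        for r in range(100):
            outcomes.append(generate_replicate(base_cohort, sc, r).cohort.outcome)
        grand = np.concatenate(outcomes).mean()
        mc_se = np.sqrt(0.1 * 0.9 / (100 * 500))
        assert abs(grand - 0.10) < 3 * mc_se


class TestSeedDiscipline:
    def test_replicates_deterministic(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(outcome_risk=0.1, exposure_prevalence=0.1, n_per_replicate=300),
            base_cohort,
        )
        a = generate_replicate(base_cohort, sc, 3)
        b = generate_replicate(base_cohort, sc, 3)
        pd.testing.assert_frame_equal(a.cohort.data, b.cohort.data)

    def test_replicate_streams_differ(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(outcome_risk=0.1, exposure_prevalence=0.1, n_per_replicate=300),
            base_cohort,
        )
        a = generate_replicate(base_cohort, sc, 0)
        b = generate_replicate(base_cohort, sc, 1)
        assert not a.cohort.data.equals(b.cohort.data)

    def test_child_seed_depends_on_both_keys(self):
        s = {replicate_seed(m, r).entropy for m in (0, 1) for r in (0, 1)}
        assert len(s) == 4

    def test_observed_exposure_keeps_base_labels(self, base_cohort):
        sc = bind_base(
            ScenarioConfig(outcome_risk=0.1, exposure_prevalence=OBSERVED, n_per_replicate=400),
            base_cohort,
        )
        sim = generate_replicate(base_cohort, sc, 0)
        lookup = base_cohort.data.set_index("subject_id")["exposure"]
        assert (sim.cohort.exposure == lookup.loc[sim.cohort.source_id].to_numpy()).all()


class TestScenarioConfig:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(outcome_risk=1.5).validate()
        with pytest.raises(ConfigurationError):
            ScenarioConfig(effect_type="quadratic").validate()
        with pytest.raises(ConfigurationError):
            ScenarioConfig(n_replicates=0).validate()

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "sc.yaml"
        path.write_text(
            "scenario_id: demo\noutcome_risk: 0.1\nexposure_prevalence: observed\n"
            "effect_type: heterogeneous_binary\nn_replicates: 7\n"
        )
        sc = ScenarioConfig.from_file(path)
        assert sc.scenario_id == "demo"
        assert sc.outcome_risk == 0.1
        assert sc.exposure_prevalence == OBSERVED
        assert sc.n_replicates == 7

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "sc.yaml"
        path.write_text("no_such_key: 1\n")
        with pytest.raises(ConfigurationError, match="unknown"):
            ScenarioConfig.from_file(path)

    def test_scale_stats_from_base(self, base_cohort):
        stats = compute_scale_stats(base_cohort)
        assert set(stats) == {"age", "distance", "elig_months", "mc_months", "elixhauser"}
        mean, sd = stats["age"]
        assert mean == pytest.approx(base_cohort.data["age"].mean())
        assert sd == pytest.approx(base_cohort.data["age"].std(ddof=1))
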