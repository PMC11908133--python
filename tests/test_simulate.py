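import math

import numpy as np
import pandas as pd
import pytest

from clonedyn.errors import ParameterError
from clonedyn.simulate import (
    COHORT_DESIGNS,
    CloneSpec,
    VariantSpec,
    _latent_vafs,
    extinction_probability,
    sample_birth_death,
    simulate_clone,
    simulate_cohort,
    simulate_markers,
    simulate_participant,
    simulate_survival,
)


class TestSimulateClone:
    def test_deterministic_reference_value(self):
        x = simulate_clone(0.1, 50.0, [120.0])
        assert x[0] == pytest.approx(1096.6331584284585, abs=1e-9)

    def test_neutral_clone_stays_single(self):
        assert simulate_clone(0.0, 30.0, [80.0])[0] == 1.0

    def test_deterministic_ratio_identity(self):
        ages = [55.0, 62.0, 69.0]
        x = simulate_clone(0.23, 40.0, ages)
        assert x[1] / x[0] == pytest.approx(math.exp(0.23 * 7.0), rel=1e-12)
        assert x[2] / x[1] == pytest.approx(math.exp(0.23 * 7.0), rel=1e-12)

    def test_pre_acquisition_zero_and_empty(self):
        x = simulate_clone(0.2, 60.0, [50.0, 70.0])
        assert x[0] == 0.0 and x[1] > 0
        assert simulate_clone(0.2, 60.0, []).size == 0

    def test_negative_fitness_error(self):
        with pytest.raises(ParameterError):
            simulate_clone(-0.1, 10.0, [50.0])


class TestBirthDeath:
    def test_conditioned_mean_matches_analytic(self, rng):
        """Monte-Carlo mean of conditioned paths vs the analytic expectation."""
        s, atma, age, n = 0.2, 40.0, 70.0, 10_000
        sizes = sample_birth_death(s, atma, [age], rng, n=n)[:, 0]
        alpha = extinction_probability(s, age - atma)
        analytic = math.exp(s * (age - atma)) / (1.0 - alpha)
        se = sizes.std() / math.sqrt(n)
        assert abs(sizes.mean() - analytic) < 3 * se

    def test_unconditioned_mean_matches_exponential(self, rng):
        s, atma, age, n = 0.2, 40.0, 55.0, 20_000
        sizes = sample_birth_death(s, atma, [age], rng, n=n, condition_on_survival=False)[:, 0]
        se = sizes.std() / math.sqrt(n)
        assert abs(sizes.mean() - math.exp(s * (age - atma))) < 3 * se

    def test_nonnegative_integers_no_resurrection(self, rng):
        paths = sample_birth_death(0.05, 30.0, [40.0, 50.0, 60.0, 70.0], rng, n=2000,
                                   condition_on_survival=False)
        assert paths.dtype.kind == "i" and np.all(paths >= 0)
        for row in paths:
            dead = np.flatnonzero(row == 0)
            if dead.size:
                assert np.all(row[dead[0]:] == 0)

    def test_single_realization_mode(self):
        x = simulate_clone(0.2, 40.0, [50.0, 60.0], mode="birth_death", seed=7)
        assert x.shape == (2,) and x[0] >= 1  # conditioned on survival


class TestSimulateParticipant:
    def test_single_clone_monotone_expected_vaf(self, rng):
        scen = [CloneSpec(0.3, (VariantSpec("JAK2", "v", 45.0),))]
        vafs = _latent_vafs(scen, np.array([70.0, 76.0, 82.0]), __import__("clonedyn").GrowthModelParams())
        v = vafs["JAK2:v"]
        assert np.all(np.diff(v) > 0)

    def test_equal_clones_symmetric(self):
        from clonedyn.growth import GrowthModelParams

        scen = [
            CloneSpec(0.2, (VariantSpec("TET2", "a", 30.0),)),
            CloneSpec(0.2, (VariantSpec("JAK2", "b", 30.0),)),
        ]
        vafs = _latent_vafs(scen, np.array([60.0, 70.0, 80.0]), GrowthModelParams())
        assert np.allclose(vafs["TET2:a"], vafs["JAK2:b"])

    def test_nested_later_variant_smaller(self):
        from clonedyn.growth import GrowthModelParams

        scen = [CloneSpec(0.25, (VariantSpec("TET2", "a", 25.0), VariantSpec("SF3B1", "b", 40.0)))]
        vafs = _latent_vafs(scen, np.array([55.0, 65.0, 75.0]), GrowthModelParams())
        assert np.all(vafs["SF3B1:b"] <= vafs["TET2:a"])

    def test_binomial_read_noise_unbiased(self, rng):
        """Empirical mean of alt/depth over many draws is within 3 SE of VAF."""
        v, d, n = 0.0375, 2000, 10_000
        draws = rng.binomial(d, v, size=n) / d
        tol = 3 * math.sqrt(v * (1 - v) / (n * d))
        assert abs(draws.mean() - v) < tol

    def test_duplicate_labels_rejected(self, rng):
        scen = [CloneSpec(0.2, (VariantSpec("TET2", "a", 30.0), VariantSpec("TET2", "a", 40.0)))]
        with pytest.raises(ParameterError):
            simulate_participant(scen, [60.0], rng)

    def test_empty_scenario_gives_empty_rows(self, rng):
        rows, truth = simulate_participant([], [60.0, 70.0], rng)
        assert rows == [] and truth.blocks == ()


class TestSimulateCohort:
    def test_lbc_template_contract(self):
        tables = simulate_cohort("LBC", 10, seed=11)
        v = tables["variants"]
        for _, sub in v.groupby("participant_id"):
            ages = np.sort(sub["age"].unique())
            assert len(ages) == 3
            assert abs(ages[0] - 70) < 4 and abs(ages[1] - 76) < 4 and abs(ages[2] - 82) < 4

    def test_whi_all_female(self):
        tables = simulate_cohort("WHI", 15, seed=2)
        assert (tables["covariates"]["sex"] == "F").all()

    def test_same_seed_byte_identical(self):
        a = simulate_cohort("SardiNIA", 8, seed=5)
        b = simulate_cohort("SardiNIA", 8, seed=5)
        for key in a:
            assert a[key].to_csv(index=False) == b[key].to_csv(index=False)

    def test_unknown_template_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cohort("UKB", 5)

    def test_truth_table_keys_match_variants(self):
        tables = simulate_cohort("LBC", 6, seed=9)
        truth_keys = set(zip(tables["truth"]["participant_id"], tables["truth"]["variant"]))
        v = tables["variants"]
        obs_keys = {(p, f"{g}:{m}") for p, g, m in zip(v["participant_id"], v["gene"], v["variant"])}
        assert obs_keys == truth_keys


class TestSimulateMarkers:
    def _metrics(self, n, rng):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "cohort": "synthetic",
                "max_vaf": rng.uniform(0.01, 0.4, n),
                "max_fitness": rng.uniform(0.02, 0.4, n),
                "log_macs120": rng.uniform(0, 30, n),
            }
        )

    def test_null_model_is_standard_normal_plus_intercept(self, rng):
        metrics = self._metrics(200, rng)
        visits = {p: [60.0, 65.0, 70.0] for p in metrics["participant_id"]}
        df = simulate_markers(metrics, visits, {"M": {}}, random_intercept_sd=0.0,
                              residual_sd=1.0, rng=rng)
        v = df["value"].to_numpy()
        assert abs(v.mean()) < 3 / math.sqrt(len(v))
        assert abs(v.std() - 1.0) < 0.05

    def test_binary_marker_values(self, rng):
        metrics = self._metrics(50, rng)
        visits = {p: [60.0, 65.0] for p in metrics["participant_id"]}
        df = simulate_markers(metrics, visits, {"B": {}}, rng=rng, binary_markers=("B",))
        assert set(df["value"].unique()) <= {0.0, 1.0}

    def test_zero_visits_error(self, rng):
        metrics = self._metrics(3, rng)
        visits = {p: [] for p in metrics["participant_id"]}
        with pytest.raises(ParameterError):
            simulate_markers(metrics, visits, {"M": {}}, rng=rng)


class TestSimulateSurvival:
    def _metrics(self, n, rng):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "sex": rng.choice(["F", "M"], n),
                "age_first_obs": rng.uniform(50, 85, n),
                "max_vaf": rng.uniform(0.01, 0.4, n),
                "max_fitness": rng.uniform(0.02, 0.4, n),
                "log_macs120": rng.uniform(0, 30, n),
            }
        )

    def test_full_censoring(self, rng):
        surv = simulate_survival(self._metrics(40, rng), censor_rate=1.0, rng=rng)
        assert (surv["event"] == 0).all()

    def test_no_censoring(self, rng):
        surv = simulate_survival(self._metrics(40, rng), censor_rate=0.0, rng=rng)
        assert (surv["event"] == 1).all()

    def test_negative_baseline_rejected(self, rng):
        with pytest.raises(ParameterError):
            simulate_survival(self._metrics(5, rng), baseline_hazard=-0.1, rng=rng)

    def test_null_coefficients_logrank_uniform(self, rng):
        """With zero effects, covariate-split halves have indistinguishable survival."""
        from lifelines.statistics import logrank_test

        pvals = []
        for rep in range(20):
            m = self._metrics(120, rng)
            surv = simulate_survival(m, coefs={}, censor_rate=0.3, rng=rng)
            merged = surv.merge(m, on="participant_id")
            hi = merged["log_macs120"] > merged["log_macs120"].median()
            res = logrank_test(
                merged.loc[hi, "time"], merged.loc[~hi, "time"],
                merged.loc[hi, "event"], merged.loc[~hi, "event"],
            )
            pvals.append(res.p_value)
        # uniform-ish p over replicates: not clustered near 0
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_design_registry(self):
        assert set(COHORT_DESIGNS) == {"LBC", "SardiNIA", "WHI"}
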