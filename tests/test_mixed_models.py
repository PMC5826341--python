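"""Tests of the Laplace GLMM engine, likelihood-ratio machinery, ablation
sweep, vowel models and the estimation-robustness sweep."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lingadapt import (
    ModelSpec,
    RandomTerm,
    WorldConfig,
    ablation_sweep,
    estimation_sweep,
    fit_mixed,
    generate_world,
    lrt,
    vowel_models,
)
from lingadapt.mixed_models import ABLATION_ROWS, ModelFit, tone_model_spec


def _zscore(x):
    return (x - x.mean()) / x.std(ddof=0)


@pytest.fixture(scope="module")
def small_world():
    return generate_world(WorldConfig(n_families=20, languages_per_family=10, seed=21))


class TestFitMixedGlmSpecialCase:
    """With no random terms the engine must match plain ML GLMs."""

    def test_poisson_matches_statsmodels(self, small_world):
        fit = fit_mixed(small_world, ModelSpec("n_tones", "poisson-log", ("humidity",)))
        X = sm.add_constant(_zscore(small_world["humidity"]))
        ref = sm.GLM(small_world["n_tones"], X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ref.params.to_numpy(), atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_gaussian_matches_ols(self, small_world):
        df = small_world.assign(ratio=small_world["n_vowels"]
                                / (small_world["n_vowels"] + small_world["n_consonants"]))
        fit = fit_mixed(df, ModelSpec("ratio", "gaussian-identity", ("humidity",)))
        ref = sm.OLS(df["ratio"], sm.add_constant(_zscore(df["humidity"]))).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ref.params.to_numpy(), atol=1e-6)

    def test_binomial_matches_statsmodels(self, small_world):
        df = small_world.assign(total=small_world["n_vowels"] + small_world["n_consonants"])
        fit = fit_mixed(
            df, ModelSpec("n_vowels", "binomial-logit", ("humidity",), trials="total")
        )
        X = sm.add_constant(_zscore(df["humidity"]))
        ref = sm.GLM(
            np.column_stack([df["n_vowels"], df["total"] - df["n_vowels"]]),
            X,
            family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ref.params.to_numpy(), atol=1e-6)


class TestFitMixed:
    def test_gaussian_random_intercept_matches_mixedlm(self, rng):
        """Independent cross-check of the Laplace engine (exact for gaussian)
        against statsmodels MixedLM maximum likelihood."""
        n = 300
        groups = rng.integers(0, 15, n)
        x = rng.normal(0, 1, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.7, 15)[groups] + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        fit = fit_mixed(df, ModelSpec("y", "gaussian-identity", ("x",),
                                      (RandomTerm("g", "intercept"),)))
        ref = sm.MixedLM(df["y"], sm.add_constant(_zscore(df["x"])), groups=df["g"]).fit(
            reml=False
        )
        np.testing.assert_allclose(fit.coef.to_numpy(), ref.fe_params.to_numpy(), atol=2e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-2)

    def test_zero_variance_world_agrees_with_glm(self, flat_world):
        mixed = fit_mixed(flat_world, tone_model_spec())
        glm = fit_mixed(flat_world, ModelSpec("n_tones", "poisson-log", ("humidity",)))
        b, se = mixed.coef["humidity"], mixed.params.set_index("term").loc["humidity", "se"]
        assert abs(b - glm.coef["humidity"]) < 2 * se

    def test_estimate_invariant_to_group_relabeling(self, small_world):
        relabeled = small_world.copy()
        relabeled["family_id"] = "Z" + relabeled["family_id"]
        spec = ModelSpec("n_tones", "poisson-log", ("humidity",),
                         (RandomTerm("family_id", "intercept"),))
        a = fit_mixed(small_world, spec)
        b = fit_mixed(relabeled, spec)
        assert a.coef["humidity"] == pytest.approx(b.coef["humidity"], abs=1e-8)

    def test_degenerate_predictor_flagged_not_fatal(self, small_world):
        df = small_world.assign(humidity=0.01)
        fit = fit_mixed(df, ModelSpec("n_tones", "poisson-log", ("humidity",)))
        assert "humidity" in fit.degenerate
        assert np.isnan(fit.params.set_index("term").loc["humidity", "estimate"])

    def test_missing_response_column(self, small_world):
        with pytest.raises(ValueError, match="missing"):
            fit_mixed(small_world, ModelSpec("nope", "poisson-log", ()))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "poisson-log", ("a", "a"))
        with pytest.raises(ValueError):
            RandomTerm("g", "slope")
        with pytest.raises(ValueError):
            ModelSpec("y", "binomial-logit", ())


class TestLrt:
    def test_identical_fits_give_zero(self, small_world):
        spec = ModelSpec("n_tones", "poisson-log", ("humidity",))
        fit = fit_mixed(small_world, spec)
        stat, df, p = lrt(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_statistic_is_twice_loglik_gap(self, small_world):
        """A log-likelihood gap of 0.22 corresponds to a chi-square statistic
        of 0.44 (internal consistency of the definition)."""
        spec1 = ModelSpec("n_tones", "poisson-log", ("humidity",))
        spec0 = ModelSpec("n_tones", "poisson-log", ())
        fit1 = fit_mixed(small_world, spec1)
        fit0 = fit_mixed(small_world, spec0)
        stat, df, _ = lrt(fit0, fit1)
        assert stat == pytest.approx(2 * (fit1.loglik - fit0.loglik))
        assert df == 1
        synthetic_null = ModelFit(
            spec=spec0, params=fit0.params, loglik=fit1.loglik - 0.22,
            converged=True, vc={}, n=fit1.n,
        )
        stat2, _, _ = lrt(synthetic_null, fit1)
        assert stat2 == pytest.approx(0.44, abs=1e-9)

    def test_planted_effect_strongly_significant(self):
        w = generate_world(WorldConfig(beta_humidity_tone=0.5, seed=31))
        fit1 = fit_mixed(w, ModelSpec("n_tones", "poisson-log", ("humidity",)))
        fit0 = fit_mixed(w, ModelSpec("n_tones", "poisson-log", ()))
        assert lrt(fit0, fit1)[2] < 0.001

    def test_nonnested_rejected(self, small_world):
        f1 = fit_mixed(small_world, ModelSpec("n_tones", "poisson-log", ("humidity",)))
        f2 = fit_mixed(small_world, ModelSpec("n_tones", "poisson-log", ("latitude",)))
        with pytest.raises(ValueError, match="nested"):
            lrt(f1, f2)

    def test_statistic_nonnegative_for_nested_fits(self, small_world):
        spec1 = ModelSpec("n_tones", "poisson-log", ("humidity",),
                          (RandomTerm("family_id", "intercept"),))
        fit1 = fit_mixed(small_world, spec1)
        fit0 = fit_mixed(small_world, spec1.drop_fixed("humidity"))
        stat, _, _ = lrt(fit0, fit1)
        assert stat >= -1e-6


class TestAblationSweep:
    def test_row_labels_match_contract(self, small_world):
        table = ablation_sweep(small_world)
        assert tuple(table["model"]) == ABLATION_ROWS

    def test_no_clustering_rows_agree_within_two_se(self, flat_world):
        table = ablation_sweep(flat_world).set_index("model")
        betas = table["estimate"]
        ses = table["se"]
        for row in betas.index:
            assert abs(betas[row] - betas["Full model"]) < 2 * ses[row]

    def test_missing_column_rejected(self, small_world):
        with pytest.raises(ValueError, match="n_tones"):
            ablation_sweep(small_world.drop(columns=["n_tones"]))


class TestVowelModels:
    def test_planted_humidity_effect_detected_in_majority(self):
        n_sig = 0
        for seed in range(5):
            w = generate_world(WorldConfig(seed=600 + seed, beta_humidity_vowel=0.3))
            res = vowel_models(w)
            n_sig += res.ratio_lrt_humidity[2] < 0.05
        assert n_sig >= 3

    def test_constant_humidity_reported_degenerate(self, small_world):
        df = small_world.assign(humidity=0.01)
        res = vowel_models(df)
        assert "humidity" in res.ratio_fit.degenerate

    def test_area_model_runs_with_hull_table(self, small_world):
        from lingadapt import generate_formants, vowel_space_table

        scales = {lid: 0.8 + (i % 5) * 0.1
                  for i, lid in enumerate(small_world["language_id"])}
        areas = vowel_space_table(generate_formants(scales, seed=5))
        res = vowel_models(small_world, hull_areas=areas)
        assert res.area_fit is not None
        assert np.isfinite(res.area_lrt_humidity[0])


class TestEstimationSweep:
    def test_convex_glm_agrees_across_optimizers(self, small_world):
        spec = ModelSpec("n_tones", "poisson-log", ("humidity",))
        rep = estimation_sweep(small_world, spec,
                               optimizers=("nelder-mead", "bfgs", "l-bfgs-b", "powell"))
        assert (rep.max_deviation < 1e-4).all()

    def test_same_optimizer_same_start_is_deterministic(self, small_world):
        spec = ModelSpec("n_tones", "poisson-log", ("humidity",),
                         (RandomTerm("family_id", "intercept"),))
        rep = estimation_sweep(small_world, spec,
                               optimizers=("nelder-mead", "nelder-mead"))
        runs = rep.runs.pivot_table(index="term", columns="optimizer",
                                    values="estimate", aggfunc="first")
        wide = rep.runs.groupby("term")["estimate"].agg(["min", "max"])
        assert ((wide["max"] - wide["min"]).abs() < 1e-12).all()

    def test_run_count_matches_grid(self, small_world):
        spec = ModelSpec("n_tones", "poisson-log", ("humidity",),
                         (RandomTerm("family_id", "intercept"),))
        rep = estimation_sweep(small_world, spec,
                               optimizers=("nelder-mead", "powell"), n_starts=2)
        assert rep.n_runs == 4

    def test_requires_two_optimizers(self, small_world):
        with pytest.raises(ValueError):
            estimation_sweep(small_world,
                             ModelSpec("n_tones", "poisson-log", ()),
                             optimizers=("nelder-mead",))
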