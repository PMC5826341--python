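"""Tests of the synthetic-world generator: determinism, marginal calibration,
effect recovery by an independent ML oracle, and the corpus/formant generators."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from lingadapt import (
    WorldConfig,
    generate_corpus,
    generate_formants,
    generate_world,
    suppress_complex_tone,
)
from lingadapt.world_sim import (
    LANGUAGE_TABLE_COLUMNS,
    dump_world_config,
    load_world_config,
    tone_class,
)


def _flat_config(**kw):
    base = dict(
        beta_humidity_tone=0.0,
        family_intercept_sd=0.0,
        family_slope_sd=0.0,
        area_intercept_sd=0.0,
        area_slope_sd=0.0,
        borrowing_strength=0.0,
    )
    base.update(kw)
    return WorldConfig(**base)


class TestGenerateWorld:
    def test_same_seed_is_bit_identical(self):
        cfg = WorldConfig(seed=3)
        pd.testing.assert_frame_equal(generate_world(cfg), generate_world(cfg))

    def test_different_seed_differs(self):
        a = generate_world(WorldConfig(seed=1))
        b = generate_world(WorldConfig(seed=2))
        assert not a["humidity"].equals(b["humidity"])

    def test_schema_and_invariants(self, default_world):
        w = default_world
        assert tuple(w.columns) == LANGUAGE_TABLE_COLUMNS
        assert w["language_id"].is_unique
        assert (w["n_vowels"] + w["n_consonants"] >= 2).all()
        assert (w["n_vowels"] >= 1).all() and (w["n_consonants"] >= 1).all()
        lo, hi = WorldConfig().humidity_range
        assert w["humidity"].between(lo, hi).all()
        # complex iff three or more tones
        assert ((w["tone_class"] == "complex") == (w["n_tones"] >= 3)).all()
        assert ((w["tone_class"] == "none") == (w["n_tones"] == 0)).all()

    def test_degenerate_parameters_give_single_poisson_rate(self):
        cfg = _flat_config(seed=5, n_families=100, languages_per_family=10)
        w = generate_world(cfg)
        rate = cfg.baseline_tone_rate
        se = np.sqrt(rate / len(w))
        assert abs(w["n_tones"].mean() - rate) < 3 * se

    def test_marginal_poisson_calibration(self):
        """With clustering and confounds off, n_tones is Poisson(baseline):
        chi-square GOF at alpha=0.01 passes in >= 95% of 100 seeded worlds."""
        rate = WorldConfig().baseline_tone_rate
        passed = 0
        for seed in range(100):
            w = generate_world(_flat_config(seed=seed))
            counts = np.bincount(w["n_tones"], minlength=8)[:8]
            # pool the tail so expected cell counts stay reasonable
            expected = stats.poisson.pmf(np.arange(8), rate) * len(w)
            expected[-1] = len(w) - expected[:-1].sum()
            obs = counts.astype(float)
            obs[-1] = len(w) - obs[:-1].sum()
            stat = ((obs - expected) ** 2 / expected).sum()
            p = stats.chi2.sf(stat, len(obs) - 1)
            passed += p > 0.01
        assert passed >= 95

    def test_ml_oracle_recovers_tone_effect(self):
        """Poisson ML regression (clustering-free worlds) recovers the planted
        humidity effect of 0.2 with |bias| < 0.05 over 20 replicate worlds."""
        betas = []
        for seed in range(20):
            cfg = _flat_config(
                beta_humidity_tone=0.2, seed=seed, n_families=50, languages_per_family=20
            )
            w = generate_world(cfg)
            z = (w["humidity"] - w["humidity"].mean()) / w["humidity"].std(ddof=0)
            fit = sm.GLM(w["n_tones"], sm.add_constant(z), family=sm.families.Poisson()).fit()
            betas.append(fit.params.iloc[1])
        assert abs(np.mean(betas) - 0.2) < 0.05

    def test_borrowing_confounds_naive_association(self):
        """With no causal humidity effect but strong areal diffusion, the
        naive (no-clustering-control) Poisson regression finds a significant
        humidity effect in the majority of worlds — the Galton's-problem
        fixture."""
        n_sig = 0
        for seed in range(7):
            cfg = WorldConfig(
                beta_humidity_tone=0.0, borrowing_strength=0.8, seed=seed
            )
            w = generate_world(cfg)
            z = (w["humidity"] - w["humidity"].mean()) / w["humidity"].std(ddof=0)
            fit = sm.GLM(w["n_tones"], sm.add_constant(z), family=sm.families.Poisson()).fit()
            n_sig += fit.pvalues.iloc[1] < 0.05
        assert n_sig >= 4

    @pytest.mark.parametrize(
        "bad",
        [
            dict(family_intercept_sd=-0.1),
            dict(measurement_error_sd=float("nan")),
            dict(humidity_range=(0.02, 0.01)),
            dict(beta_humidity_tone=float("inf")),
            dict(n_families=0),
            dict(languages_per_family=(5, 2)),
            dict(baseline_tone_rate=0.0),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            WorldConfig(**bad)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = WorldConfig(n_families=12, languages_per_family=(2, 6), seed=9)
        path = tmp_path / "world.yaml"
        dump_world_config(cfg, path)
        assert load_world_config(path) == cfg
        (tmp_path / "bad.yaml").write_text("no_such_key: 1\n")
        with pytest.raises(ValueError, match="no_such_key"):
            load_world_config(tmp_path / "bad.yaml")


class TestSuppression:
    def test_zero_strength_is_identity(self, default_world):
        out = suppress_complex_tone(default_world, strength=0.0, seed=1)
        pd.testing.assert_frame_equal(out, default_world)

    def test_dry_complex_share_drops(self, default_world):
        out = suppress_complex_tone(default_world, threshold_quantile=0.5, strength=1.0, seed=1)
        thr = default_world["humidity"].quantile(0.25)
        dry = default_world["humidity"] < thr
        before = (default_world.loc[dry, "n_tones"] >= 3).mean()
        after = (out.loc[dry, "n_tones"] >= 3).mean()
        assert after < before
        assert ((out["tone_class"] == "complex") == (out["n_tones"] >= 3)).all()

    def test_invalid_strength(self, default_world):
        with pytest.raises(ValueError):
            suppress_complex_tone(default_world, strength=1.5)


class TestGenerateCorpus:
    def test_null_shift_keeps_tone3_share_close(self):
        tokens, _ = generate_corpus(0.0, 0.0, 20000, seed=1, n_corpora=1,
                                    n_months=6, corpus_sd=0.0)
        pivot = tokens.groupby(["condition", "tone_category"])["count"].sum().unstack()
        shares = pivot.div(pivot.sum(axis=1), axis=0)["tone3"]
        n = pivot.sum(axis=1).min()
        bound = 3 * np.sqrt(0.21 * 0.79 / n)
        assert abs(shares["trouble_source"] - shares["baseline"]) < bound

    def test_planted_shift_hits_binomial_expectation(self):
        tokens, _ = generate_corpus(0.12, 0.0, 100_000, seed=2, n_corpora=1,
                                    n_months=1, corpus_sd=0.0)
        t = tokens[tokens["condition"] == "trouble_source"]
        share = t.loc[t["tone_category"] == "tone3", "count"].sum() / t["count"].sum()
        assert abs(share - 0.33) < 0.01

    def test_null_monthly_effect_is_flat(self):
        tokens, _ = generate_corpus(0.0, 0.0, 5000, seed=3, n_corpora=1,
                                    n_months=12, corpus_sd=0.0)
        base = tokens[tokens["condition"] == "baseline"]
        contour = base[base["tone_category"] != "tone1"]
        monthly = contour.groupby("date")["count"].sum() / base.groupby("date")["count"].sum()
        p = monthly.mean()
        sd = np.sqrt(p * (1 - p) / base.groupby("date")["count"].sum().mean())
        assert monthly.max() - monthly.min() < 3 * sd

    def test_probability_overflow_rejected(self):
        with pytest.raises(ValueError, match="tone-3"):
            generate_corpus(0.9, 0.0, 100, seed=1)

    def test_n_tokens_validated(self):
        with pytest.raises(ValueError):
            generate_corpus(0.0, 0.0, 0)


class TestGenerateFormants:
    def test_zero_dispersion_collapses_points(self):
        f = generate_formants({"L": 0.0}, k_vowels=4, jitter_sd=0.0, seed=1)
        assert f["f1"].nunique() == 1 and f["f2"].nunique() == 1

    def test_template_triangle_area_by_shoelace(self):
        from lingadapt import hull_area

        f = generate_formants({"L": 1.0}, k_vowels=6, jitter_sd=0.0, seed=1)
        area = hull_area(f[["f1", "f2"]].to_numpy())
        # shoelace by hand on (300,800), (800,1100), (300,2300)
        assert area == pytest.approx(375_000.0, rel=1e-9)

    def test_scaling_dispersion_scales_area_quadratically(self):
        from lingadapt import hull_area

        f1 = generate_formants({"L": 0.5}, jitter_sd=0.0, seed=1)
        f2 = generate_formants({"L": 1.0}, jitter_sd=0.0, seed=1)
        a1 = hull_area(f1[["f1", "f2"]].to_numpy())
        a2 = hull_area(f2[["f1", "f2"]].to_numpy())
        assert a2 == pytest.approx(4 * a1, rel=1e-9)

    def test_too_few_vowels_rejected(self):
        with pytest.raises(ValueError):
            generate_formants({"L": 1.0}, k_vowels=2)


def test_tone_class_thresholds():
    out = tone_class([0, 1, 2, 3, 7])
    assert list(out) == ["none", "noncomplex", "noncomplex", "complex", "complex"]
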