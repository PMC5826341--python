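"""Tests of the corpus statistics: repair contingency, seasonal contour-tone
modelling, vowel-ratio transcription, and the seasonal smooth."""

import numpy as np
import pandas as pd
import pytest

from lingadapt import (
    ToneContingency,
    contingency_gof,
    contingency_test,
    generate_corpus,
    seasonal_contour,
    seasonal_smooth,
    vowel_ratio_series,
)
from lingadapt.corpus_stats import read_lexicon, read_phoneme_classes, round_half_away

# Mandarin toneme counts: general-corpus baseline vs turns that elicited
# open other-initiated repair
REPAIR_BASELINE = (46, 44, 43, 71)
REPAIR_TROUBLE = (56, 34, 75, 64)


class TestContingency:
    def test_repair_counts_chi_square(self):
        table = ToneContingency.from_counts(REPAIR_BASELINE, REPAIR_TROUBLE)
        res = contingency_test(table)
        assert res.chi2 == pytest.approx(9.89, abs=0.01)
        assert res.df == 3
        assert res.p < 0.05

    def test_repair_percentage_difference_row(self):
        table = ToneContingency.from_counts(REPAIR_BASELINE, REPAIR_TROUBLE)
        assert list(table.percentage_differences) == [2, -7, 12, -7]
        assert list(table.rounded_percentages.loc["trouble_source"]) == [24, 15, 33, 28]

    def test_identical_rows_give_zero(self):
        table = ToneContingency.from_counts((10, 20, 30), (10, 20, 30))
        res = contingency_test(table)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_column_total_names_category(self):
        table = ToneContingency.from_counts((1, 0, 3), (2, 0, 4))
        with pytest.raises(ValueError, match="tone2"):
            contingency_test(table)

    def test_matches_hand_expected_counts_oracle(self, rng):
        """Pearson chi-square against an explicit E = (row total x column
        total) / grand total computation."""
        for _ in range(50):
            counts = rng.integers(1, 60, size=(2, 4))
            table = ToneContingency.from_counts(counts[0], counts[1])
            res = contingency_test(table)
            grand = counts.sum()
            expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / grand
            stat = ((counts - expected) ** 2 / expected).sum()
            assert res.chi2 == pytest.approx(stat, abs=1e-9)

    def test_reordering_categories_preserves_statistic(self):
        a = contingency_test(ToneContingency.from_counts(REPAIR_BASELINE, REPAIR_TROUBLE))
        perm = [3, 1, 0, 2]
        b = contingency_test(ToneContingency.from_counts(
            [REPAIR_BASELINE[i] for i in perm], [REPAIR_TROUBLE[i] for i in perm]
        ))
        assert a.chi2 == pytest.approx(b.chi2)

    def test_goodness_of_fit_variant(self):
        table = ToneContingency.from_counts(REPAIR_BASELINE, REPAIR_TROUBLE)
        gof = contingency_gof(table)
        assert gof.df == 3
        assert gof.chi2 > 0 and gof.chi2 != contingency_test(table).chi2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ToneContingency.from_counts((1, -2), (3, 4))

    def test_round_half_away(self):
        assert list(round_half_away([1.5, -1.5, 2.4, -2.6])) == [2, -2, 2, -3]


class TestSeasonalContour:
    def test_planted_effect_detected(self):
        n_sig = 0
        for seed in range(3):
            tokens, monthly = generate_corpus(0.0, 0.5, 400, seed=800 + seed, corpus_sd=0.2)
            res = seasonal_contour(tokens, monthly)
            n_sig += res.lrt_humidity[2] < 0.01
        assert n_sig >= 2

    def test_single_month_is_degenerate_not_fatal(self):
        tokens, monthly = generate_corpus(0.0, 0.0, 200, seed=5, n_months=1)
        res = seasonal_contour(tokens, monthly)
        assert res.degenerate
        assert res.lrt_humidity is None

    def test_months_without_humidity_are_excluded_and_counted(self):
        tokens, monthly = generate_corpus(0.0, 0.0, 200, seed=6, n_months=6)
        trimmed = monthly.iloc[:-2]
        res = seasonal_contour(tokens, trimmed)
        assert res.n_excluded_months == 2
        assert len(res.monthly) == 4


class TestVowelRatioSeries:
    LEX = {"ba": ("b", "a"), "tak": ("t", "a", "k"), "a": ("a",), "b": ("b",)}
    CLASSES = {"a": "V", "b": "C", "t": "C", "k": "C"}

    def test_balanced_document_has_ratio_one(self):
        out = vowel_ratio_series([("d1", "2001-01-01", "b a b a")],
                                 self.LEX, self.CLASSES)
        row = out.iloc[0]
        assert row["ratio"] == 1.0 and row["coverage"] == 1.0 and not row["flagged"]

    def test_constructed_two_to_one_consonant_mix(self):
        out = vowel_ratio_series([("d1", "2001-01-01", ["tak", "tak", "ba"])],
                                 self.LEX, self.CLASSES)
        # phones: t a k t a k b a -> 3 V, 5 C... use tak alone for exact 0.5
        out2 = vowel_ratio_series([("d2", "2001-01-02", ["tak", "tak"])],
                                  self.LEX, self.CLASSES)
        assert out2.iloc[0]["ratio"] == 0.5

    def test_out_of_lexicon_token_reduces_coverage(self):
        out = vowel_ratio_series([("d1", "2001-01-01", "ba xyzzy")],
                                 self.LEX, self.CLASSES)
        row = out.iloc[0]
        assert row["coverage"] == 0.5 and row["ratio"] == 1.0

    def test_empty_document_flagged(self):
        out = vowel_ratio_series([("d1", "2001-01-01", [])], self.LEX, self.CLASSES)
        assert out.iloc[0]["flagged"] and np.isnan(out.iloc[0]["ratio"])

    def test_token_order_irrelevant(self):
        a = vowel_ratio_series([("d", "x", ["ba", "tak", "a"])], self.LEX, self.CLASSES)
        b = vowel_ratio_series([("d", "x", ["a", "ba", "tak"])], self.LEX, self.CLASSES)
        assert a.iloc[0]["ratio"] == b.iloc[0]["ratio"]

    def test_tsv_loaders(self, tmp_path):
        lex = tmp_path / "lex.tsv"
        lex.write_text("ba\tb a\n# comment\ntak\tt a k\n")
        cls = tmp_path / "cls.tsv"
        cls.write_text("a\tV\nb\tC\nt\tC\nk\tC\n")
        assert read_lexicon(lex)["ba"] == ("b", "a")
        assert read_phoneme_classes(cls)["a"] == "V"
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tQ\n")
        with pytest.raises(ValueError):
            read_phoneme_classes(bad)


def _daily_frames(rng, n_days=900, effect=0.0, noise=0.004):
    dates = pd.date_range("2001-01-01", periods=n_days, freq="D")
    hum = 0.01 + 0.004 * np.sin(2 * np.pi * dates.dayofyear / 365) \
        + rng.normal(0, 5e-4, n_days)
    ratio = 0.66 + effect * hum + rng.normal(0, noise, n_days)
    return (
        pd.DataFrame({"date": dates.astype(str), "ratio": ratio}),
        pd.DataFrame({"date": dates.astype(str), "humidity": hum}),
    )


class TestSeasonalSmooth:
    def test_planted_monotone_effect_detected_with_sign(self, rng):
        series, cov = _daily_frames(rng, effect=8.0)
        res = seasonal_smooth(series, cov)
        assert res.p < 0.001
        assert res.slope_sign == 1

    def test_constant_series_fits_flat_trend(self, rng):
        series, cov = _daily_frames(rng, noise=0.0, effect=0.0)
        series["ratio"] = 0.66
        res = seasonal_smooth(series, cov)
        assert res.p == pytest.approx(1.0)
        assert np.allclose(res.trend["fitted"], 0.66, atol=1e-9)

    def test_insufficient_span_rejected(self, rng):
        series, cov = _daily_frames(rng, n_days=300)
        with pytest.raises(ValueError, match="two years"):
            seasonal_smooth(series, cov)
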