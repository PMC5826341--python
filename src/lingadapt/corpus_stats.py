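"""Corpus-facing statistics: repair contingencies, seasonal tone use, and
phoneme-level vowel ratios.

Three corpus analyses probe individual links of the adaptation hypothesis:

* **miscommunication** — are hard-to-produce tone categories over-represented
  in conversational turns that triggered other-initiated repair?  A 2 x K
  contingency of tone counts (baseline vs trouble-source condition) is tested
  with Pearson's chi-square;
* **seasonal production** — does the monthly proportion of contour tones in a
  spoken corpus track monthly specific humidity?  A binomial-logit mixed
  model with corpus random intercepts supplies the likelihood-ratio test;
* **individual speech** — does a single speaker's vowel-to-consonant phone
  ratio vary with daily humidity?  Documents are transcribed through a
  user-supplied lexicon and phoneme-class map, and the ratio series is
  analysed with fixed-basis smooths (a periodic Fourier basis over day of
  year, a cubic B-spline basis for the covariate) and a classical F-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import chi2_contingency, chisquare, f as f_dist

from .mixed_models import ModelSpec, RandomTerm, fit_mixed, lrt
from .world_sim import DEFAULT_CONTOUR_CATEGORIES

__all__ = [
    "ToneContingency",
    "ChiSquareResult",
    "contingency_test",
    "contingency_gof",
    "round_half_away",
    "seasonal_contour",
    "SeasonalContourResult",
    "vowel_ratio_series",
    "read_lexicon",
    "read_phoneme_classes",
    "seasonal_smooth",
    "SeasonalSmoothResult",
]

CONDITIONS = ("baseline", "trouble_source")


def round_half_away(x):
    """Round to the nearest integer with halves away from zero (printed-table
    convention)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass
class ToneContingency:
    """2 x K tone-category counts for baseline vs trouble-source turns."""

    counts: pd.DataFrame  # index CONDITIONS, columns tone categories

    def __post_init__(self) -> None:
        counts = self.counts
        if list(counts.index) != list(CONDITIONS):
            raise ValueError(f"counts index must be {CONDITIONS}")
        arr = counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @classmethod
    def from_counts(cls, baseline, trouble_source, categories=None) -> "ToneContingency":
        baseline = list(baseline)
        trouble_source = list(trouble_source)
        if categories is None:
            categories = [f"tone{i + 1}" for i in range(len(baseline))]
        return cls(
            pd.DataFrame(
                [baseline, trouble_source], index=list(CONDITIONS), columns=list(categories)
            ).astype(int)
        )

    @property
    def percentages(self) -> pd.DataFrame:
        """Unrounded within-condition percentages."""
        counts = self.counts.to_numpy(dtype=float)
        return pd.DataFrame(
            100.0 * counts / counts.sum(axis=1, keepdims=True),
            index=self.counts.index,
            columns=self.counts.columns,
        )

    @property
    def rounded_percentages(self) -> pd.DataFrame:
        return self.percentages.apply(round_half_away)

    @property
    def percentage_differences(self) -> pd.Series:
        """Per-category trouble-source minus baseline percentage points,
        rounded half-away-from-zero (the convention that matches printed
        contingency tables); see also ``raw_percentage_differences``."""
        raw = self.raw_percentage_differences
        return pd.Series(round_half_away(raw.to_numpy()), index=raw.index)

    @property
    def raw_percentage_differences(self) -> pd.Series:
        pct = self.percentages
        return pct.loc["trouble_source"] - pct.loc["baseline"]


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def contingency_test(table: ToneContingency) -> ChiSquareResult:
    """Pearson chi-square homogeneity test (no continuity correction) on the
    2 x K tone counts; df = K - 1.  A zero column total is rejected with the
    offending category named."""
    counts = table.counts
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column total for category {zero.index[0]!r}")
    res = chi2_contingency(counts.to_numpy(), correction=False)
    return ChiSquareResult(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def contingency_gof(table: ToneContingency) -> ChiSquareResult:
    """Alternative reading: goodness-of-fit of the trouble-source counts
    against the baseline proportions treated as fixed; df = K - 1."""
    base = table.counts.loc["baseline"].to_numpy(dtype=float)
    trouble = table.counts.loc["trouble_source"].to_numpy(dtype=float)
    if (base == 0).any():
        raise ValueError("baseline proportions undefined for a zero category")
    expected = base / base.sum() * trouble.sum()
    stat, p = chisquare(trouble, expected)
    return ChiSquareResult(chi2=float(stat), df=len(base) - 1, p=float(p))


# ---------------------------------------------------------------------------
# seasonal contour-tone analysis


@dataclass
class SeasonalContourResult:
    monthly: pd.DataFrame  # date, contour, total, proportion
    fit: object | None
    lrt_humidity: tuple | None
    n_excluded_months: int
    degenerate: bool = False
    note: str = ""


def seasonal_contour(
    tokens: pd.DataFrame,
    monthly_humidity: pd.DataFrame,
    contour_categories: tuple[str, ...] = DEFAULT_CONTOUR_CATEGORIES,
) -> SeasonalContourResult:
    """Monthly contour-tone proportions and a humidity likelihood-ratio test.

    Token counts are aggregated to (corpus, month) cells with contour vs
    level totals using the supplied tone-to-class mapping; months without a
    humidity value are excluded (their number is reported).  A binomial-logit
    mixed model with random corpus intercepts tests whether z-scored monthly
    humidity predicts the contour proportion.  With a single month (or
    constant humidity) the humidity term is inestimable and the result is
    flagged degenerate rather than raising.
    """
    df = tokens.copy()
    df["is_contour"] = df["tone_category"].isin(contour_categories)
    cell = (
        df.groupby(["corpus_id", "date"])
        .apply(
            lambda g: pd.Series(
                {
                    "contour": int(g.loc[g["is_contour"], "count"].sum()),
                    "total": int(g["count"].sum()),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    known = set(monthly_humidity["date"])
    n_excluded = cell.loc[~cell["date"].isin(known), "date"].nunique()
    cell = cell.merge(monthly_humidity, on="date", how="inner")

    monthly = (
        cell.groupby("date")[["contour", "total"]].sum().reset_index().sort_values("date")
    )
    monthly["proportion"] = monthly["contour"] / monthly["total"]

    if cell["date"].nunique() < 2 or cell["humidity"].std() == 0:
        return SeasonalContourResult(
            monthly=monthly, fit=None, lrt_humidity=None,
            n_excluded_months=int(n_excluded), degenerate=True,
            note="humidity term inestimable: single month or constant humidity",
        )
    spec = ModelSpec(
        "contour",
        "binomial-logit",
        ("humidity",),
        (RandomTerm("corpus_id", "intercept"),),
        trials="total",
    )
    fit_full = fit_mixed(cell, spec)
    fit_null = fit_mixed(cell, spec.drop_fixed("humidity"))
    return SeasonalContourResult(
        monthly=monthly,
        fit=fit_full,
        lrt_humidity=lrt(fit_null, fit_full),
        n_excluded_months=int(n_excluded),
    )


# ---------------------------------------------------------------------------
# phoneme-level vowel ratio series


def read_lexicon(path) -> dict:
    """Lexicon TSV: word <tab> space-separated phonemes."""
    lex = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            word, _, phones = line.partition("\t")
            lex[word.strip().lower()] = tuple(phones.split())
    return lex


def read_phoneme_classes(path) -> dict:
    """Phoneme-class TSV: phoneme <tab> V or C."""
    classes = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            phone, _, cls = line.partition("\t")
            cls = cls.strip().upper()
            if cls not in ("V", "C"):
                raise ValueError(f"phoneme class must be V or C, got {cls!r}")
            classes[phone.strip()] = cls
    return classes


def vowel_ratio_series(documents, lexicon: dict, phoneme_classes: dict) -> pd.DataFrame:
    """Per-document vowel/consonant phone ratio with transcription coverage.

    ``documents`` is an iterable of ``(doc_id, date, tokens)`` where tokens is
    a sequence of word tokens (or one whitespace-joined string).  Tokens
    absent from the lexicon are skipped and reflected in ``coverage``; a
    document with no transcribable tokens (or no consonant phones) gets a NaN
    ratio and ``flagged = True``.  Token order within a document is
    irrelevant.
    """
    rows = []
    for doc_id, date, tokens in documents:
        if isinstance(tokens, str):
            tokens = tokens.split()
        n_tok = len(tokens)
        covered = 0
        v = c = 0
        for tok in tokens:
            phones = lexicon.get(str(tok).lower())
            if phones is None:
                continue
            covered += 1
            for ph in phones:
                cls = phoneme_classes.get(ph)
                if cls == "V":
                    v += 1
                elif cls == "C":
                    c += 1
        ratio = v / c if c > 0 else float("nan")
        rows.append(
            {
                "doc_id": doc_id,
                "date": date,
                "vowel_count": v,
                "consonant_count": c,
                "ratio": ratio,
                "coverage": covered / n_tok if n_tok else 0.0,
                "flagged": n_tok == 0 or c == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["doc_id", "date", "vowel_count", "consonant_count",
                 "ratio", "coverage", "flagged"],
    )


# ---------------------------------------------------------------------------
# seasonal smooth of the ratio series


def _fourier_basis(day_of_year: np.ndarray, n_harmonics: int) -> np.ndarray:
    t = 2 * np.pi * day_of_year / 365.25
    cols = []
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(k * t))
        cols.append(np.cos(k * t))
    return np.column_stack(cols)


def _bspline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with df columns and interior knots at quantiles."""
    degree = 3
    n_interior = max(df - degree, 0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior else np.array([])
    lo, hi = x.min(), x.max()
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    return design[:, 1:]  # drop one column (absorbed by the intercept)


@dataclass
class SeasonalSmoothResult:
    trend: pd.DataFrame  # day_of_year, fitted ratio
    f_stat: float
    df_num: int
    df_den: int
    p: float
    slope_sign: int  # sign of the linear humidity projection
    n: int


def seasonal_smooth(
    series: pd.DataFrame,
    covariate: pd.DataFrame,
    n_harmonics: int = 3,
    spline_df: int = 4,
) -> SeasonalSmoothResult:
    """Periodic trend of the ratio series plus a covariate association F-test.

    ``series`` needs columns (date, ratio); ``covariate`` columns
    (date, humidity); dates are parseable calendar dates spanning at least
    two years (a periodic fit over day-of-year is meaningless on less).  The
    day-of-year trend uses a fixed Fourier basis with ``n_harmonics``
    harmonics; the association test regresses the ratio on a fixed-df cubic
    B-spline basis in the covariate and compares it to the intercept-only
    model with a classical F-test.  The sign of the linear projection of the
    fitted association is reported so a planted monotone effect can be
    checked for direction.
    """
    df = series.merge(covariate, on="date", how="inner").dropna(subset=["ratio", "humidity"])
    if not len(df):
        raise ValueError("no overlapping dates between series and covariate")
    dates = pd.to_datetime(df["date"])
    span_days = (dates.max() - dates.min()).days
    if span_days < 2 * 365:
        raise ValueError("need at least two years of data for a periodic fit")
    y = df["ratio"].to_numpy(dtype=float)
    n = len(y)

    # periodic trend over day of year
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    Xf = np.column_stack([np.ones(n), _fourier_basis(doy, n_harmonics)])
    beta_f, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    grid = np.arange(1, 366, dtype=float)
    trend = pd.DataFrame(
        {
            "day_of_year": grid,
            "fitted": np.column_stack([np.ones(len(grid)), _fourier_basis(grid, n_harmonics)])
            @ beta_f,
        }
    )

    # covariate association: spline regression vs intercept-only
    h = df["humidity"].to_numpy(dtype=float)
    if h.std() == 0 or y.std() == 0:
        # a constant covariate or constant series carries no association
        return SeasonalSmoothResult(trend, 0.0, spline_df, n - spline_df - 1, 1.0, 0, n)
    B = _bspline_basis(h, spline_df)
    X = np.column_stack([np.ones(n), B])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_num = B.shape[1]
    df_den = n - X.shape[1]
    if df_den <= 0 or rss1 <= 0:
        raise ValueError("not enough observations for the spline F-test")
    f_stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    p = float(f_dist.sf(f_stat, df_num, df_den))
    zh = (h - h.mean()) / h.std()
    slope = float(zh @ (X @ beta)) / n
    sign = 0 if abs(slope) < 1e-12 else int(math.copysign(1, slope))
    return SeasonalSmoothResult(trend, float(f_stat), df_num, df_den, p, sign, n)
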