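"""Measurement robustness: inter-source agreement and bias detection.

When two typological databases count the tones of the same languages, their
agreement bounds how much any downstream correlation can be trusted.  This
module computes chance-corrected agreement (Cohen's kappa, with linear or
quadratic disagreement weights for ordered categories), Pearson correlation
and exact-match proportion for paired integer measurements, and a
mixed-model procedure that asks whether the *differences* between the two
sources are biased by language family, geographic area, or a covariate such
as humidity: if the measurement error is unbiased, random intercepts for
family and area should explain no significant variance and the covariate
should not improve the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr

from .mixed_models import ModelSpec, RandomTerm, fit_mixed, lrt

__all__ = [
    "weighted_kappa",
    "crosstab",
    "agreement_report",
    "AgreementReport",
    "bias_test",
    "BiasReport",
]


def _disagreement_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "unweighted":
        return (i != j).astype(float)
    if weighting == "linear":
        return np.abs(i - j) / max(k - 1, 1)
    if weighting == "quadratic":
        return ((i - j) / max(k - 1, 1)) ** 2
    raise ValueError("weighting must be 'linear', 'quadratic' or 'unweighted'")


def weighted_kappa(table, weighting: str = "linear") -> float:
    """Cohen's (weighted) kappa from a square confusion table of counts.

    kappa_w = 1 - sum(w_ij O_ij) / sum(w_ij E_ij), with disagreement weights
    w from the chosen scheme and E the independence expectation from the
    margins.  The unweighted scheme reduces to Cohen's kappa.  If both raters
    use a single category the expected disagreement is zero and kappa is
    undefined; NaN is returned.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] != O.shape[1]:
        raise ValueError("confusion table must be square")
    if (O < 0).any() or O.sum() <= 0:
        raise ValueError("confusion table needs nonnegative counts with a positive total")
    k = O.shape[0]
    n = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    w = _disagreement_weights(k, weighting)
    expected = (w * E).sum()
    if expected == 0:
        return float("nan")
    return float(1.0 - (w * O).sum() / expected)


def crosstab(x, y) -> pd.DataFrame:
    """Square cross-tabulation over the union of observed values (sorted
    numerically), so kappa is defined even when one source never uses a
    category."""
    x = np.asarray(x)
    y = np.asarray(y)
    cats = np.unique(np.concatenate([x, y]))
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=int)
    for a, b in zip(x, y):
        table[idx[a], idx[b]] += 1
    return pd.DataFrame(table, index=cats, columns=cats)


@dataclass
class AgreementReport:
    kappa: float
    weighted_kappa: float
    pearson_r: float
    percent_agreement: float
    n: int
    weighting: str = "linear"


def agreement_report(x, y, weighting: str = "linear") -> AgreementReport:
    """Agreement statistics for two paired integer series (paired by language)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    table = crosstab(x, y).to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(x.astype(float), y.astype(float)).statistic)
    return AgreementReport(
        kappa=weighted_kappa(table, "unweighted"),
        weighted_kappa=weighted_kappa(table, weighting),
        pearson_r=r,
        percent_agreement=float(np.mean(x == y)),
        n=len(x),
        weighting=weighting,
    )


@dataclass
class BiasReport:
    """Variance-component and covariate tests on between-source differences."""

    p_family: float
    p_area: float
    p_covariate: float
    mean_difference: float
    direction: str  # sign of the mean difference


def _variance_component_p(stat: float) -> float:
    """Boundary-corrected LRT p-value for one variance component.

    Testing sigma^2 = 0 places the null on the boundary of the parameter
    space, so the LRT statistic is asymptotically a 50:50 mixture of a point
    mass at zero and chi-square(1); the p-value is half the chi-square(1)
    tail (and 1 when the statistic is nonpositive).
    """
    if stat <= 1e-10:
        return 1.0
    return float(0.5 * chi2.sf(stat, 1))


def bias_test(differences, family, area, covariate) -> BiasReport:
    """Test whether between-source differences are biased.

    Fits a gaussian mixed model of the differences with random intercepts for
    family and area; each variance component is tested by a likelihood-ratio
    test of the full model against the model without that intercept
    (boundary-corrected), and the covariate by an ordinary LRT of adding it
    as a fixed effect.  Constant differences carry no information, so every
    test reports p = 1.
    """
    df = pd.DataFrame(
        {
            "difference": np.asarray(differences, dtype=float),
            "family_id": np.asarray(family),
            "area_id": np.asarray(area),
            "covariate": np.asarray(covariate, dtype=float),
        }
    )
    for col in ("family_id", "area_id"):
        if df[col].nunique() < 2:
            raise ValueError(f"{col} needs at least 2 levels")
    mean_diff = float(df["difference"].mean())
    direction = "positive" if mean_diff > 0 else ("negative" if mean_diff < 0 else "zero")
    if df["difference"].std() == 0:
        return BiasReport(1.0, 1.0, 1.0, mean_diff, direction)

    full_spec = ModelSpec(
        "difference",
        "gaussian-identity",
        (),
        (RandomTerm("family_id", "intercept"), RandomTerm("area_id", "intercept")),
    )
    fit_full = fit_mixed(df, full_spec)
    fit_no_fam = fit_mixed(df, full_spec.drop_random(RandomTerm("family_id", "intercept")))
    fit_no_area = fit_mixed(df, full_spec.drop_random(RandomTerm("area_id", "intercept")))
    p_family = _variance_component_p(2.0 * (fit_full.loglik - fit_no_fam.loglik))
    p_area = _variance_component_p(2.0 * (fit_full.loglik - fit_no_area.loglik))

    if df["covariate"].std() == 0:
        p_cov = 1.0
    else:
        fit_cov = fit_mixed(df, ModelSpec(
            "difference", "gaussian-identity", ("covariate",), full_spec.random_terms))
        _, _, p_cov = lrt(fit_full, fit_cov)
    return BiasReport(p_family, p_area, p_cov, mean_diff, direction)
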