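"""Mixed-effects regressions and structural/estimation robustness sweeps.

Cross-linguistic observations are not independent: languages share descent
(families) and contact (areas), so a credible humidity effect must survive
random intercepts and random humidity slopes for both grouping factors
(Galton's problem).  This module provides a generalized linear mixed model
fitted by maximising the Laplace-approximated marginal likelihood, plus the
robustness procedures built on it: nested-model likelihood-ratio tests,
the five-way random-effect ablation sweep for the Poisson tone model, the
vowel-proportion and vowel-area models, and an optimizer/start-point
stability sweep.

Estimation
----------
Random effects are independent Gaussian blocks, one variance per declared
term (an intercept or a slope-on-a-covariate for one grouping factor).  For
variance parameters ``theta`` (log standard deviations, plus the log residual
sd for the gaussian family) the fixed effects and random-effect modes are
found jointly by a penalized Newton iteration; the marginal log-likelihood is
then the Laplace approximation

    ll(theta) = l(y | eta_hat) - b_hat' D^-1 b_hat / 2
                - log|D|/2 - log|Z'WZ + D^-1|/2

which is exact for the gaussian family.  ``theta`` is optimised by a
derivative-free or numeric-gradient scipy optimizer (configurable — that
choice is precisely what the estimation-robustness sweep varies).  Standard
errors come from the observed information of the marginal likelihood over
the fixed effects and variance parameters jointly (falling back to the
conditional penalized-likelihood Hessian when that information matrix is
not positive definite); confidence intervals use a t reference with
containment degrees of freedom.

Continuous predictors are z-scored before entering the linear predictor and
interactions are formed after scaling, so coefficients are per-standard-
deviation effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln
from scipy.stats import chi2, norm, t as t_dist

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "ModelFit",
    "fit_mixed",
    "lrt",
    "fixed_effect_lrt",
    "ablation_sweep",
    "ABLATION_ROWS",
    "vowel_models",
    "VowelModelResults",
    "estimation_sweep",
    "StabilityReport",
    "DEFAULT_OPTIMIZERS",
]

_FAMILIES = ("poisson-log", "gaussian-identity", "binomial-logit")

#: Seven scipy optimizers used by default in the estimation-robustness sweep.
DEFAULT_OPTIMIZERS = (
    "nelder-mead",
    "powell",
    "l-bfgs-b",
    "bfgs",
    "cg",
    "tnc",
    "slsqp",
)

_THETA_MIN, _THETA_MAX = -8.0, 3.0  # bounds on log-sd to keep D well scaled


@dataclass(frozen=True)
class RandomTerm:
    """One random-effect term: an intercept or a slope for a grouping factor."""

    factor: str
    kind: str = "intercept"  # "intercept" or "slope"
    covariate: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "slope"):
            raise ValueError("kind must be 'intercept' or 'slope'")
        if self.kind == "slope" and not self.covariate:
            raise ValueError(f"slope term for {self.factor!r} requires a covariate")
        if self.kind == "intercept" and self.covariate:
            raise ValueError("intercept term must not name a covariate")

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return f"(1|{self.factor})"
        return f"({self.covariate}|{self.factor})"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model specification.

    ``fixed_terms`` are column names; ``"a:b"`` denotes the interaction of the
    z-scored columns a and b.  ``trials`` names the trial-count column for the
    binomial family (the response column then holds success counts).
    """

    response: str
    family: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[RandomTerm, ...] = ()
    trials: str | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.family == "binomial-logit" and not self.trials:
            raise ValueError("binomial-logit requires a trials column")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("duplicate random terms")

    def drop_fixed(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise ValueError(f"{term!r} not among fixed terms")
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))

    def drop_random(self, term: RandomTerm) -> "ModelSpec":
        if term not in self.random_terms:
            raise ValueError(f"{term.label} not among random terms")
        return replace(self, random_terms=tuple(t for t in self.random_terms if t != term))


@dataclass
class ModelFit:
    """Result of one mixed-model fit."""

    spec: ModelSpec
    params: pd.DataFrame  # term, estimate, se, z, p
    loglik: float
    converged: bool
    vc: dict  # random-term label -> estimated sd
    n: int
    scale: float | None = None  # residual sd (gaussian family)
    degenerate: tuple[str, ...] = ()
    optimizer: str = "nelder-mead"

    #: residual degrees of freedom for interval construction; for mixed fits
    #: this is the containment heuristic (levels of the smallest grouping
    #: factor minus one), since a cluster-level covariate is effectively
    #: replicated at the cluster level, not the observation level
    df_interval: float = math.inf

    @property
    def coef(self) -> pd.Series:
        return self.params.set_index("term")["estimate"]

    def coef_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        row = self.params.set_index("term").loc[term]
        if math.isfinite(self.df_interval):
            crit = t_dist.ppf(0.5 + level / 2.0, self.df_interval)
        else:
            crit = norm.ppf(0.5 + level / 2.0)
        half = crit * row["se"]
        return row["estimate"] - half, row["estimate"] + half

    @property
    def n_parameters(self) -> int:
        n_fixed = int(self.params["estimate"].notna().sum())
        extra = 1 if self.spec.family == "gaussian-identity" else 0
        return n_fixed + len(self.spec.random_terms) + extra


# ---------------------------------------------------------------------------
# design construction


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std()
    # a column that is constant up to floating-point rounding is degenerate
    scale = max(float(np.abs(x).max(initial=0.0)), 1.0)
    if not np.isfinite(sd) or sd <= 1e-12 * scale:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def _build_design(data: pd.DataFrame, spec: ModelSpec):
    """Return (y, trials, X, names, Z, block_sizes, degenerate, covariates)."""
    n = len(data)
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    y = data[spec.response].to_numpy(dtype=float)
    trials = data[spec.trials].to_numpy(dtype=float) if spec.trials else None

    scaled: dict[str, np.ndarray] = {}
    degenerate: list[str] = []

    def get_scaled(col: str) -> np.ndarray:
        if col not in scaled:
            if col not in data.columns:
                raise ValueError(f"predictor column {col!r} missing")
            zs, bad = _zscore(data[col].to_numpy(dtype=float))
            if bad:
                degenerate.append(col)
            scaled[col] = zs
        return scaled[col]

    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in spec.fixed_terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(get_scaled(a) * get_scaled(b))
        else:
            cols.append(get_scaled(term))
        names.append(term)
    # degenerate terms (zero-variance predictors) are dropped from the design
    keep = [i for i, name in enumerate(names)
            if i == 0 or not any(d in name.split(":") or d == name for d in degenerate)]
    X = np.column_stack([cols[i] for i in keep])
    kept_names = [names[i] for i in keep]
    dropped = [names[i] for i in range(len(names)) if i not in keep]

    z_blocks = []
    block_sizes = []
    for term in spec.random_terms:
        if term.factor not in data.columns:
            raise ValueError(f"grouping factor {term.factor!r} missing")
        codes, levels = pd.factorize(data[term.factor], sort=True)
        if len(levels) < 2:
            raise ValueError(f"grouping factor {term.factor!r} needs >= 2 levels")
        values = np.ones(n) if term.kind == "intercept" else get_scaled(term.covariate)
        block = sparse.csr_matrix(
            (values, (np.arange(n), codes)), shape=(n, len(levels))
        )
        z_blocks.append(block)
        block_sizes.append(len(levels))
    Z = sparse.hstack(z_blocks, format="csr") if z_blocks else None
    return y, trials, X, kept_names, dropped, Z, block_sizes


# ---------------------------------------------------------------------------
# family log-likelihoods (eta-parameterised)


def _family_funcs(family: str, y, trials, sigma_e: float | None):
    if family == "poisson-log":
        const = -gammaln(y + 1.0).sum()

        def loglik(eta):
            mu = np.exp(np.clip(eta, -30, 30))
            return float(y @ np.clip(eta, -30, 30) - mu.sum() + const)

        def grad_w(eta):
            mu = np.exp(np.clip(eta, -30, 30))
            return y - mu, mu

    elif family == "binomial-logit":
        const = float(
            (gammaln(trials + 1) - gammaln(y + 1) - gammaln(trials - y + 1)).sum()
        )

        def loglik(eta):
            eta_c = np.clip(eta, -30, 30)
            return float(y @ eta_c - trials @ np.log1p(np.exp(eta_c)) + const)

        def grad_w(eta):
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            return y - trials * p, np.maximum(trials * p * (1.0 - p), 1e-10)

    elif family == "gaussian-identity":
        inv_var = 1.0 / (sigma_e**2)
        const = -0.5 * len(y) * math.log(2 * math.pi * sigma_e**2)

        def loglik(eta):
            return float(const - 0.5 * inv_var * np.sum((y - eta) ** 2))

        def grad_w(eta):
            return inv_var * (y - eta), np.full(len(y), inv_var)

    else:  # pragma: no cover
        raise ValueError(family)
    return loglik, grad_w


# ---------------------------------------------------------------------------
# core fitting


def _penalized_newton(y, X, Z, d_inv_diag, loglik, grad_w, coef0=None, max_iter=60):
    """Jointly maximise the penalized log-likelihood over (beta, b).

    Returns (coef, H, pl, converged) where H is the joint negative Hessian
    (U'WU + P) at the optimum and pl the penalized log-likelihood.
    """
    n, p = X.shape
    q = Z.shape[1] if Z is not None else 0
    coef = np.zeros(p + q) if coef0 is None else coef0.copy()

    def eta_of(c):
        eta = X @ c[:p]
        if q:
            eta = eta + Z @ c[p:]
        return eta

    def pl_of(c):
        pen = 0.5 * np.sum(d_inv_diag * c[p:] ** 2) if q else 0.0
        return loglik(eta_of(c)) - pen

    pl = pl_of(coef)
    converged = False
    H = None
    for _ in range(max_iter):
        eta = eta_of(coef)
        g_eta, w = grad_w(eta)
        Xw = X * w[:, None]
        H = np.empty((p + q, p + q))
        H[:p, :p] = X.T @ Xw
        grad = np.empty(p + q)
        grad[:p] = X.T @ g_eta
        if q:
            XwZ = Z.T.dot(Xw).T  # p x q
            ZwZ = (Z.T @ sparse.diags(w) @ Z).toarray()
            ZwZ[np.diag_indices(q)] += d_inv_diag
            H[:p, p:] = XwZ
            H[p:, :p] = XwZ.T
            H[p:, p:] = ZwZ
            grad[p:] = Z.T @ g_eta - d_inv_diag * coef[p:]
        H[np.diag_indices(p + q)] += 1e-10
        try:
            chol = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            return coef, H, pl, False
        step = cho_solve(chol, grad)
        # step-halving line search on the penalized objective
        t = 1.0
        for _ in range(30):
            cand = coef + t * step
            pl_new = pl_of(cand)
            if np.isfinite(pl_new) and pl_new >= pl - 1e-12:
                break
            t *= 0.5
        else:
            return coef, H, pl, False
        coef = cand
        if abs(pl_new - pl) < 1e-10 * (1.0 + abs(pl)) and np.max(np.abs(t * step)) < 1e-6:
            pl = pl_new
            converged = True
            break
        pl = pl_new
    # refresh Hessian at the optimum
    eta = eta_of(coef)
    _, w = grad_w(eta)
    Xw = X * w[:, None]
    H = np.empty((p + q, p + q))
    H[:p, :p] = X.T @ Xw
    if q:
        XwZ = Z.T.dot(Xw).T
        ZwZ = (Z.T @ sparse.diags(w) @ Z).toarray()
        ZwZ[np.diag_indices(q)] += d_inv_diag
        H[:p, p:] = XwZ
        H[p:, :p] = XwZ.T
        H[p:, p:] = ZwZ
    H[np.diag_indices(p + q)] += 1e-10
    return coef, H, pl, converged


def _moment_theta0(data, spec: ModelSpec, y, trials) -> np.ndarray:
    """Method-of-moments starting values for the variance parameters.

    Intercept terms start at the spread of group means on the link scale;
    slope terms start small; the gaussian residual sd starts at the pooled
    within-group spread.  Good starts matter: the profiled surface can have
    flat plateaus where a derivative-free optimizer stalls.
    """
    link_y = {
        "poisson-log": lambda m: np.log(m + 0.5),
        "binomial-logit": lambda m: np.log((m + 0.02) / (1.0 - m + 0.02)),
        "gaussian-identity": lambda m: m,
    }[spec.family]
    resp = y / np.maximum(trials, 1.0) if spec.family == "binomial-logit" else y
    theta = []
    first_within_sd = None
    for term in spec.random_terms:
        groups = pd.Series(resp).groupby(data[term.factor].to_numpy())
        if term.kind == "intercept":
            means = link_y(groups.mean().to_numpy())
            sd = float(np.nanstd(means))
            theta.append(math.log(min(max(sd, 0.05), 5.0)))
            if first_within_sd is None and spec.family == "gaussian-identity":
                within = resp - groups.transform("mean").to_numpy()
                first_within_sd = float(np.std(within))
        else:
            theta.append(math.log(0.1))
    if spec.family == "gaussian-identity":
        sd_y = float(np.std(y)) if np.std(y) > 0 else 1.0
        theta.append(math.log(max(first_within_sd or sd_y, 1e-3 * sd_y, 1e-8)))
    return np.asarray(theta)


def _joint_marginal_se(y, trials, X, Z, block_sizes, spec, beta_hat, theta_hat,
                       n_terms, gaussian):
    """Standard errors from the joint observed information of the Laplace
    marginal log-likelihood over (beta, theta).

    The inner Newton here runs over the random-effect modes only, with the
    fixed-effect contribution held as an offset.  Variance parameters whose
    estimate collapsed to (near) zero sit on the boundary and are excluded
    from the Hessian; if the information matrix is not positive definite the
    caller falls back to the conditional standard errors.
    """
    p = X.shape[1]
    active = [i for i in range(n_terms) if math.exp(theta_hat[i]) > 5e-3]
    if gaussian:
        active.append(len(theta_hat) - 1)
    X0 = np.zeros((len(y), 0))
    warm = {"b": None}

    def negll(u):
        beta = u[:p]
        theta = theta_hat.copy()
        theta[active] = u[p:]
        theta = np.clip(theta, _THETA_MIN, _THETA_MAX)
        sigma_e = math.exp(theta[-1]) if gaussian else None
        sds = np.exp(theta[:n_terms])
        d_inv = np.concatenate(
            [np.full(m, 1.0 / (sd**2 + 1e-12)) for m, sd in zip(block_sizes, sds)]
        )
        loglik, grad_w = _family_funcs(spec.family, y, trials, sigma_e)
        offset = X @ beta
        b, Hb, pl, _ = _penalized_newton(
            y, X0, Z, d_inv,
            lambda eta: loglik(eta + offset),
            lambda eta: grad_w(eta + offset),
            coef0=warm["b"],
        )
        warm["b"] = b
        logdet_d = float(
            sum(2 * m * math.log(sd + 1e-300) for m, sd in zip(block_sizes, sds))
        )
        ll = pl - 0.5 * logdet_d - 0.5 * _logdet_posdef(Hb)
        return -ll if np.isfinite(ll) else 1e10

    u0 = np.concatenate([beta_hat, theta_hat[active]])
    m = len(u0)
    h = 1e-4 * (1.0 + np.abs(u0))
    try:
        f0 = negll(u0)
        hess = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h[i]
                ej = np.zeros(m); ej[j] = h[j]
                if i == j:
                    val = (negll(u0 + ei) - 2 * f0 + negll(u0 - ei)) / h[i] ** 2
                else:
                    val = (
                        negll(u0 + ei + ej) - negll(u0 + ei - ej)
                        - negll(u0 - ei + ej) + negll(u0 - ei - ej)
                    ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)[:p]
        if (diag <= 0).any():
            return None
        return np.sqrt(diag)
    except (np.linalg.LinAlgError, ValueError):
        return None


def _logdet_posdef(mat: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        return math.inf
    return logdet


def fit_mixed(
    data: pd.DataFrame,
    spec: ModelSpec,
    optimizer: str = "nelder-mead",
    theta0: np.ndarray | None = None,
    maxiter: int = 400,
) -> ModelFit:
    """Fit a mixed model by Laplace-approximated maximum likelihood.

    With no random terms this reduces to an ordinary maximum-likelihood GLM
    (and, for the gaussian family, to ordinary least squares).
    Non-convergence is flagged on the returned fit, never silent.
    """
    y, trials, X, names, dropped, Z, block_sizes = _build_design(data, spec)
    n, p = X.shape
    n_terms = len(spec.random_terms)
    gaussian = spec.family == "gaussian-identity"

    # starting values for log-sds (+ log residual sd for gaussian)
    if theta0 is None:
        theta0 = _moment_theta0(data, spec, y, trials)
    theta0 = np.asarray(theta0, dtype=float)

    state = {"coef": None}

    def marginal_negll(theta):
        theta = np.clip(theta, _THETA_MIN, _THETA_MAX)
        sigma_e = math.exp(theta[-1]) if gaussian else None
        sds = np.exp(theta[:n_terms])
        d_inv = (
            np.concatenate(
                [np.full(m, 1.0 / (sd**2 + 1e-12)) for m, sd in zip(block_sizes, sds)]
            )
            if n_terms
            else np.zeros(0)
        )
        loglik, grad_w = _family_funcs(spec.family, y, trials, sigma_e)
        coef, H, pl, ok = _penalized_newton(
            y, X, Z, d_inv, loglik, grad_w, coef0=state["coef"]
        )
        if not np.all(np.isfinite(coef)):
            return 1e10
        state["coef"] = coef
        state["H"] = H
        state["inner_ok"] = ok
        if n_terms:
            logdet_d = float(
                sum(2 * m * math.log(sd + 1e-300) for m, sd in zip(block_sizes, sds))
            )
            ll = pl - 0.5 * logdet_d - 0.5 * _logdet_posdef(H[p:, p:])
        else:
            ll = pl
        state["ll"] = ll
        return -ll if np.isfinite(ll) else 1e10

    if n_terms or gaussian:
        def _optimize(start):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return optimize.minimize(
                    marginal_negll,
                    start,
                    method=optimizer,
                    options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7}
                    if optimizer == "nelder-mead"
                    else {"maxiter": maxiter},
                )

        res = _optimize(theta0)
        # a solution pinned to the log-sd clamp is a stalled plateau walk;
        # retry once from a generic start and keep the better optimum
        on_boundary = np.any(np.clip(res.x, _THETA_MIN, _THETA_MAX) >= _THETA_MAX - 1e-6)
        if on_boundary or not np.isfinite(res.fun):
            alt = np.full_like(theta0, math.log(0.3))
            if gaussian:
                alt[-1] = math.log(max(float(np.std(y)), 1e-8))
            res_alt = _optimize(alt)
            if np.isfinite(res_alt.fun) and res_alt.fun < res.fun:
                res = res_alt
        theta_hat = np.clip(res.x, _THETA_MIN, _THETA_MAX)
        marginal_negll(theta_hat)  # refresh state at the optimum
        outer_ok = bool(res.success) or res.status in (1, 2)
    else:
        marginal_negll(theta0)
        theta_hat = theta0
        outer_ok = True

    coef = state["coef"]
    H = state["H"]
    ll = state["ll"]
    converged = bool(outer_ok and state.get("inner_ok", True) and np.isfinite(ll))

    # conditional (on theta_hat) covariance of the fixed effects
    try:
        cov = np.linalg.inv(H)[:p, :p]
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False

    # for mixed fits, replace the conditional standard errors with ones from
    # the observed information of the marginal likelihood over (beta, theta)
    # jointly, so interval width also reflects variance-parameter uncertainty
    if n_terms and converged:
        se_joint = _joint_marginal_se(
            y, trials, X, Z, block_sizes, spec, coef[:p], theta_hat, n_terms, gaussian
        )
        if se_joint is not None:
            se = np.where(np.isfinite(se_joint) & (se_joint >= se), se_joint, se)

    beta = coef[:p]
    zval = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pval = 2 * norm.sf(np.abs(zval))
    rows = [
        {"term": nm, "estimate": b, "se": s, "z": zv, "p": pv}
        for nm, b, s, zv, pv in zip(names, beta, se, zval, pval)
    ]
    for nm in dropped:
        rows.append({"term": nm, "estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan})
    params = pd.DataFrame(rows, columns=["term", "estimate", "se", "z", "p"])

    vc = {
        term.label: float(math.exp(theta_hat[i]))
        for i, term in enumerate(spec.random_terms)
    }
    return ModelFit(
        spec=spec,
        params=params,
        loglik=float(ll),
        converged=converged,
        vc=vc,
        n=n,
        scale=float(math.exp(theta_hat[-1])) if gaussian else None,
        degenerate=tuple(dropped),
        optimizer=optimizer,
        df_interval=float(max(min(block_sizes) - 1, 1)) if n_terms else math.inf,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio machinery


def _is_nested(null: ModelSpec, full: ModelSpec) -> bool:
    return (
        null.response == full.response
        and null.family == full.family
        and set(null.fixed_terms) <= set(full.fixed_terms)
        and set(null.random_terms) <= set(full.random_terms)
        and (set(null.fixed_terms) < set(full.fixed_terms)
             or set(null.random_terms) < set(full.random_terms)
             or null == full)
    )


def lrt(fit_null: ModelFit, fit_full: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (chi2, df, p).

    chi2 = 2 * (ll_full - ll_null); df = difference in parameter count.
    Identical models give chi2 = 0, p = 1.
    """
    if fit_null.n != fit_full.n:
        raise ValueError("fits are not on identical data (different n)")
    if not _is_nested(fit_null.spec, fit_full.spec):
        raise ValueError("specs are not nested")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    df = fit_full.n_parameters - fit_null.n_parameters
    if df <= 0:
        return max(stat, 0.0), 0, 1.0
    p = float(chi2.sf(max(stat, 0.0), df))
    return float(stat), int(df), p


def fixed_effect_lrt(
    data: pd.DataFrame, spec: ModelSpec, term: str, optimizer: str = "nelder-mead"
) -> tuple[ModelFit, ModelFit, tuple[float, int, float]]:
    """Forwards nested comparison for one fixed term: fit with and without it."""
    fit_full = fit_mixed(data, spec, optimizer=optimizer)
    fit_null = fit_mixed(data, spec.drop_fixed(term), optimizer=optimizer)
    return fit_null, fit_full, lrt(fit_null, fit_full)


# ---------------------------------------------------------------------------
# structural robustness: random-effect ablation for the tone model

ABLATION_ROWS = (
    "Full model",
    "No family intercept",
    "No family slope",
    "No area intercept",
    "No area slope",
)


def tone_model_spec(
    humidity: str = "humidity",
    response: str = "n_tones",
    family_col: str = "family_id",
    area_col: str = "area_id",
) -> ModelSpec:
    """Poisson tone model: humidity fixed effect, intercepts and humidity
    slopes for language family and geographic area."""
    return ModelSpec(
        response=response,
        family="poisson-log",
        fixed_terms=(humidity,),
        random_terms=(
            RandomTerm(family_col, "intercept"),
            RandomTerm(family_col, "slope", humidity),
            RandomTerm(area_col, "intercept"),
            RandomTerm(area_col, "slope", humidity),
        ),
    )


def ablation_sweep(data: pd.DataFrame, optimizer: str = "nelder-mead") -> pd.DataFrame:
    """Refit the tone model under five random-effect structures.

    Rows: the full model and the four single-term ablations.  Each row reports
    the humidity coefficient with its Wald z and p plus the model
    log-likelihood and a convergence flag; non-convergence is marked per row.
    """
    for col in ("family_id", "area_id", "humidity", "n_tones"):
        if col not in data.columns:
            raise ValueError(f"column {col!r} required")
    full = tone_model_spec()
    specs = {
        "Full model": full,
        "No family intercept": full.drop_random(RandomTerm("family_id", "intercept")),
        "No family slope": full.drop_random(RandomTerm("family_id", "slope", "humidity")),
        "No area intercept": full.drop_random(RandomTerm("area_id", "intercept")),
        "No area slope": full.drop_random(RandomTerm("area_id", "slope", "humidity")),
    }
    rows = []
    for label, spec in specs.items():
        try:
            fit = fit_mixed(data, spec, optimizer=optimizer)
            stats = fit.params.set_index("term").loc["humidity"]
            rows.append(
                {
                    "model": label,
                    "estimate": stats["estimate"],
                    "se": stats["se"],
                    "z": stats["z"],
                    "p": stats["p"],
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                }
            )
        except Exception as exc:  # failure is recorded, sweep continues
            rows.append(
                {"model": label, "estimate": np.nan, "se": np.nan, "z": np.nan,
                 "p": np.nan, "loglik": np.nan, "converged": False, "error": str(exc)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vowel models


@dataclass
class VowelModelResults:
    ratio_fit: ModelFit
    ratio_lrt_humidity: tuple[float, int, float]
    ratio_lrt_interaction: tuple[float, int, float]
    area_fit: ModelFit | None = None
    area_lrt_humidity: tuple[float, int, float] | None = None


def vowel_models(
    data: pd.DataFrame, hull_areas: pd.DataFrame | None = None,
    optimizer: str = "nelder-mead",
) -> VowelModelResults:
    """Fit the vowel-proportion and (optionally) vowel-area mixed models.

    The ratio model is a gaussian mixed model of the vowel share of the
    inventory on z-scored humidity, inventory size and their interaction, with
    family and area random intercepts.  LRTs are forwards comparisons:
    humidity is tested against the inventory-size-only model, the interaction
    against the main-effects model.  If a per-language hull-area table is
    given (columns language_id, hull_area), the area model regresses z-scored
    hull area on humidity and vowel count with the same random intercepts.
    Degenerate predictors (e.g. an all-equal humidity column) are reported on
    the fit, not raised.
    """
    df = data.copy()
    df["inventory_size"] = df["n_vowels"] + df["n_consonants"]
    df["vowel_ratio"] = df["n_vowels"] / df["inventory_size"]
    random = (RandomTerm("family_id", "intercept"), RandomTerm("area_id", "intercept"))

    spec2 = ModelSpec("vowel_ratio", "gaussian-identity",
                      ("inventory_size", "humidity", "humidity:inventory_size"), random)
    spec1 = spec2.drop_fixed("humidity:inventory_size")
    spec0 = spec1.drop_fixed("humidity")
    fit0 = fit_mixed(df, spec0, optimizer=optimizer)
    fit1 = fit_mixed(df, spec1, optimizer=optimizer)
    fit2 = fit_mixed(df, spec2, optimizer=optimizer)
    out = VowelModelResults(
        ratio_fit=fit2,
        ratio_lrt_humidity=lrt(fit0, fit1),
        ratio_lrt_interaction=lrt(fit1, fit2),
    )

    if hull_areas is not None:
        merged = df.merge(hull_areas[["language_id", "hull_area"]], on="language_id")
        sd = merged["hull_area"].std()
        merged["hull_area_z"] = (
            (merged["hull_area"] - merged["hull_area"].mean()) / sd if sd > 0 else 0.0
        )
        spec_a = ModelSpec("hull_area_z", "gaussian-identity",
                           ("n_vowels", "humidity"), random)
        fit_a = fit_mixed(merged, spec_a, optimizer=optimizer)
        fit_a0 = fit_mixed(merged, spec_a.drop_fixed("humidity"), optimizer=optimizer)
        out.area_fit = fit_a
        out.area_lrt_humidity = lrt(fit_a0, fit_a)
    return out


# ---------------------------------------------------------------------------
# estimation robustness


@dataclass
class StabilityReport:
    """Coefficients across optimizer/start combinations and their spread."""

    runs: pd.DataFrame  # optimizer, start, term, estimate, converged, error
    max_deviation: pd.Series  # per term: max absolute pairwise deviation

    @property
    def n_runs(self) -> int:
        return self.runs[["optimizer", "start"]].drop_duplicates().shape[0]


def estimation_sweep(
    data: pd.DataFrame,
    spec: ModelSpec,
    optimizers: tuple[str, ...] = DEFAULT_OPTIMIZERS,
    n_starts: int = 1,
    seed: int = 0,
    start_sd: float = 0.5,
) -> StabilityReport:
    """Refit one model under several optimizers and jittered start points.

    Individual failures are recorded and the sweep continues.  For specs
    without random terms the outer optimization is over the fixed effects
    directly (a convex GLM problem, so all optimizers should agree closely).
    """
    if len(optimizers) < 2:
        raise ValueError("need at least 2 optimizer configurations")
    rng = np.random.default_rng(seed)
    gaussian = spec.family == "gaussian-identity"
    n_theta = len(spec.random_terms) + (1 if gaussian else 0)
    rows = []
    for opt in optimizers:
        for start in range(n_starts):
            jitter = rng.normal(0.0, start_sd, size=n_theta) if start > 0 else None
            try:
                if spec.random_terms or gaussian:
                    theta0 = np.full(len(spec.random_terms), math.log(0.3))
                    if gaussian:
                        theta0 = np.append(theta0, 0.0)
                    if jitter is not None:
                        theta0 = theta0 + jitter
                    fit = _fit_or_glm(data, spec, opt, theta0)
                else:
                    fit = _glm_by_optimizer(data, spec, opt, rng if start else None)
                for _, row in fit.params.iterrows():
                    rows.append({"optimizer": opt, "start": start, "term": row["term"],
                                 "estimate": row["estimate"], "converged": fit.converged,
                                 "error": ""})
            except Exception as exc:
                rows.append({"optimizer": opt, "start": start, "term": "",
                             "estimate": np.nan, "converged": False, "error": str(exc)})
    runs = pd.DataFrame(rows)
    ok = runs[(runs["error"] == "") & runs["estimate"].notna()]
    max_dev = ok.groupby("term")["estimate"].agg(lambda s: float(s.max() - s.min()))
    return StabilityReport(runs=runs, max_deviation=max_dev)


def _fit_or_glm(data, spec, optimizer, theta0):
    return fit_mixed(data, spec, optimizer=optimizer, theta0=theta0)


def _glm_by_optimizer(data, spec, optimizer, rng=None):
    """Plain GLM with the outer scipy optimizer applied to beta itself."""
    y, trials, X, names, dropped, _, _ = _build_design(data, spec)
    sigma_e = float(y.std()) if spec.family == "gaussian-identity" else None
    loglik, grad_w = _family_funcs(spec.family, y, trials, sigma_e or 1.0)

    def negll(beta):
        return -loglik(X @ beta)

    beta0 = np.zeros(X.shape[1])
    if rng is not None:
        beta0 = beta0 + rng.normal(0, 0.1, size=len(beta0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(negll, beta0, method=optimizer,
                                options={"maxiter": 2000},
                                tol=1e-10)
    params = pd.DataFrame(
        {"term": names, "estimate": res.x, "se": np.nan, "z": np.nan, "p": np.nan}
    )
    return ModelFit(spec=spec, params=params, loglik=float(-res.fun),
                    converged=bool(res.success), vc={}, n=len(y), optimizer=optimizer)
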