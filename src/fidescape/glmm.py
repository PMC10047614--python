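"""Per-species mixed models of escape with a park random intercept.

Two model families are fitted for each species:

* **Model 1** — flight-initiation distance (FID) on route connectivity (RC),
  perch density (PD) and starting distance (StD);
* **Model 2** — distance fled on starting-distance-adjusted FID (FID_Adj),
  RC and PD, plus FID_Adj x RC and FID_Adj x PD interactions.

Both include the park (location) of the approach as a random intercept.
Predictors are z-scaled before fitting. Families: gaussian (identity link,
optionally on the log response) via REML linear mixed models, and poisson /
negative-binomial (log link) via a Laplace approximation to the
random-intercept likelihood, written here because no installed library fits
a negative-binomial mixed model. The negative binomial uses the quadratic
(NB2) mean-variance form Var = mu + alpha mu^2 with alpha estimated by
maximum likelihood.

Inference is Wald throughout: z statistics for the count families, t
statistics (residual degrees of freedom n - p) for gaussian fits, matching
how such tables are conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

GAUSSIAN_FAMILIES = ("gaussian", "gaussian_log")
COUNT_FAMILIES = ("poisson", "negative_binomial")

TERM_COLUMNS = {"RC": "rc_prop", "PD": "pd_per_m", "StD": "std_m",
                "FID_Adj": "fid_adj_m"}
RESPONSE_COLUMNS = {"fid": "fid_m", "distance_fled": "distance_fled_m"}

SIGMA_BOUNDARY = 1e-3        # random-effect SD below this is "at the boundary"
DISPERSION_THRESHOLD = 1.5   # Pearson chi^2 / df above this suggests NB
COOKS_FACTOR = 4.0           # influence threshold 4 / n

_Z95 = stats.norm.ppf(0.975)


class ScalingError(ValueError):
    """Raised when a predictor has zero variance and cannot be z-scaled."""


class ConvergenceError(RuntimeError):
    """Raised when a mixed-model fit cannot be completed at all."""


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one per-species model."""

    response: str                              # "fid" or "distance_fled"
    fixed_terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    family: str = "gaussian"
    random_factor: str = "park_id"
    scale_predictors: bool = True

    def term_names(self) -> list[str]:
        return list(self.fixed_terms) + [f"{a}:{b}" for a, b in self.interactions]


def model1_spec(family: str = "gaussian") -> ModelSpec:
    """FID ~ RC + PD + StD + (1 | park)."""
    return ModelSpec(response="fid", fixed_terms=("RC", "PD", "StD"), family=family)


def model2_spec(family: str = "gaussian") -> ModelSpec:
    """distance fled ~ FID_Adj * (RC + PD) + (1 | park)."""
    return ModelSpec(response="distance_fled",
                     fixed_terms=("FID_Adj", "RC", "PD"),
                     interactions=(("FID_Adj", "RC"), ("FID_Adj", "PD")),
                     family=family)


@dataclass
class FitResult:
    """Per-term Wald summaries for one fitted model."""

    table: pd.DataFrame          # index: term; estimate, se, statistic, p, ci_low, ci_high
    family: str
    statistic_kind: str          # "z" or "t"
    random_sd: float
    converged: bool
    boundary: bool = False       # random variance estimated at (or near) zero
    nb_alpha: Optional[float] = None
    n_obs: int = 0
    n_groups: int = 0
    label: str = ""
    fixed_only: Optional["FitResult"] = None  # reported alongside boundary fits
    # internals for diagnostics
    _y: Optional[np.ndarray] = None
    _X: Optional[np.ndarray] = None
    _mu: Optional[np.ndarray] = None
    _groups: Optional[np.ndarray] = None

    def params(self) -> pd.Series:
        return self.table["estimate"]


@dataclass
class DiagnosticsReport:
    max_abs_pairwise_correlation: float = 0.0
    collinear_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dispersion_ratio: Optional[float] = None
    nb_recommended: bool = False
    cooks_influential_rows: list = field(default_factory=list)
    refit_qualitative_change: bool = False
    refit: Optional[FitResult] = None


# ---------------------------------------------------------------------------
# predictor preparation


def scale_predictors(table: pd.DataFrame, terms: Sequence[str]):
    """Centre each column to mean 0 and sample SD 1 (ddof=1).

    Returns the scaled table and a {column: (mean, sd)} map for
    back-transformation of coefficients.
    """
    table = table.copy()
    scalers: dict[str, tuple[float, float]] = {}
    for col in terms:
        x = table[col].astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ScalingError(f"predictor {col!r} has zero variance")
        table[col] = (x - mu) / sd
        scalers[col] = (mu, sd)
    return table, scalers


def check_collinearity(table: pd.DataFrame, terms: Sequence[str],
                       threshold: float = 0.5) -> DiagnosticsReport:
    """All pairwise Pearson correlations among predictors; flag |r| > threshold."""
    if len(terms) < 2:
        raise ValueError("need at least two predictors")
    rep = DiagnosticsReport()
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            r = float(np.corrcoef(table[a].astype(float),
                                  table[b].astype(float))[0, 1])
            rep.max_abs_pairwise_correlation = max(
                rep.max_abs_pairwise_correlation, abs(r))
            if abs(r) > threshold:
                rep.collinear_pairs.append((a, b, r))
    return rep


def build_design(spec: ModelSpec, table: pd.DataFrame,
                 term_columns: Optional[dict[str, str]] = None):
    """Response vector, design matrix (intercept first) and group codes.

    Interactions are products of the (scaled) main-effect columns, formed
    after scaling as in the conventional scale-then-cross workflow.
    """
    cols = dict(TERM_COLUMNS)
    if term_columns:
        cols.update(term_columns)
    data = table.copy()
    y = data[RESPONSE_COLUMNS[spec.response]].astype(float).to_numpy()
    if spec.family == "gaussian_log":
        if np.any(y <= 0):
            raise ValueError("gaussian_log family requires a positive response")
        y = np.log(y)
    main_cols = [cols[t] for t in spec.fixed_terms]
    if spec.scale_predictors:
        data, scalers = scale_predictors(data, main_cols)
    else:
        scalers = {c: (0.0, 1.0) for c in main_cols}
    X = [np.ones(len(data))]
    names = ["Intercept"]
    for t in spec.fixed_terms:
        X.append(data[cols[t]].astype(float).to_numpy())
        names.append(t)
    for a, b in spec.interactions:
        X.append(data[cols[a]].astype(float).to_numpy()
                 * data[cols[b]].astype(float).to_numpy())
        names.append(f"{a}:{b}")
    X = np.column_stack(X)
    groups, levels = pd.factorize(data[spec.random_factor], sort=True)
    return y, X, names, np.asarray(groups), len(levels), scalers


# ---------------------------------------------------------------------------
# Laplace-approximated Poisson / NB random-intercept likelihood


def _count_derivs(y, mu, family, alpha):
    """(dl/deta, -d2l/deta2) per observation for log-link count families."""
    if family == "poisson":
        return y - mu, mu
    g = (y - mu) / (1.0 + alpha * mu)
    h = mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2
    return g, np.maximum(h, 1e-12)


def _count_loglik(y, eta, mu, family, alpha):
    if family == "poisson":
        return y * eta - mu - special.gammaln(y + 1)
    r = 1.0 / alpha
    return (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300))


def _inner_modes(y, eta0, gidx, ngroups, sigma2, family, alpha,
                 b0=None, tol=1e-10, max_iter=100):
    """Newton optimisation of all group intercepts at once."""
    b = np.zeros(ngroups) if b0 is None else b0.copy()
    for _ in range(max_iter):
        eta = np.clip(eta0 + b[gidx], -30, 30)
        mu = np.exp(eta)
        g_obs, h_obs = _count_derivs(y, mu, family, alpha)
        grad = np.bincount(gidx, weights=g_obs, minlength=ngroups) - b / sigma2
        hess = np.bincount(gidx, weights=h_obs, minlength=ngroups) + 1.0 / sigma2
        step = np.clip(grad / hess, -3.0, 3.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    return b, hess


def _laplace_nll(theta, y, X, gidx, ngroups, family):
    p = X.shape[1]
    beta = theta[:p]
    sigma = np.exp(theta[p])
    alpha = np.exp(theta[p + 1]) if family == "negative_binomial" else None
    eta0 = X @ beta
    b, hess = _inner_modes(y, eta0, gidx, ngroups, sigma ** 2, family, alpha)
    eta = np.clip(eta0 + b[gidx], -30, 30)
    mu = np.exp(eta)
    ll = (_count_loglik(y, eta, mu, family, alpha).sum()
          - 0.5 * np.sum(b ** 2) / sigma ** 2
          - ngroups * np.log(sigma)
          - 0.5 * np.sum(np.log(hess)))
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps ** 2)
    return H


def _fit_count_glmm(y, X, names, gidx, ngroups, family, label=""):
    # start from the fixed-effects GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta0 = np.asarray(glm.params)
    theta0 = list(beta0) + [np.log(0.3)]
    bounds = [(None, None)] * X.shape[1] + [(np.log(1e-4), np.log(20.0))]
    if family == "negative_binomial":
        theta0.append(np.log(0.5))
        bounds.append((np.log(1e-4), np.log(50.0)))
    theta0 = np.asarray(theta0)
    res = optimize.minimize(
        _laplace_nll, theta0, args=(y, X, gidx, ngroups, family),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8})
    theta = res.x
    p = X.shape[1]
    sigma = float(np.exp(theta[p]))
    alpha = float(np.exp(theta[p + 1])) if family == "negative_binomial" else None
    boundary = sigma < SIGMA_BOUNDARY
    # Wald covariance from the observed information; at a variance boundary the
    # sigma direction is flat, so drop it from the Hessian.
    free = list(range(p)) + ([p + 1] if family == "negative_binomial" else []) \
        if boundary else list(range(len(theta)))

    def nll_free(v):
        full = theta.copy()
        full[free] = v
        return _laplace_nll(full, y, X, gidx, ngroups, family)

    H = _numeric_hessian(nll_free, theta[free])
    try:
        cov = np.linalg.inv(H)
        se_full = np.full(len(theta), np.nan)
        se_full[free] = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_full = np.full(len(theta), np.nan)
    est = theta[:p]
    se = se_full[:p]
    zval = est / se
    pvals = 2 * stats.norm.sf(np.abs(zval))
    tab = pd.DataFrame({
        "estimate": est, "se": se, "statistic": zval, "p": pvals,
        "ci_low": est - _Z95 * se, "ci_high": est + _Z95 * se}, index=names)
    b, _ = _inner_modes(y, X @ est, gidx, ngroups, max(sigma, 1e-8) ** 2,
                        family, alpha)
    mu = np.exp(np.clip(X @ est + b[gidx], -30, 30))
    fit = FitResult(table=tab, family=family, statistic_kind="z",
                    random_sd=sigma, converged=bool(res.success),
                    boundary=boundary, nb_alpha=alpha,
                    n_obs=len(y), n_groups=ngroups, label=label,
                    _y=y, _X=X, _mu=mu, _groups=gidx)
    if boundary:
        fit.fixed_only = _fit_fixed_only(y, X, names, family, label)
    return fit


def _fit_fixed_only(y, X, names, family, label=""):
    """Ordinary (no random effect) fit: OLS / GLM benchmark and boundary fallback."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family in GAUSSIAN_FAMILIES:
            res = sm.OLS(y, X).fit()
            kind, dfree = "t", res.df_resid
        elif family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            kind, dfree = "z", None
        else:
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            kind, dfree = "z", None
    est = np.asarray(res.params)[:X.shape[1]]
    se = np.asarray(res.bse)[:X.shape[1]]
    stat = est / se
    if kind == "t":
        pvals = 2 * stats.t.sf(np.abs(stat), dfree)
        crit = stats.t.ppf(0.975, dfree)
    else:
        pvals = 2 * stats.norm.sf(np.abs(stat))
        crit = _Z95
    tab = pd.DataFrame({
        "estimate": est, "se": se, "statistic": stat, "p": pvals,
        "ci_low": est - crit * se, "ci_high": est + crit * se}, index=names)
    mu = res.fittedvalues if kind != "t" else X @ est
    alpha = float(res.params[-1]) if family == "negative_binomial" else None
    return FitResult(table=tab, family=family, statistic_kind=kind,
                     random_sd=0.0, converged=True, nb_alpha=alpha,
                     n_obs=len(y), n_groups=1, label=label,
                     _y=y, _X=X, _mu=np.asarray(mu), _groups=np.zeros(len(y), int))


def _fit_gaussian_glmm(y, X, names, gidx, ngroups, family, label=""):
    model = sm.MixedLM(y, X, groups=gidx)
    res = None
    # lbfgs can hit a singular profile Hessian when the random variance sits
    # at the boundary; fall through to derivative-free optimisers.
    for method in (["lbfgs"], ["powell"], ["nm"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method, maxiter=2000)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if res.converged:
            break
    if res is None:
        raise ConvergenceError("gaussian mixed model failed in every optimiser")
    p = X.shape[1]
    est = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    dfree = max(len(y) - p, 1)
    stat = est / se
    pvals = 2 * stats.t.sf(np.abs(stat), dfree)
    crit = stats.t.ppf(0.975, dfree)
    tab = pd.DataFrame({
        "estimate": est, "se": se, "statistic": stat, "p": pvals,
        "ci_low": est - crit * se, "ci_high": est + crit * se}, index=names)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    sigma = float(np.sqrt(max(re_var, 0.0)))
    boundary = sigma < SIGMA_BOUNDARY
    fitted = np.asarray(res.fittedvalues)
    fit = FitResult(table=tab, family=family, statistic_kind="t",
                    random_sd=sigma, converged=bool(res.converged),
                    boundary=boundary, n_obs=len(y), n_groups=ngroups,
                    label=label, _y=y, _X=X, _mu=fitted, _groups=gidx)
    if boundary:
        fit.fixed_only = _fit_fixed_only(y, X, names, family, label)
    return fit


def fit_glmm(spec: ModelSpec, table: pd.DataFrame, label: str = "",
             include_random: bool = True,
             term_columns: Optional[dict[str, str]] = None) -> FitResult:
    """Fit one per-species model.

    With fewer than two random-factor levels (or ``include_random=False``)
    the model degenerates to the ordinary fixed-effects fit, which is
    reported as such.
    """
    y, X, names, gidx, ngroups, _ = build_design(spec, table, term_columns)
    if not include_random or ngroups < 2:
        return _fit_fixed_only(y, X, names, spec.family, label)
    if spec.family in GAUSSIAN_FAMILIES:
        return _fit_gaussian_glmm(y, X, names, gidx, ngroups, spec.family, label)
    if spec.family in COUNT_FAMILIES:
        return _fit_count_glmm(y, X, names, gidx, ngroups, spec.family, label)
    raise ValueError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# diagnostics


def overdispersion_check(fit: FitResult,
                         threshold: float = DISPERSION_THRESHOLD) -> DiagnosticsReport:
    """Pearson chi^2 / residual df of a Poisson fit; large ratios call for NB."""
    if fit._y is None or fit._mu is None or len(fit._y) == 0:
        raise ValueError("fit carries no residuals")
    mu = np.maximum(fit._mu, 1e-12)
    pearson = np.sum((fit._y - mu) ** 2 / mu)
    df = len(fit._y) - fit._X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    rep = DiagnosticsReport(dispersion_ratio=float(pearson / df))
    rep.nb_recommended = rep.dispersion_ratio > threshold
    return rep


def _working_weights(fit: FitResult) -> tuple[np.ndarray, float]:
    """IRLS weights and dispersion for the hat-matrix influence approximation."""
    y, mu = fit._y, fit._mu
    if fit.family in GAUSSIAN_FAMILIES:
        resid = y - mu
        phi = float(np.sum(resid ** 2) / max(len(y) - fit._X.shape[1], 1))
        return np.ones(len(y)), phi
    if fit.family == "poisson":
        return np.maximum(mu, 1e-12), 1.0
    alpha = fit.nb_alpha if fit.nb_alpha else 0.0
    return np.maximum(mu / (1.0 + alpha * mu), 1e-12), 1.0


def cooks_distances(fit: FitResult) -> np.ndarray:
    """One-step Cook's distances from the conditional (given random effects) fit."""
    y, X, mu = fit._y, fit._X, fit._mu
    w, phi = _working_weights(fit)
    if fit.family in GAUSSIAN_FAMILIES:
        var = np.full(len(y), phi)
    elif fit.family == "poisson":
        var = np.maximum(mu, 1e-12)
    else:
        alpha = fit.nb_alpha if fit.nb_alpha else 0.0
        var = np.maximum(mu * (1.0 + alpha * mu), 1e-12)
    r_p = (y - mu) / np.sqrt(var)
    WX = X * np.sqrt(w)[:, None]
    try:
        XtWX_inv = np.linalg.inv(WX.T @ WX)
    except np.linalg.LinAlgError:
        XtWX_inv = np.linalg.pinv(WX.T @ WX)
    h = np.clip(np.einsum("ij,jk,ik->i", WX, XtWX_inv, WX), 0.0, 1.0 - 1e-9)
    p = X.shape[1]
    return (r_p ** 2 / p) * h / (1.0 - h) ** 2


def influence_refit(spec: ModelSpec, table: pd.DataFrame, fit: FitResult,
                    threshold: Optional[float] = None,
                    term_columns: Optional[dict[str, str]] = None) -> DiagnosticsReport:
    """Drop rows with Cook's distance above ``4 / n`` and refit.

    The report says whether any term's effect / trend / none label changes —
    the qualitative-findings leverage check.
    """
    if not fit.converged:
        raise ConvergenceError("influence analysis requires a converged fit")
    n = fit.n_obs
    thr = (COOKS_FACTOR / n) if threshold is None else threshold
    d = cooks_distances(fit)
    influential = np.where(d > thr)[0]
    rep = DiagnosticsReport(cooks_influential_rows=list(table.index[influential]))
    if len(influential) == 0:
        rep.refit = fit
        return rep
    keep = table.drop(index=rep.cooks_influential_rows)
    if len(keep) < 10:
        raise ValueError(
            f"refit refused: only {len(keep)} rows would remain after "
            f"removing {len(influential)} influential points")
    refit = fit_glmm(spec, keep, label=fit.label, term_columns=term_columns)
    before = classify_effects(fit)
    after = classify_effects(refit)
    rep.refit = refit
    rep.refit_qualitative_change = any(
        before.get(t) != after.get(t) for t in before)
    return rep


def classify_effects(fit: FitResult) -> dict[str, str]:
    """Label each non-intercept term: significant (p < 0.05), trend
    (0.05 <= p < 0.10) or none."""
    labels = {}
    for term, p in fit.table["p"].items():
        if term == "Intercept":
            continue
        if p < 0.05:
            labels[term] = "significant"
        elif p < 0.10:
            labels[term] = "trend"
        else:
            labels[term] = "none"
    return labels


def fit_with_overdispersion_fallback(spec: ModelSpec, table: pd.DataFrame,
                                     label: str = "") -> tuple[FitResult, DiagnosticsReport]:
    """Fit Poisson first and fall back to NB when overdispersed (ratio > 1.5)."""
    fit = fit_glmm(replace(spec, family="poisson"), table, label=label)
    rep = overdispersion_check(fit)
    if rep.nb_recommended:
        fit = fit_glmm(replace(spec, family="negative_binomial"), table, label=label)
    return fit, rep
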