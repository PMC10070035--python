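"""Regression engines for PheWAS with Firth-fallback logistic regression.

Quantitative phenotypes are fit by ordinary least squares.  Binary phenotypes
use maximum-likelihood logistic regression (Newton-Raphson with step-halving);
when that fit fails to converge or the estimate runs away — the signature of
(quasi-)separation, common for low-frequency variants with a strong
case-control imbalance — the engine falls back to Firth penalized logistic
regression, which maximizes

    l*(beta) = l(beta) + 1/2 * log det I(beta)

(the Jeffreys-prior penalty) via the modified score

    U*(beta) = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_i

where h_i is the leverage of the weighted design at the current iterate.
Firth estimates are finite even under complete separation and carry reduced
small-sample bias, restoring type-I error control.  The genotypic (2-df)
model is tested by a likelihood-ratio of the full model against the
covariates-only model, penalized on both sides when the fallback triggers.

All fits are complete-case: rows missing the response, the predictor or any
covariate are dropped first and the post-drop counts recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PhewasError, ValidationError
from .synth import generate_null_binary

__all__ = [
    "DesignMatrix", "FitResult", "build_design",
    "fit_linear", "fit_logistic", "fit_firth", "firth_fallback", "firth_lrt",
    "lrt_genotypic", "inverse_normal_transform", "simulate_type1",
    "BETA_CAP",
]

BETA_CAP = 15.0


@dataclass
class DesignMatrix:
    """Complete-case response + design with an implicit leading intercept."""

    y: np.ndarray                # response after complete-case drop
    X: np.ndarray                # n x (1 + k) with intercept column first
    predictor_cols: list[int]    # column indices of the predictor(s) in X
    names: list[str]
    n_used: int
    n_dropped: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None


@dataclass
class FitResult:
    beta: np.ndarray             # per predictor column
    se: np.ndarray
    p: np.ndarray
    loglik: float
    method: str                  # linear | logistic | firth | lrt_2df
    converged: bool
    n_used: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    reason: str = ""
    full_beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    df: Optional[int] = None


def build_design(y: pd.Series, predictors: pd.DataFrame,
                 covariates: Optional[pd.DataFrame] = None,
                 binary: Optional[bool] = None) -> DesignMatrix:
    """Align on the shared index and drop rows with any missing value."""
    parts = [y.rename("__y__"), predictors]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates)
    df = pd.concat(parts, axis=1, join="inner")
    n_total = len(df)
    df = df.dropna()
    yv = df["__y__"].to_numpy(dtype=float)
    pred_names = list(predictors.columns)
    cov_names = list(covariates.columns) if covariates is not None else []
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(dtype=float) for c in pred_names + cov_names])
    if binary is None:
        binary = set(np.unique(yv)).issubset({0.0, 1.0})
    n_cases = int((yv == 1).sum()) if binary else None
    n_controls = int((yv == 0).sum()) if binary else None
    return DesignMatrix(
        y=yv, X=X,
        predictor_cols=list(range(1, 1 + len(pred_names))),
        names=["intercept"] + pred_names + cov_names,
        n_used=len(df), n_dropped=n_total - len(df),
        n_cases=n_cases, n_controls=n_controls,
    )


# ---------------------------------------------------------------------------
# linear

def fit_linear(design: DesignMatrix) -> FitResult:
    """OLS via the normal equations; Wald p from the t distribution on n-p df."""
    y, X = design.y, design.X
    n, p = X.shape
    if n <= p + 1:
        return _failed(design, "linear", "insufficient observations")
    if np.linalg.matrix_rank(X) < p:
        return _failed(design, "linear", "collinear")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2 * (n - p) / n) + 1.0)
    idx = design.predictor_cols
    return FitResult(beta[idx], se[idx], pvals[idx], float(ll), "linear", True,
                     design.n_used, design.n_cases, design.n_controls,
                     full_beta=beta)


# ---------------------------------------------------------------------------
# logistic + Firth

def _logistic_ll(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: -log(1+exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _pi_w(X: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eta = np.clip(X @ beta, -30, 30)
    pi = 1.0 / (1.0 + np.exp(-eta))
    return pi, pi * (1.0 - pi)


def fit_logistic(design: DesignMatrix, max_iter: int = 25, tol: float = 1e-6,
                 beta_cap: float = BETA_CAP) -> FitResult:
    """Maximum-likelihood logistic regression (Newton-Raphson, step-halving).

    Converged iff max|delta| < tol within max_iter AND max|beta| <= beta_cap;
    a runaway estimate is the working definition of separation here.
    Wald p per predictor column.
    """
    y, X = design.y, design.X
    bad = _degenerate(design)
    if bad:
        return _failed(design, "logistic", bad)
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = _safe_logit(np.mean(y))
    ll = _logistic_ll(y, X, beta)
    converged = False
    for _ in range(max_iter):
        pi, w = _pi_w(X, beta)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - pi)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return _wald_result(design, beta, info, ll, "logistic", False, "singular information")
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            ll_new = _logistic_ll(y, X, cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        ll = _logistic_ll(y, X, beta)
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    if converged and np.max(np.abs(beta)) > beta_cap:
        converged = False
        reason = "estimate exceeded beta_cap (separation suspected)"
    elif not converged:
        reason = "max iterations reached"
    else:
        reason = ""
    pi, w = _pi_w(X, beta)
    info = (X * w[:, None]).T @ X
    return _wald_result(design, beta, info, ll, "logistic", converged, reason)


def fit_firth(design: DesignMatrix, max_iter: int = 50, tol: float = 1e-6,
              score_tol: float = 1e-6) -> FitResult:
    """Firth penalized logistic regression.

    Newton iterations on the modified score with step-halving on the
    penalized log-likelihood; estimates are finite even under separation.
    Convergence: the parameter step falls below ``tol`` or the modified score
    falls below ``score_tol`` (the optimality condition itself, which guards
    against micro-oscillation at floating precision).  Wald p on the
    penalized estimates (penalized covariance).
    """
    y, X = design.y, design.X
    bad = _degenerate(design)
    if bad:
        return _failed(design, "firth", bad)
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = _safe_logit((np.sum(y) + 0.5) / (n + 1.0))
    pll = _penalized_ll(y, X, beta)
    converged = False
    for _ in range(max_iter):
        pi, w = _pi_w(X, beta)
        Xw = X * np.sqrt(w)[:, None]
        info = Xw.T @ Xw
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return _wald_result(design, beta, np.eye(p), pll, "firth", False,
                                "singular information")
        h = np.einsum("ij,jk,ik->i", Xw, info_inv, Xw)
        score_star = X.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score_star)) < score_tol:
            converged = True          # modified score vanished: at the optimum
            break
        delta = info_inv @ score_star
        step = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + step * delta
            pll_new = _penalized_ll(y, X, cand)
            if pll_new >= pll - 1e-12:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        beta = beta + step * delta
        pll = _penalized_ll(y, X, beta)
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    pi, w = _pi_w(X, beta)
    info = (X * w[:, None]).T @ X
    reason = "" if converged else "max iterations reached"
    return _wald_result(design, beta, info, pll, "firth", converged, reason)


def _penalized_ll(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    pi, w = _pi_w(X, beta)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _logistic_ll(y, X, beta) + 0.5 * logdet


def firth_fallback(design: DesignMatrix, max_iter: int = 25, tol: float = 1e-6,
                   beta_cap: float = BETA_CAP) -> FitResult:
    """Standard logistic first; Firth when it fails.

    The fallback trigger (non-convergence or |beta| > beta_cap) is recorded in
    the returned reason string.
    """
    res = fit_logistic(design, max_iter=max_iter, tol=tol, beta_cap=beta_cap)
    if res.converged:
        return res
    trigger = res.reason or "logistic failure"
    firth = fit_firth(design, max_iter=2 * max_iter, tol=tol)
    firth.reason = f"fallback: {trigger}"
    return firth


def firth_lrt(design: DesignMatrix) -> FitResult:
    """Penalized likelihood-ratio test of the predictor columns.

    Alternative to Wald inference on Firth estimates: compares the penalized
    log-likelihood of the full model against the model without the predictor
    columns, referred to chi-square on as many df as predictor columns.
    """
    full = fit_firth(design)
    null = fit_firth(_drop_columns(design, design.predictor_cols))
    if not (full.converged and null.converged):
        return _failed(design, "firth", "nested fit failed")
    df = len(design.predictor_cols)
    lr = 2.0 * (full.loglik - null.loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), df=df))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return FitResult(full.beta, full.se, np.full(df, p), full.loglik, "firth", True,
                     design.n_used, design.n_cases, design.n_controls,
                     reason="penalized LRT", full_beta=full.full_beta, df=df)


def lrt_genotypic(design: DesignMatrix, use_firth: Optional[bool] = None) -> FitResult:
    """2-df genotypic test: likelihood ratio of full vs covariates-only model.

    Both nested fits use the same engine — penalized when the fallback
    triggers on the full model — so the likelihoods are comparable.  A
    constant indicator column degrades to a flagged 1-df test.
    """
    if len(design.predictor_cols) != 2:
        raise ValidationError("genotypic test needs exactly 2 predictor columns")
    # constant indicator -> 1-df fallback on the remaining column
    const = [j for j in design.predictor_cols
             if np.nanstd(design.X[:, j]) == 0.0]
    if const:
        keep = [j for j in design.predictor_cols if j not in const]
        if not keep:
            return _failed(design, "lrt_2df", "both indicators constant")
        sub = _drop_columns(design, const)
        res = firth_fallback(sub)
        res.method = "lrt_2df"
        res.df = 1
        res.reason = (res.reason + "; " if res.reason else "") + "constant indicator: 1-df test"
        return res

    full = firth_fallback(design)
    penalized = full.method == "firth" if use_firth is None else use_firth
    if penalized and full.method != "firth":
        full = fit_firth(design)
    null_design = _drop_columns(design, design.predictor_cols)
    null = fit_firth(null_design) if penalized else fit_logistic(null_design)
    if not (full.converged and null.converged):
        return _failed(design, "lrt_2df", "nested fit failed")
    lr = 2.0 * (full.loglik - null.loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), df=2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return FitResult(full.beta, full.se, np.array([p, p]), full.loglik, "lrt_2df", True,
                     design.n_used, design.n_cases, design.n_controls,
                     reason=("penalized" if penalized else ""), full_beta=full.full_beta, df=2)


# ---------------------------------------------------------------------------
# transforms and simulation harness

def inverse_normal_transform(y: pd.Series, offset: float = 3.0 / 8.0) -> pd.Series:
    """Rank-based inverse normal transform Phi^-1((r - c)/(n + 1 - 2c)).

    Blom offset c = 3/8 by default; ties get average ranks; missing preserved.
    """
    obs = y.dropna()
    if obs.nunique() < 2:
        raise PhewasError("inverse normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(obs.to_numpy(), method="average")
    n = len(obs)
    z = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    out = pd.Series(np.nan, index=y.index, dtype=float)
    out[obs.index] = z
    return out


def simulate_type1(n: int, case_fraction: float, maf: float, alpha: float,
                   reps: int, seed: int) -> tuple[float, float]:
    """Empirical type-I error of standard-Wald logistic vs the Firth fallback.

    Under the null (phenotype independent of genotype) each replicate is fit
    both ways; returns the fraction of replicates with p <= alpha for
    (standard Wald even when flagged, firth_fallback).  Deterministic given
    the seed.
    """
    if reps < 100:
        raise ValidationError("simulate_type1 needs reps >= 100")
    data = generate_null_binary(n, case_fraction, maf, reps, seed)
    rej_std = 0
    rej_fb = 0
    for y, g in data:
        design = build_design(pd.Series(y), pd.DataFrame({"g": g}), binary=True)
        std = fit_logistic(design)
        p_std = std.p[0] if std.p.size else np.nan  # Wald p even if flagged
        if np.isfinite(p_std) and p_std <= alpha:
            rej_std += 1
        fb = std if std.converged else firth_fallback(design)
        p_fb = fb.p[0] if fb.p.size else np.nan
        if np.isfinite(p_fb) and p_fb <= alpha:
            rej_fb += 1
    return rej_std / reps, rej_fb / reps


# ---------------------------------------------------------------------------
# helpers

def _safe_logit(p: float) -> float:
    p = min(max(p, 1e-10), 1 - 1e-10)
    return float(np.log(p / (1 - p)))


def _degenerate(design: DesignMatrix) -> str:
    classes = set(np.unique(design.y))
    if not classes.issubset({0.0, 1.0}):
        raise ValidationError("binary fit requires a 0/1 response")
    if len(classes) < 2:
        return "degenerate response"
    if design.X.shape[0] <= design.X.shape[1]:
        return "insufficient observations"
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        return "collinear"
    return ""


def _wald_result(design: DesignMatrix, beta: np.ndarray, info: np.ndarray, ll: float,
                 method: str, converged: bool, reason: str) -> FitResult:
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    idx = design.predictor_cols
    return FitResult(beta[idx], se[idx], p[idx], float(ll), method, converged,
                     design.n_used, design.n_cases, design.n_controls,
                     reason=reason, full_beta=beta)


def _drop_columns(design: DesignMatrix, cols: Sequence[int]) -> DesignMatrix:
    keep = [j for j in range(design.X.shape[1]) if j not in cols]
    remap = {old: new for new, old in enumerate(keep)}
    return DesignMatrix(
        y=design.y, X=design.X[:, keep],
        predictor_cols=[remap[j] for j in design.predictor_cols if j in remap],
        names=[design.names[j] for j in keep],
        n_used=design.n_used, n_dropped=design.n_dropped,
        n_cases=design.n_cases, n_controls=design.n_controls,
    )


def _failed(design: DesignMatrix, method: str, reason: str) -> FitResult:
    k = len(design.predictor_cols)
    nan = np.full(k, np.nan)
    return FitResult(nan, nan.copy(), nan.copy(), float("nan"), method, False,
                     design.n_used, design.n_cases, design.n_controls, reason=reason)
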