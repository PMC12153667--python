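"""Binomial mixed model for hourly activity (logit link, random intercepts).

P(active_it = 1) = logistic(x_it' beta + b_i), b_i ~ N(0, sigma_b^2).

Fitted by a Laplace approximation: for a trial sigma_b the joint penalized
log-likelihood in (beta, b) is maximized by Newton iterations on the
stacked system (the b-block carries a ridge penalty 1/sigma_b^2), and the
marginal log-likelihood is approximated as

    logL = sum_i [ l_i(b_hat_i) - b_hat_i^2/(2 sigma_b^2)
                   - 0.5 log(1 + sigma_b^2 * sum_t w_it) ]

with w = p(1-p) at the mode.  sigma_b is profiled by a bounded scalar
search.  Classification quality (accuracy at the 0.5 cut and the Matthews
correlation coefficient) is computed from *conditional* predictions, i.e.
including each individual's estimated intercept.

Model selection for the activity response runs without residual
autocorrelation (a computational concession at selection time); once a
spec is selected, ``include_ar1=True`` refits it as a marginal GEE with an
AR-1 working correlation within individual-deployment series (statsmodels),
whose coefficient table is attached to the fit's ``extras``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special

from .design import ModelSpec, build_design
from .lmm import ModelFit, _segment_ids
from .metrics import compute_mcc

__all__ = ["fit_glmm_binomial"]


def _penalized_newton(y, X, group_idx, n_groups, sigma_b2, beta0=None, b0=None,
                      max_iter=100, tol=1e-9):
    """Joint Newton maximization of the penalized binomial log-likelihood."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    Zb = b[group_idx]
    for _ in range(max_iter):
        eta = X @ beta + Zb
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        # score
        r = y - mu
        g_beta = X.T @ r
        g_b = np.bincount(group_idx, weights=r, minlength=n_groups) - b / sigma_b2
        # Hessian blocks
        H_bb = np.bincount(group_idx, weights=w, minlength=n_groups) + 1.0 / sigma_b2
        XtWX = X.T @ (X * w[:, None])
        XtWZ = np.zeros((p, n_groups))
        for j in range(p):
            XtWZ[j] = np.bincount(group_idx, weights=w * X[:, j], minlength=n_groups)
        # solve via Schur complement on the (diagonal) b-block
        Hbb_inv = 1.0 / H_bb
        S = XtWX - (XtWZ * Hbb_inv) @ XtWZ.T
        rhs = g_beta - XtWZ @ (Hbb_inv * g_b)
        try:
            d_beta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            d_beta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        d_b = Hbb_inv * (g_b - XtWZ.T @ d_beta)
        beta += d_beta
        b += d_b
        Zb = b[group_idx]
        if max(np.max(np.abs(d_beta)), np.max(np.abs(d_b))) < tol:
            break
    return beta, b


def _laplace_neg_loglik(y, X, group_idx, n_groups, sigma_b2, beta, b):
    eta = X @ beta + b[group_idx]
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll -= float(np.sum(b**2) / (2 * sigma_b2))
    sum_w = np.bincount(group_idx, weights=w, minlength=n_groups)
    ll -= 0.5 * float(np.sum(np.log1p(sigma_b2 * sum_w)))
    return -ll


def fit_glmm_binomial(data: pd.DataFrame, spec: ModelSpec,
                      include_ar1: bool = False,
                      check_standardized: bool = True) -> ModelFit:
    """Fit the hourly activity model; see module docstring for the method.

    ``data`` needs the binary response column (``spec.response``), ``hour``
    and the standardized covariates.  Raises if only one class is present;
    warns on apparent complete separation (runaway coefficients).
    """
    d = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = d[spec.response].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response has a single class; cannot fit a binomial model")
    X, names = build_design(d, spec, check_standardized=check_standardized)
    groups = d[spec.group_col].to_numpy()
    labels, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(labels)

    state = {"beta": None, "b": None}

    def objective(log_sigma_b):
        sigma_b2 = float(np.exp(2 * log_sigma_b))
        beta, b = _penalized_newton(y, X, group_idx, n_groups, sigma_b2,
                                    beta0=state["beta"], b0=state["b"])
        state["beta"], state["b"] = beta, b
        return _laplace_neg_loglik(y, X, group_idx, n_groups, sigma_b2, beta, b)

    res = optimize.minimize_scalar(objective, bounds=(-6.0, 2.0), method="bounded",
                                   options={"xatol": 1e-4})
    sigma_b = float(np.exp(res.x))
    sigma_b2 = sigma_b**2
    beta, b = _penalized_newton(y, X, group_idx, n_groups, sigma_b2,
                                beta0=state["beta"], b0=state["b"])
    neg_ll = _laplace_neg_loglik(y, X, group_idx, n_groups, sigma_b2, beta, b)
    loglik = -neg_ll

    if np.max(np.abs(beta)) > 15:
        warnings.warn("very large coefficients: possible complete separation", stacklevel=2)

    # SEs from the beta-block of the penalized-likelihood Hessian (Schur complement)
    eta = X @ beta + b[group_idx]
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H_bb = np.bincount(group_idx, weights=w, minlength=n_groups) + 1.0 / sigma_b2
    XtWX = X.T @ (X * w[:, None])
    XtWZ = np.zeros((X.shape[1], n_groups))
    for j in range(X.shape[1]):
        XtWZ[j] = np.bincount(group_idx, weights=w * X[:, j], minlength=n_groups)
    S = XtWX - (XtWZ / H_bb) @ XtWZ.T
    cov = np.linalg.pinv(S)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    # conditional classification quality at the 0.5 cut
    pred = (mu > 0.5).astype(int)
    acc = float(np.mean(pred == y))
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    mcc = compute_mcc(tp, tn, fp, fn)

    k = X.shape[1] + 1
    extras = {"accuracy": acc, "mcc": mcc, "confusion": (tp, tn, fp, fn)}

    if include_ar1:
        extras["gee_ar1"] = _gee_ar1_refit(d, spec, X, names, y)

    r = np.corrcoef(mu, y)[0, 1]
    return ModelFit(
        kind="glmm_binomial",
        spec=spec,
        design_names=names,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        vcov=cov,
        sigma_individual=sigma_b,
        sigma_resid=1.0,
        rho=float(extras.get("gee_ar1", {}).get("rho", 0.0)) if include_ar1 else 0.0,
        loglik=float(loglik),
        aic=float(2 * neg_ll + 2 * k),
        n_obs=len(d),
        n_params=k,
        r2=float(r**2) if np.isfinite(r) else 0.0,
        converged=bool(res.success),
        boundary=bool(sigma_b < 1e-3),
        blups=pd.DataFrame({"intercept": b}, index=labels),
        fitted=mu,
        extras=extras,
    )


def _gee_ar1_refit(d, spec, X, names, y) -> dict:
    """Working-correlation refit of the selected activity spec (GEE, AR-1)."""
    import statsmodels.api as sm
    from statsmodels.genmod.cov_struct import Autoregressive

    seg = _segment_ids(d, spec)
    time = np.arange(len(d))
    starts = np.r_[0, np.flatnonzero(np.diff(seg)) + 1]
    for s0, s1 in zip(starts, np.r_[starts[1:], len(d)]):
        time[s0:s1] = np.arange(s1 - s0)
    cov_struct = Autoregressive(grid=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=d[spec.group_col].to_numpy(),
                       time=time[:, None], family=sm.families.Binomial(),
                       cov_struct=cov_struct)
        fit = model.fit(maxiter=60)
    return {
        "beta": pd.Series(fit.params, index=names),
        "se": pd.Series(fit.bse, index=names),
        "rho": float(getattr(cov_struct, "dep_params", np.nan)),
    }
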