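"""Linear mixed models with AR-1 residual correlation, fitted by direct ML.

The hourly ODBA model is

    log2(ODBA_it) = x_it' beta + b_i (+ u_i * z_it) + e_it

with individual random intercepts b_i ~ N(0, sigma_b^2), optionally an
independent random slope u_i ~ N(0, sigma_s^2) on one standardized weather
covariate, and residuals e_it following an AR-1 process (coefficient rho,
stationary SD sigma_e) *within each contiguous run of hours* of an
individual-deployment series — a gap in the record resets the correlation.

Estimation maximizes the profiled marginal likelihood directly: for given
variance parameters, beta is the GLS solution; V_i^{-1} is applied through
the Woodbury identity, using the tridiagonal inverse of the AR-1 blocks, so
each likelihood evaluation is O(n * p).  ML (not REML) is used throughout
so that AIC values are comparable across fixed-effect subsets during
all-subsets selection.

AIC = -2 logLik + 2 k, with k counting fixed coefficients plus every
estimated variance/correlation parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ModelSpec, build_design

__all__ = ["ModelFit", "fit_lmm_ar1", "compare_random_slopes"]

_BOUNDARY_RATIO = 1e-3  # sigma_b/sigma_e below this is flagged as a boundary fit


@dataclass
class ModelFit:
    """Result of one mixed-model fit (Gaussian or binomial)."""

    kind: str                       # "lmm_ar1" | "glmm_binomial" | ...
    spec: ModelSpec
    design_names: list[str]
    beta: pd.Series
    se: pd.Series
    vcov: np.ndarray
    sigma_individual: float
    sigma_resid: float
    rho: float
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    r2: float
    converged: bool
    boundary: bool
    blups: pd.DataFrame             # index: individual_id; columns: intercept [, slope]
    fitted: np.ndarray
    sigma_slope: float | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{self.kind}: n={self.n_obs}, k={self.n_params}, "
            f"logLik={self.loglik:.2f}, AIC={self.aic:.2f}, R2={self.r2:.3f}",
            f"sigma_individual={self.sigma_individual:.4f}  "
            f"sigma_resid={self.sigma_resid:.4f}  rho={self.rho:.3f}"
            + (f"  sigma_slope={self.sigma_slope:.4f}" if self.sigma_slope is not None else ""),
        ]
        for name in self.design_names:
            lines.append(f"  {name:>14s}  {self.beta[name]:+9.4f}  (SE {self.se[name]:.4f})")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (term, estimate, se) for CSV export."""
        return pd.DataFrame({"term": self.design_names,
                             "estimate": self.beta.to_numpy(),
                             "se": self.se.to_numpy()})


def _segment_ids(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Label contiguous hourly runs within individual-deployment series."""
    t = pd.to_datetime(data[spec.time_col]).to_numpy()
    series = data[spec.series_col].to_numpy() if spec.series_col in data.columns \
        else data[spec.group_col].to_numpy()
    new = np.ones(len(data), dtype=bool)
    if len(data) > 1:
        gap = (t[1:] - t[:-1]) != np.timedelta64(3600, "s")
        new[1:] = (series[1:] != series[:-1]) | gap
    return np.cumsum(new) - 1


def _apply_ar1_precision(M: np.ndarray, seg_lengths: Sequence[int], rho: float,
                         sigma_e2: float) -> np.ndarray:
    """(sigma_e^2 R)^{-1} @ M for block-diagonal AR-1 correlation R."""
    out = np.empty_like(M, dtype=float)
    c = 1.0 / (sigma_e2 * (1.0 - rho**2))
    pos = 0
    for L in seg_lengths:
        blk = M[pos : pos + L]
        if L == 1:
            out[pos] = blk[0] / sigma_e2
        else:
            r = blk * (1.0 + rho**2) * c
            r[0] = blk[0] * c
            r[-1] = blk[-1] * c
            r[1:] -= rho * c * blk[:-1]
            r[:-1] -= rho * c * blk[1:]
            out[pos : pos + L] = r
        pos += L
    return out


class _MixedData:
    """Pre-grouped arrays for fast repeated likelihood evaluation."""

    def __init__(self, y, X, groups, seg_ids, Z):
        order = np.lexsort((seg_ids, groups))
        self.y = y[order]
        self.X = X[order]
        self.Z = Z[order]
        self.groups = groups[order]
        seg = seg_ids[order]
        self.order = order
        self.group_labels, starts = np.unique(self.groups, return_index=True)
        bounds = np.append(starts, len(y))
        self.slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(self.group_labels))]
        self.seg_lengths = []
        for sl in self.slices:
            _, counts = np.unique(seg[sl], return_counts=True)
            self.seg_lengths.append(counts)


def _neg2_profile_loglik(theta, md: _MixedData, est_rho: bool, q: int,
                         return_fit: bool = False):
    """Profiled -2 logLik; optionally returns (beta, cov, blups, quadform)."""
    log_sigma_e = theta[0]
    sigma_e2 = np.exp(2 * log_sigma_e)
    g_sd = np.exp(theta[1 : 1 + q])          # random-effect SDs (intercept [, slope])
    rho = np.tanh(theta[1 + q]) if est_rho else 0.0

    p = md.X.shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    parts = []  # per-group pieces for BLUPs

    for sl, seg_lengths in zip(md.slices, md.seg_lengths):
        X_i, y_i, Z_i = md.X[sl], md.y[sl], md.Z[sl]
        M = np.column_stack([X_i, y_i[:, None], Z_i])
        WM = _apply_ar1_precision(M, seg_lengths, rho, sigma_e2)
        WX, Wy, WZ = WM[:, :p], WM[:, p], WM[:, p + 1 :]
        ZtWX = Z_i.T @ WX
        ZtWy = Z_i.T @ Wy
        ZtWZ = Z_i.T @ WZ
        Gh = np.diag(g_sd)
        Mq = np.eye(q) + Gh @ ZtWZ @ Gh
        Mq_inv = np.linalg.inv(Mq)
        C = Gh @ Mq_inv @ Gh                      # q x q correction kernel
        A += X_i.T @ WX - ZtWX.T @ C @ ZtWX
        bvec += X_i.T @ Wy - ZtWX.T @ C @ ZtWy
        yVy += float(y_i @ Wy - ZtWy @ C @ ZtWy)
        L = np.asarray(seg_lengths)
        logdet += float(np.sum(L) * np.log(sigma_e2) + np.sum((L - 1)) * np.log(1 - rho**2))
        logdet += float(np.log(np.linalg.det(Mq)))
        if return_fit:
            parts.append((sl, ZtWX, ZtWy, C, Gh, WX, Wy, WZ))

    A_inv = np.linalg.inv(A)
    beta = A_inv @ bvec
    quad = yVy - float(bvec @ beta)
    n = len(md.y)
    neg2 = logdet + n * np.log(2 * np.pi) + quad
    if not return_fit:
        return neg2

    # BLUPs: b_hat_i = G Z' V^{-1} (y_i - X_i beta)
    blups = np.zeros((len(md.slices), q))
    G = np.diag(g_sd**2)
    for k, (sl, ZtWX, ZtWy, C, Gh, WX, Wy, WZ) in enumerate(parts):
        ZtW_r = ZtWy - ZtWX @ beta                # Z' W r
        ZtWZ = md.Z[sl].T @ WZ
        # Z'V^{-1} r = Z'Wr - Z'WZ C Z'Wr
        blups[k] = G @ (ZtW_r - ZtWZ @ C @ ZtW_r)
    return neg2, beta, A_inv, blups, quad


def fit_mixed_arrays(y, X, groups, names, *, seg_ids=None, ar1=False, Z=None,
                     spec: ModelSpec | None = None, kind: str = "lmm_ar1") -> ModelFit:
    """Fit a Gaussian mixed model from prepared arrays.

    The workhorse behind :func:`fit_lmm_ar1` and the nightly-scale models:
    random intercept (plus optional slope columns in ``Z``), optional AR-1
    residuals over the segments in ``seg_ids``, ML estimation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if seg_ids is None:
        _, seg_ids = np.unique(groups, return_inverse=True)
    if Z is None:
        Z = np.ones((len(y), 1))
    q = Z.shape[1]

    md = _MixedData(y, X, groups, seg_ids, Z)

    # starting values from OLS residual scale
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    s0 = max(float(np.std(resid0)), 1e-3)
    theta0 = [np.log(s0)] + [np.log(s0 / 2)] * q + ([np.arctanh(0.3)] if ar1 else [])

    res = optimize.minimize(
        _neg2_profile_loglik, np.asarray(theta0),
        args=(md, ar1, q), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
    )
    neg2, beta, cov, blups, _ = _neg2_profile_loglik(res.x, md, ar1, q, return_fit=True)

    sigma_e = float(np.exp(res.x[0]))
    sds = np.exp(res.x[1 : 1 + q])
    rho = float(np.tanh(res.x[1 + q])) if ar1 else 0.0
    p = X.shape[1]
    k = p + 1 + q + (1 if ar1 else 0)
    loglik = -0.5 * neg2
    aic = neg2 + 2 * k

    # conditional fitted values (fixed + BLUP), in original row order
    blup_map = pd.DataFrame(blups, index=md.group_labels,
                            columns=["intercept", "slope"][:q])
    fitted_sorted = md.X @ beta + (md.Z * blups[np.searchsorted(md.group_labels, md.groups)]).sum(axis=1)
    fitted = np.empty_like(fitted_sorted)
    fitted[md.order] = fitted_sorted
    r = np.corrcoef(fitted, y)[0, 1]
    r2 = float(r**2) if np.isfinite(r) else 0.0

    se = np.sqrt(np.diag(cov))
    return ModelFit(
        kind=kind,
        spec=spec,
        design_names=names,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        vcov=cov,
        sigma_individual=float(sds[0]),
        sigma_slope=float(sds[1]) if q == 2 else None,
        sigma_resid=sigma_e,
        rho=rho,
        loglik=float(loglik),
        aic=float(aic),
        n_obs=len(y),
        n_params=k,
        r2=r2,
        converged=bool(res.success),
        boundary=bool(sds[0] < _BOUNDARY_RATIO * sigma_e),
        blups=blup_map,
        fitted=fitted,
    )


def fit_lmm_ar1(data: pd.DataFrame, spec: ModelSpec,
                check_standardized: bool = True) -> ModelFit:
    """Fit the Gaussian hourly model by profiled maximum likelihood.

    ``data`` needs the response column (``spec.response``), ``hour``,
    ``hour_start``, the grouping columns, and standardized covariate
    columns for the spec's fixed terms.  Rows with missing response are
    dropped (hours of zero ODBA cannot be log-transformed and are excluded
    upstream).  Boundary estimates (sigma_individual collapsing to 0) are
    flagged on the returned fit, not raised.
    """
    d = data.dropna(subset=[spec.response]).reset_index(drop=True)
    counts = d[spec.group_col].value_counts()
    if (counts < 2).any():
        raise ValueError("every individual needs at least 2 observations")
    X, names = build_design(d, spec, check_standardized=check_standardized)
    y = d[spec.response].to_numpy(dtype=float)
    groups = d[spec.group_col].to_numpy()
    seg_ids = _segment_ids(d, spec)

    if spec.random_slope is not None:
        if spec.random_slope not in d.columns:
            raise KeyError(f"random slope covariate {spec.random_slope!r} not in data")
        Z = np.column_stack([np.ones(len(d)), d[spec.random_slope].to_numpy(dtype=float)])
    else:
        Z = None
    return fit_mixed_arrays(y, X, groups, names, seg_ids=seg_ids, ar1=spec.ar1,
                            Z=Z, spec=spec, kind="lmm_ar1")


def compare_random_slopes(data: pd.DataFrame, base_spec: ModelSpec,
                          slope_covariates: Sequence[str]) -> pd.DataFrame:
    """Random-slope vs random-intercept comparison, one covariate at a time.

    For each candidate weather covariate the base model is refitted with an
    added independent random slope; the table reports the slope SD, the AIC
    difference (negative favours the slope model), and a likelihood-ratio
    p-value using the 50:50 chi-square(0)/chi-square(1) boundary mixture.
    A LRT statistic of 0 (identical fits) yields p = 1 by convention.
    """
    base = fit_lmm_ar1(data, base_spec)
    rows = []
    for cov_name in slope_covariates:
        try:
            fit_s = fit_lmm_ar1(data, replace(base_spec, random_slope=cov_name))
        except Exception as err:  # non-convergent slope models reported, not fatal
            rows.append({"covariate": cov_name, "converged": False, "error": str(err)})
            continue
        lrt = 2.0 * (fit_s.loglik - base.loglik)
        p = 1.0 if lrt <= 0 else 0.5 * stats.chi2.sf(lrt, df=1)
        rows.append({
            "covariate": cov_name,
            "sigma_slope": fit_s.sigma_slope,
            "aic_base": base.aic,
            "aic_slope": fit_s.aic,
            "delta_aic": fit_s.aic - base.aic,
            "lrt": lrt,
            "p_boundary": p,
            "converged": fit_s.converged,
        })
    return pd.DataFrame(rows)
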