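"""Daily ODBA prediction and condition-dependent plasticity surfaces.

Hourly model predictions are on the log2 scale; total daily ODBA under a
covariate scenario is the sum over the 24 scenario hours of 2^prediction.
Uncertainty comes from the delta method on the fixed-effect linear
predictor: with eta_h = x_h' beta, T = sum_h 2^eta_h has gradient
dT/dbeta = ln 2 * sum_h 2^eta_h x_h, and Var(T) ~= g' Cov(beta) g.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import build_design, term_parents
from .lmm import ModelFit

__all__ = ["predict_daily_odba", "plasticity_surface"]

LN2 = np.log(2.0)


def predict_daily_odba(fit: ModelFit, scenario: pd.DataFrame) -> dict:
    """Total daily ODBA (natural scale) under a 24-hour covariate scenario.

    ``scenario`` must hold 24 rows (one per hour, ``hour`` column in
    [0, 24)) with every standardized covariate the model uses.  Returns the
    point estimate, its delta-method SE, and the per-hour predictions.
    """
    mains: set[str] = set()
    for term in fit.spec.fixed_terms:
        parents = term_parents(term)
        mains.update(parents if parents else (term,))
    missing = sorted(m for m in mains if m not in scenario.columns)
    if missing:
        raise KeyError(f"scenario missing covariates: {missing}")
    if len(scenario) != 24:
        raise ValueError("scenario must supply exactly 24 hourly rows")

    X, _ = build_design(scenario, fit.spec, check_standardized=False)
    eta = X @ fit.beta.to_numpy()
    per_hour = 2.0**eta
    total = float(per_hour.sum())
    g = LN2 * (X * per_hour[:, None]).sum(axis=0)
    var = float(g @ fit.vcov @ g)
    return {"total": total, "se": float(np.sqrt(max(var, 0.0))),
            "per_hour": pd.Series(per_hour, index=scenario["hour"].to_numpy())}


def _base_scenario(fit: ModelFit) -> pd.DataFrame:
    """All standardized covariates at 0 (their mean), hours 0..23."""
    cols: dict = {"hour": np.arange(24, dtype=float)}
    for term in fit.spec.fixed_terms:
        for main in ([term] if "_x_" not in term else term.split("_x_")):
            base = main[:-1] if main.endswith("2") else main
            cols.setdefault(base, np.zeros(24))
    return pd.DataFrame(cols)


def plasticity_surface(
    fit: ModelFit,
    bci_values: dict[str, float],
    temp_grid: np.ndarray,
    observed_temp_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Predicted daily ODBA across temperature at named BCI levels.

    ``bci_values`` maps labels (e.g. quantile names) to standardized BCI
    values; ``temp_grid`` is on the standardized temperature scale.  The
    fit must contain the BCI-by-temperature interaction.  Values outside
    ``observed_temp_range`` are flagged ``extrapolated``.  Returns a tidy
    frame: bci_label, temp, daily_odba, se, lo95, hi95, extrapolated.
    """
    if "BCI_x_Temp" not in fit.spec.fixed_terms:
        raise ValueError("fit does not contain the BCI_x_Temp interaction")
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    if observed_temp_range is not None:
        lo, hi = observed_temp_range
        outside = (temp_grid < lo) | (temp_grid > hi)
        if outside.any():
            warnings.warn("temperature grid extends beyond the observed range", stacklevel=2)
    rows = []
    for label, bci in bci_values.items():
        for t in temp_grid:
            scen = _base_scenario(fit)
            scen["Temp"] = t
            scen["BCI"] = bci
            pred = predict_daily_odba(fit, scen)
            extrap = (observed_temp_range is not None
                      and not (observed_temp_range[0] <= t <= observed_temp_range[1]))
            rows.append({"bci_label": label, "bci": bci, "temp": t,
                         "daily_odba": pred["total"], "se": pred["se"],
                         "lo95": pred["total"] - 1.96 * pred["se"],
                         "hi95": pred["total"] + 1.96 * pred["se"],
                         "extrapolated": extrap})
    return pd.DataFrame(rows)
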