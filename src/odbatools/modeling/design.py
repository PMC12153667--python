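"""Model specifications and design matrices for the hourly models.

A :class:`ModelSpec` names the response (log2 hourly ODBA or binary hourly
activity), the fixed weather/trait terms, the circadian spline dimension,
and the random/correlation structure.  Fixed terms use a small naming
convention:

- main effects: ``Temp``, ``Rain``, ``Wind``, ``RH``, ``SoilM``,
  ``SoilT10``, ``SoilT30``, ``age``, ``BCI``, ``sexM``
- quadratics: ``Temp2`` = standardized Temp squared (requires ``Temp``)
- interactions: ``BCI_x_Temp`` etc. (require both parents)

Continuous weather covariates must arrive standardized (mean 0, SD 1);
quadratic and interaction columns are formed *after* standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..weather import WEATHER_COVARIATES
from .splines import cyclic_spline_basis

__all__ = ["ModelSpec", "term_parents", "expand_terms", "build_design"]

_QUADRATIC_BASES = {f"{c}2": c for c in [*WEATHER_COVARIATES, "age", "BCI"]}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one hourly mixed model."""

    response: str = "log2_odba"          # or "active"
    fixed_terms: tuple[str, ...] = ()
    n_knots: int = 10
    group_col: str = "individual_id"
    series_col: str = "series_id"        # individual-deployment for AR-1
    time_col: str = "hour_start"
    hour_col: str = "hour"
    ar1: bool = True
    random_slope: str | None = None      # one weather covariate, or None

    def __post_init__(self):
        for t in self.fixed_terms:
            for parent in term_parents(t):
                if parent not in self.fixed_terms:
                    raise ValueError(f"term {t!r} requires its parent {parent!r} (marginality)")

    def with_terms(self, terms: Sequence[str]) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(terms))


def term_parents(term: str) -> tuple[str, ...]:
    """Marginality parents of a term (empty for main effects)."""
    if term in _QUADRATIC_BASES:
        return (_QUADRATIC_BASES[term],)
    if "_x_" in term:
        return tuple(term.split("_x_"))
    return ()


def expand_terms(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Columns for each named term, deriving quadratics and interactions."""
    out = {}
    for t in terms:
        if t in data.columns:
            out[t] = data[t].to_numpy(dtype=float)
        elif t in _QUADRATIC_BASES:
            out[t] = data[_QUADRATIC_BASES[t]].to_numpy(dtype=float) ** 2
        elif "_x_" in t:
            a, b = t.split("_x_")
            out[t] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown term {t!r}")
    return pd.DataFrame(out, index=data.index)


def _check_standardized(data: pd.DataFrame, terms: Sequence[str]) -> None:
    for t in terms:
        if t in WEATHER_COVARIATES and t in data.columns:
            x = data[t].to_numpy(dtype=float)
            if abs(float(np.mean(x))) > 0.01 or abs(float(np.std(x, ddof=1)) - 1.0) > 0.01:
                raise ValueError(f"covariate {t!r} is not standardized (mean 0, SD 1)")


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 check_standardized: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + cyclic spline of hour + fixed terms.

    The cardinal spline columns sum to one, so the first spline column is
    dropped against the intercept.  ``check_standardized=False`` skips the
    mean-0/SD-1 guard — needed when building rows for prediction scenarios
    or cross-validation folds, which inherit the full data's standardization
    but are not themselves exactly standardized.  Returns the matrix and
    column names.
    """
    if check_standardized:
        _check_standardized(data, spec.fixed_terms)
    hour = data[spec.hour_col].to_numpy(dtype=float)
    if np.any((hour < 0) | (hour >= 24)):
        raise ValueError("hour must lie in [0, 24)")
    spline = cyclic_spline_basis(hour, n_knots=spec.n_knots)[:, 1:]
    cols = [np.ones(len(data)), *spline.T]
    names = ["Intercept"] + [f"s(hour).{k}" for k in range(1, spec.n_knots)]
    if spec.fixed_terms:
        tm = expand_terms(data, spec.fixed_terms)
        for t in spec.fixed_terms:
            cols.append(tm[t].to_numpy())
            names.append(t)
    return np.column_stack(cols), names
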