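"""Night-scale models: repeatability (ICC), cross-season consistency, disparity.

Hour-scale models are dominated by the circadian cycle, which swamps
between-individual variance; stable "activity types" are therefore
quantified at the night scale.  Total nightly ODBA (log2) and nightly
active minutes are modeled as linear mixed models with individual random
intercepts and the night-averaged weather covariates selected by the
hourly models; the intra-class correlation

    ICC = var(individual) / (var(individual) + var(residual))

is the repeatability of the nightly response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import ModelFit, fit_mixed_arrays
from .metrics import VarianceDecomposition

__all__ = ["fit_nightly_model", "intercept_consistency", "nightly_disparity"]


def fit_nightly_model(
    nights: pd.DataFrame,
    covariates: list[str],
    response: str = "log2_total_odba",
    min_individuals: int = 5,
    min_nights: int = 3,
) -> tuple[ModelFit, VarianceDecomposition]:
    """Random-intercept model of a nightly response; returns fit and ICC.

    ``nights`` holds one row per individual-night with the response column
    and night-averaged covariates (already standardized).  Responses:
    ``log2_total_odba`` (computed from ``total_odba`` if absent) or
    ``active_minutes``.  Replication below the configured floor
    (``min_individuals`` individuals with ``min_nights`` nights each)
    raises.
    """
    d = nights.copy()
    if response == "log2_total_odba" and response not in d.columns:
        if (d["total_odba"] <= 0).any():
            d = d[d["total_odba"] > 0]
        d[response] = np.log2(d["total_odba"])
    d = d.dropna(subset=[response, *covariates]).reset_index(drop=True)

    counts = d.groupby("individual_id").size()
    if (counts >= min_nights).sum() < min_individuals:
        raise ValueError(
            f"insufficient replication: need >= {min_individuals} individuals "
            f"with >= {min_nights} nights; have {(counts >= min_nights).sum()}")

    X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in covariates])
    names = ["Intercept", *covariates]
    fit = fit_mixed_arrays(
        d[response].to_numpy(dtype=float), X, d["individual_id"].to_numpy(),
        names, ar1=False, kind="nightly_lmm",
    )
    decomp = VarianceDecomposition(var_individual=fit.sigma_individual**2,
                                   var_residual=fit.sigma_resid**2)
    return fit, decomp


def intercept_consistency(seasonal_fits: dict[str, ModelFit]) -> dict:
    """Do individuals keep their rank across seasons?

    Collects each season's conditional-mode (BLUP) individual intercepts
    and computes the Spearman rank correlation for every season pair over
    the individuals shared between them.  Pairs with fewer than 3 shared
    individuals are reported without a correlation.
    """
    tables = {
        season: fit.blups["intercept"].rename(season)
        for season, fit in seasonal_fits.items()
    }
    table = pd.concat(tables.values(), axis=1)
    seasons = list(tables)
    rows = []
    for i, a in enumerate(seasons):
        for b in seasons[i + 1 :]:
            shared = table[[a, b]].dropna()
            if len(shared) < 3:
                rows.append({"season_a": a, "season_b": b, "n_shared": len(shared),
                             "spearman_r": np.nan, "p": np.nan,
                             "note": "fewer than 3 shared individuals"})
                continue
            r, p = stats.spearmanr(shared[a], shared[b])
            rows.append({"season_a": a, "season_b": b, "n_shared": len(shared),
                         "spearman_r": float(r), "p": float(p), "note": ""})
    return {"intercepts": table, "correlations": pd.DataFrame(rows)}


def nightly_disparity(nights: pd.DataFrame) -> dict:
    """Max/min total-ODBA ratio across individuals, night by night.

    Only nights with >= 2 individuals contribute; nights whose minimum
    total ODBA is zero are excluded (flagged in the output).  Returns the
    per-night table plus the mean and range of the ratio.
    """
    rows = []
    excluded = 0
    for night_id, grp in nights.groupby("night_id"):
        if len(grp) < 2:
            continue
        lo, hi = float(grp["total_odba"].min()), float(grp["total_odba"].max())
        if lo <= 0:
            excluded += 1
            continue
        rows.append({"night_id": night_id, "n_individuals": len(grp),
                     "ratio": hi / lo})
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("no nights with >= 2 individuals and positive ODBA")
    return {
        "per_night": table,
        "mean_ratio": float(table["ratio"].mean()),
        "range": (float(table["ratio"].min()), float(table["ratio"].max())),
        "n_excluded_zero": excluded,
    }
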