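"""Repeatability and classification metrics: ICC, MCC, grouped k-fold CV."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["VarianceDecomposition", "compute_icc", "compute_mcc", "k_fold_cv"]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Individual vs residual variance and the implied repeatability."""

    var_individual: float
    var_residual: float

    @property
    def icc(self) -> float:
        return compute_icc(self.var_individual, self.var_residual)


def compute_icc(var_individual: float, var_residual: float) -> float:
    """Intra-class correlation: var_individual / (var_individual + var_residual).

    The fraction of (covariate-adjusted) variance attributable to stable
    between-individual differences; 0 = no repeatability, 1 = perfectly
    repeatable individuals.
    """
    if var_individual < 0 or var_residual < 0:
        raise ValueError("variance components must be non-negative")
    total = var_individual + var_residual
    if total == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return float(var_individual / total)


def compute_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), in [-1, 1]:
    +1 for perfect classification, -1 for perfect negative correlation,
    0 when any marginal is empty (degenerate denominator; returned as 0).
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = (float(c) for c in counts)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def _confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, tn, fp, fn


def k_fold_cv(data: pd.DataFrame, spec, k: int = 5, seed: int = 0,
              group_cols: tuple[str, ...] = ("individual_id", "night_id")) -> dict:
    """Held-out classification quality of the activity model.

    Folds are formed over individual-night groups (all hours of one
    individual's night stay together), so no night leaks between training
    and test.  Each fold's model is fitted on the remaining groups; held-out
    hours are predicted conditionally — an individual's random intercept
    from the training fit is reused, since individuals (but never nights)
    appear in both partitions.  Returns mean/SD of accuracy and MCC across
    folds plus the per-fold table.
    """
    from .glmm import fit_glmm_binomial

    if k < 2:
        raise ValueError("k must be >= 2")
    present = [c for c in group_cols if c in data.columns]
    key = data[present].astype(str).agg("|".join, axis=1)
    groups = key.unique()
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)
    folds = np.array_split(groups, k)

    rows = []
    for i, held in enumerate(folds):
        test_mask = key.isin(held).to_numpy()
        train = data[~test_mask]
        test = data[test_mask]
        yte = test[spec.response].to_numpy(dtype=float)
        if train[spec.response].nunique() < 2:
            raise ValueError(f"fold {i}: a class is absent from the training data")
        fit = fit_glmm_binomial(train, spec, check_standardized=False)
        from .design import build_design
        Xte, _ = build_design(test, spec, check_standardized=False)
        b = fit.blups["intercept"].reindex(test[spec.group_col]).fillna(0.0).to_numpy()
        p = special.expit(Xte @ fit.beta.to_numpy() + b)
        pred = (p > 0.5).astype(int)
        acc = float(np.mean(pred == yte))
        mcc = compute_mcc(*_confusion(yte, pred))
        rows.append({"fold": i, "n_test": len(test), "accuracy": acc, "mcc": mcc})
    table = pd.DataFrame(rows)
    return {
        "accuracy_mean": float(table["accuracy"].mean()),
        "accuracy_sd": float(table["accuracy"].std(ddof=1)),
        "mcc_mean": float(table["mcc"].mean()),
        "mcc_sd": float(table["mcc"].std(ddof=1)),
        "folds": table,
    }
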