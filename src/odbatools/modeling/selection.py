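"""All-subsets AIC model selection with marginality and collinearity rules.

Candidate models are every subset of the full spec's fixed terms that
(a) respects marginality — a quadratic only with its linear term, an
interaction only with both main effects — and (b) never contains both
members of a forbidden (collinear) covariate pair.  Candidates are ranked
by AIC; ties break toward fewer parameters.  The summary also reports, for
each term, the percentage of candidate models within 2 AIC units of the
best that contain it — a term-importance measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import pandas as pd

from .design import ModelSpec, term_parents

__all__ = ["SelectionTable", "enumerate_subsets", "all_subsets_selection"]

MAX_TERMS = 12  # 2^12 candidate subsets before filtering


@dataclass
class SelectionTable:
    """Ranked candidates and ΔAIC<2 term-importance percentages."""

    table: pd.DataFrame            # one row per candidate: aic, delta_aic, term flags
    term_importance: pd.Series     # % of ΔAIC<2 models containing each term
    best_spec: ModelSpec
    best_fit: object


def _valid(subset: frozenset, forbidden_pairs: Sequence[tuple[str, str]]) -> bool:
    for t in subset:
        if any(p not in subset for p in term_parents(t)):
            return False
    for a, b in forbidden_pairs:
        if a in subset and b in subset:
            return False
    return True


def enumerate_subsets(terms: Sequence[str],
                      forbidden_pairs: Sequence[tuple[str, str]] = ()) -> list[tuple[str, ...]]:
    """All marginality-respecting, collinearity-free subsets (incl. empty)."""
    terms = list(terms)
    if len(terms) > MAX_TERMS:
        raise ValueError(
            f"{len(terms)} terms would enumerate 2^{len(terms)} subsets; "
            f"limit is {MAX_TERMS}")
    out = []
    for r in range(len(terms) + 1):
        for combo in combinations(terms, r):
            if _valid(frozenset(combo), forbidden_pairs):
                out.append(combo)
    return out


def all_subsets_selection(
    data: pd.DataFrame,
    full_spec: ModelSpec,
    forbidden_pairs: Sequence[tuple[str, str]] = (),
    fitter: Callable | None = None,
) -> SelectionTable:
    """Fit every admissible subset of the full spec and rank by AIC.

    ``fitter`` defaults to the Gaussian AR-1 mixed model for a
    ``log2_odba`` response and the binomial mixed model (without AR-1,
    added later to the selected spec only) for an ``active`` response.
    """
    if fitter is None:
        if full_spec.response == "active":
            from .glmm import fit_glmm_binomial
            fitter = fit_glmm_binomial
        else:
            from .lmm import fit_lmm_ar1
            fitter = fit_lmm_ar1

    subsets = enumerate_subsets(full_spec.fixed_terms, forbidden_pairs)
    rows = []
    fits = []
    for combo in subsets:
        spec = full_spec.with_terms(combo)
        fit = fitter(data, spec)
        fits.append(fit)
        row = {"terms": combo, "n_terms": len(combo), "k": fit.n_params,
               "loglik": fit.loglik, "aic": fit.aic}
        for t in full_spec.fixed_terms:
            row[f"has_{t}"] = t in combo
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(["aic", "k"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]

    near = table[table["delta_aic"] < 2.0]
    importance = pd.Series(
        {t: 100.0 * near[f"has_{t}"].mean() for t in full_spec.fixed_terms},
        name="pct_delta_aic_lt2",
    )
    best_idx = table.index[0]
    best_combo = table.loc[best_idx, "terms"]
    order = [i for i, c in enumerate(subsets) if c == best_combo][0]
    return SelectionTable(
        table=table,
        term_importance=importance,
        best_spec=full_spec.with_terms(best_combo),
        best_fit=fits[order],
    )
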