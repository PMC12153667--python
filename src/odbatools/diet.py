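"""Fecal diet composition: chaetae counts and occurrence frequencies.

Earthworm chaetae (bristles that survive digestion) counted in washed scat
effluent index earthworm consumption: each sample scores the mean count
over 10 one-cm^2 squares of a Petri dish.  Diet items identified in each
sample are tabulated monthly as frequency of occurrence (FO = samples
containing the item / samples) and relative frequency of occurrence
(RFO = item occurrences / total occurrences of all items).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FecalSample", "chaetae_index", "monthly_fo_rfo"]

N_SQUARES = 10


@dataclass(frozen=True)
class FecalSample:
    sample_id: str
    collection_date: pd.Timestamp
    chaetae_counts: tuple[int, ...]
    items: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.chaetae_counts) != N_SQUARES:
            raise ValueError(f"expected {N_SQUARES} square counts, "
                             f"got {len(self.chaetae_counts)}")
        if any(c < 0 for c in self.chaetae_counts):
            raise ValueError("chaetae counts must be non-negative")


def chaetae_index(sample: FecalSample) -> float:
    """Mean chaetae count over the sample's 10 squares."""
    return float(np.mean(sample.chaetae_counts))


def monthly_fo_rfo(samples: Iterable[FecalSample]) -> pd.DataFrame:
    """FO and RFO of each diet item, by calendar month.

    One row per (month, item): ``fo`` = samples containing the item divided
    by the month's samples; ``rfo`` = the item's occurrences divided by all
    item occurrences that month (summing to 1 whenever any item occurs).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    rows = []
    by_month: dict[str, list[FecalSample]] = {}
    for s in samples:
        key = pd.Timestamp(s.collection_date).strftime("%Y-%m")
        by_month.setdefault(key, []).append(s)
    for month, group in sorted(by_month.items()):
        n = len(group)
        occurrences: dict[str, int] = {}
        for s in group:
            for item in s.items:
                occurrences[item] = occurrences.get(item, 0) + 1
        total = sum(occurrences.values())
        for item, count in sorted(occurrences.items()):
            rows.append({
                "month": month, "item": item, "n_samples": n,
                "occurrences": count,
                "fo": count / n,
                "rfo": count / total if total else np.nan,
            })
    return pd.DataFrame(rows)
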