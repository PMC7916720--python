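"""Abundant / intermediate / rare OTU partitioning and conditionally rare taxa.

Global categories use each OTU's share of the grand read total: abundant above
1% and rare below 0.01% by default, with strict inequalities so a value
exactly at a threshold is intermediate. Per-sample categories use the OTU's
relative abundance within each sample (abundant > 1%, rare < 0.01%, absent at
0). Conditionally rare-to-abundant taxa (CRAT) are OTUs rare in at least one
sample (< 0.1% by default) yet abundant (> 1%) in at least one other.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTable, ValidationError

__all__ = [
    "PartitionResult",
    "classify_global",
    "classify_per_sample",
    "detect_crat",
    "category_share",
    "partition_all",
]

GLOBAL_CATEGORIES = ("abundant", "intermediate", "rare")
LOCAL_CATEGORIES = ("abundant", "intermediate", "rare", "absent")


@dataclass
class PartitionResult:
    """Outcome of the abundance partition.

    Attributes
    ----------
    global_category : pandas.Series
        OTU -> {abundant, intermediate, rare}.
    local_category : pandas.DataFrame or None
        samples x OTUs -> {abundant, intermediate, rare, absent}.
    crat_otus : set of str
        Conditionally rare-to-abundant OTUs.
    summary : pandas.DataFrame
        Per global category: OTU count, % of OTUs, % of reads.
    """

    global_category: pd.Series | None = None
    local_category: pd.DataFrame | None = None
    crat_otus: set[str] = field(default_factory=set)
    summary: pd.DataFrame | None = None


def category_share(n_category: int, n_total: int) -> float:
    """A category's size as a percentage of the total (0-100 scale)."""
    if n_total <= 0:
        raise ValidationError("total must be positive")
    return 100.0 * n_category / n_total


def classify_global(table: CommunityTable,
                    abundant_threshold: float = 0.01,
                    rare_threshold: float = 0.0001) -> PartitionResult:
    """Partition OTUs by share of the grand read total (strict inequalities)."""
    if not (0 < rare_threshold < abundant_threshold <= 1):
        raise ValidationError("need 0 < rare_threshold < abundant_threshold <= 1")
    totals = table.otu_sums()
    grand = int(totals.sum())
    if grand == 0:
        raise ValidationError("table grand total is zero")
    frac = totals / grand
    cat = pd.Series("intermediate", index=frac.index, name="category")
    cat[frac > abundant_threshold] = "abundant"
    cat[frac < rare_threshold] = "rare"
    rows = []
    for c in GLOBAL_CATEGORIES:
        mask = cat == c
        rows.append((c, int(mask.sum()),
                     category_share(int(mask.sum()), len(cat)),
                     category_share(int(totals[mask].sum()), grand)))
    summary = pd.DataFrame(
        rows, columns=["category", "n_otus", "pct_otus", "pct_reads"]
    ).set_index("category")
    return PartitionResult(global_category=cat, summary=summary)


def classify_per_sample(table: CommunityTable,
                        abundant_threshold: float = 0.01,
                        rare_threshold: float = 0.0001) -> PartitionResult:
    """Per-sample categories from within-sample relative abundance.

    p > abundant -> abundant; rare <= p <= abundant -> intermediate;
    0 < p < rare -> rare; p = 0 -> absent.
    """
    rel = table.relative_abundance()
    p = rel.to_numpy()
    out = np.full(p.shape, "intermediate", dtype=object)
    out[p > abundant_threshold] = "abundant"
    out[p < rare_threshold] = "rare"
    out[p == 0] = "absent"
    local = pd.DataFrame(out, index=rel.index, columns=rel.columns)
    return PartitionResult(local_category=local)


def detect_crat(table: CommunityTable,
                local_rare_threshold: float = 0.001,
                local_abundant_threshold: float = 0.01,
                include_absent: bool = False) -> set[str]:
    """Conditionally rare-to-abundant taxa.

    An OTU qualifies when some sample has 0 < p < ``local_rare_threshold``
    (or p = 0 too, if ``include_absent``) and some other sample has
    p > ``local_abundant_threshold``. Invariant to sample order.
    """
    rel = table.relative_abundance().to_numpy()
    if include_absent:
        rare_somewhere = (rel < local_rare_threshold).any(axis=0)
    else:
        rare_somewhere = ((rel > 0) & (rel < local_rare_threshold)).any(axis=0)
    abundant_somewhere = (rel > local_abundant_threshold).any(axis=0)
    mask = rare_somewhere & abundant_somewhere
    return {o for o, m in zip(table.otu_ids, mask) if m}


def partition_all(table: CommunityTable,
                  abundant_threshold: float = 0.01,
                  rare_threshold: float = 0.0001,
                  per_sample_abundant_threshold: float = 0.01,
                  per_sample_rare_threshold: float = 0.001,
                  include_absent_crat: bool = False) -> PartitionResult:
    """Global + per-sample partition and CRAT detection in one result."""
    g = classify_global(table, abundant_threshold, rare_threshold)
    loc = classify_per_sample(table, per_sample_abundant_threshold,
                              rare_threshold)
    crat = detect_crat(table, per_sample_rare_threshold,
                       per_sample_abundant_threshold, include_absent_crat)
    return PartitionResult(global_category=g.global_category,
                           local_category=loc.local_category,
                           crat_otus=crat, summary=g.summary)
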