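"""Rarefaction and alpha diversity.

Rarefaction subsamples each sample's reads *without replacement* (a
multivariate hypergeometric draw per sample), so a sample whose total equals
the target depth is returned unchanged and every rarefied row sums exactly to
the depth. Alpha diversity reports OTU richness, Shannon entropy (natural log
by default), and Good's coverage 1 - singletons/reads.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityTable, ValidationError, derive_seed

__all__ = [
    "rarefy",
    "alpha_diversity",
    "mean_alpha_over_resamples",
    "rarefaction_curve",
]


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    richness: float
    shannon: float
    goods_coverage: float
    n_resamples: int
    depth: int


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    if depth <= 0:
        raise ValidationError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    short = list(sums.index[sums < depth])
    if short:
        raise ValidationError(
            f"samples with fewer than {depth} reads: {short}")
    rng = np.random.default_rng(seed)
    counts = table.matrix()
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CommunityTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns),
        table.taxonomy)


def _alpha_row(row: np.ndarray, base: str) -> tuple[float, float, float]:
    total = row.sum()
    if total == 0:
        raise ValidationError("empty sample in alpha diversity")
    present = row[row > 0]
    richness = float(present.size)
    p = present / total
    shannon = float(-(p * np.log(p)).sum())
    if base == "2":
        shannon /= np.log(2)
    goods = 1.0 - float((present == 1).sum()) / float(total)
    return richness, shannon, goods


def alpha_diversity(table: CommunityTable, base: str = "e") -> pd.DataFrame:
    """Richness, Shannon, and Good's coverage per sample.

    Shannon is in nats (``base='e'``, default) or bits (``base='2'``).
    Returns a DataFrame indexed by sample with columns ``richness``,
    ``shannon``, ``goods_coverage``, ``depth``, ``n_resamples`` (=1 here).
    """
    rows = []
    for sid, row in zip(table.sample_ids, table.matrix()):
        richness, shannon, goods = _alpha_row(row, base)
        rows.append((sid, richness, shannon, goods, 1, int(row.sum())))
    return pd.DataFrame(
        rows, columns=["sample_id", "richness", "shannon", "goods_coverage",
                       "n_resamples", "depth"]).set_index("sample_id")


def mean_alpha_over_resamples(table: CommunityTable, depth: int,
                              n_resamples: int, seed: int,
                              base: str = "e") -> pd.DataFrame:
    """Average alpha indices over repeated independent rarefactions.

    Each replicate uses a child seed derived from ``(seed, replicate)``, so a
    single-replicate call reproduces ``alpha_diversity(rarefy(...))`` with the
    same derived seed.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    acc: pd.DataFrame | None = None
    for r in range(n_resamples):
        rep = alpha_diversity(
            rarefy(table, depth, derive_seed(seed, "rarefy", r)), base)
        cols = rep[["richness", "shannon", "goods_coverage"]]
        acc = cols if acc is None else acc + cols
    mean = acc / n_resamples
    mean["n_resamples"] = n_resamples
    mean["depth"] = depth
    return mean


def rarefaction_curve(table: CommunityTable, depths: list[int],
                      n_resamples: int, seed: int) -> pd.DataFrame:
    """Mean (+/- sd) OTU richness at increasing read depths, per sample.

    Depths must be strictly increasing. Within one replicate the draws are
    nested (a random permutation of the sample's reads, truncated at each
    depth), so each replicate's richness is non-decreasing in depth, and so is
    the mean.
    """
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValidationError("depths must be strictly increasing")
    if not depths or depths[0] < 1:
        raise ValidationError("depths must be >= 1")
    sums = table.sample_sums()
    short = list(sums.index[sums < max(depths)])
    if short:
        raise ValidationError(
            f"samples with fewer than {max(depths)} reads: {short}")
    records = []
    for sid, row in zip(table.sample_ids, table.matrix()):
        reads = np.repeat(np.arange(row.size), row)
        rich = np.empty((n_resamples, len(depths)))
        for r in range(n_resamples):
            rng = np.random.default_rng(derive_seed(seed, "curve", sid, r))
            perm = rng.permutation(reads)
            seen = np.zeros(row.size, dtype=bool)
            prev = 0
            for k, d in enumerate(depths):
                seen[perm[prev:d]] = True
                prev = d
                rich[r, k] = seen.sum()
        for k, d in enumerate(depths):
            records.append((sid, d, rich[:, k].mean(),
                            rich[:, k].std(ddof=1) if n_resamples > 1 else 0.0))
    return pd.DataFrame(records,
                        columns=["sample_id", "depth", "mean_richness", "sd"])
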