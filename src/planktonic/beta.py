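"""Bray-Curtis beta diversity and the permutation statistics built on it.

Implements the quantitative surface of a PRIMER-style workflow: Bray-Curtis
dissimilarity on relative abundances, principal coordinate analysis (classical
scaling), UPGMA agglomeration with deterministic lexicographic tie-breaking,
the rank-based ANOSIM permutation test, and SIMPER decomposition of
between-group dissimilarity into per-OTU contributions.

Permutation p-values use the (1 + count) / (1 + n_perm) estimator throughout,
so p is never zero and has resolution 1/(n_perm + 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .io import CommunityTable, ValidationError

__all__ = [
    "bray_curtis",
    "pcoa",
    "upgma",
    "anosim",
    "simper",
    "AnosimResult",
    "SimperResult",
    "OrdinationResult",
    "UPGMAResult",
]


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(table: CommunityTable, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / sum_i (x_i + y_i). With
    ``normalize`` (default) rows are converted to relative abundance first,
    which makes the result scale-invariant per sample.
    """
    rows = (table.relative_abundance() if normalize else table.counts).to_numpy(
        dtype=float)
    condensed = pdist(rows, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), table.sample_ids)


# ---------------------------------------------------------------------------
# PCoA (classical scaling)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA output: coordinates on axes with positive eigenvalues.

    ``eigenvalues`` holds the full spectrum in decreasing order (negative
    eigenvalues are reported but excluded from the proportion-explained
    denominator and carry no coordinates).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J. Axes are
    ordered by decreasing eigenvalue; signs are fixed deterministically (the
    largest-magnitude loading of each axis is positive).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12 * abs(eigvals[0]), 1e-12)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    prop = eigvals[pos] / eigvals[pos].sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class UPGMAResult:
    """Group-average dendrogram over samples.

    ``merges`` records each agglomeration (representative labels of the two
    clusters and the average distance at which they merge; heights are
    non-decreasing). ``newick`` encodes the ultrametric tree, with each leaf
    at depth (last merge height)/2.
    """

    merges: pd.DataFrame
    newick: str
    _coph: DistanceMatrix | None = field(default=None, repr=False)

    def cophenetic(self) -> DistanceMatrix:
        """Merge height joining each pair of samples (an ultrametric)."""
        return self._coph


def upgma(dm: DistanceMatrix) -> UPGMAResult:
    """Average-linkage agglomeration; ties broken by lexicographic label pair."""
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 samples")
    # cluster state: representative label (lexicographic min of members)
    members: dict[str, list[str]] = {i: [i] for i in ids}
    newick_of: dict[str, str] = {i: i for i in ids}
    depth: dict[str, float] = {i: 0.0 for i in ids}
    dist: dict[tuple[str, str], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            key = tuple(sorted((ids[a], ids[b])))
            dist[key] = float(dm.data[a, b])
    coph = pd.DataFrame(0.0, index=ids, columns=ids)
    merges = []
    active = sorted(ids)
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        for x in members[a]:
            for y in members[b]:
                coph.loc[x, y] = coph.loc[y, x] = h
        na, nb = len(members[a]), len(members[b])
        rep = min(a, b)
        other_rep = max(a, b)
        merges.append((a, b, h, na + nb))
        # average-linkage update against every other active cluster
        new_dist: dict[tuple[str, str], float] = {}
        for key, d in dist.items():
            if a in key and b in key:
                continue
            if a in key or b in key:
                o = key[0] if key[1] in (a, b) else key[1]
                da = dist[tuple(sorted((a, o)))]
                db = dist[tuple(sorted((b, o)))]
                new_dist[tuple(sorted((rep, o)))] = (na * da + nb * db) / (na + nb)
            else:
                new_dist[key] = d
        dist = new_dist
        la = newick_of[a] + f":{h / 2 - depth[a]:.10g}"
        lb = newick_of[b] + f":{h / 2 - depth[b]:.10g}"
        newick_of[rep] = f"({la},{lb})"
        depth[rep] = h / 2
        members[rep] = members[a] + members[b]
        if other_rep != rep:
            for d_ in (members, newick_of, depth):
                d_.pop(other_rep, None)
        active = [x for x in active if x not in (a, b)] + [rep]
        active.sort()
    root = active[0]
    merge_df = pd.DataFrame(merges, columns=["cluster_a", "cluster_b",
                                             "height", "size"])
    return UPGMAResult(merges=merge_df, newick=newick_of[root] + ";",
                       _coph=DistanceMatrix(coph.to_numpy(), ids))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    comparison: str  # "global" or "A vs B"
    r_statistic: float
    p_value: float
    n_permutations: int
    n_samples: int


def _group_codes(dm: DistanceMatrix, groups: Mapping[str, str] | pd.Series,
                 ) -> np.ndarray:
    labels = [groups[sid] for sid in dm.ids]
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _anosim_stat_and_p(dm: DistanceMatrix, codes: np.ndarray, n_perm: int,
                       rng: np.random.Generator) -> tuple[float, float]:
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])  # average-rank ties over all pairs
    m = ranks.size
    total = ranks.sum()

    def r_of(within: np.ndarray) -> float:
        w = within.sum()
        if w == 0 or w == m:
            return np.nan
        rw = ranks[within].sum() / w
        rb = (total - ranks[within].sum()) / (m - w)
        return (rb - rw) / (m / 2)

    obs = r_of(codes[iu[0]] == codes[iu[1]])
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    cp = codes[perms]  # (n_perm, n)
    within_all = cp[:, iu[0]] == cp[:, iu[1]]  # (n_perm, m)
    w = within_all.sum(axis=1).astype(float)  # constant across perms
    sw = within_all @ ranks
    r_perm = ((total - sw) / (m - w) - sw / w) / (m / 2)
    p = (1 + int((r_perm >= obs - 1e-12).sum())) / (1 + n_perm)
    return float(obs), float(p)


def anosim(dm: DistanceMatrix, groups: Mapping[str, str] | pd.Series,
           n_perm: int = 999, seed: int = 0,
           pairwise: bool = True) -> list[AnosimResult]:
    """Global and pairwise analysis of similarities.

    The statistic r = (mean between-group rank - mean within-group rank)
    divided by M/2, with ranks over all M = n(n-1)/2 pairwise distances (ties
    averaged). p is one-sided under label permutation. The first result is
    the global test, followed by one result per unordered group pair.
    """
    groups = dict(groups) if not isinstance(groups, Mapping) else groups
    labels = np.array([groups[sid] for sid in dm.ids])
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    rng = np.random.default_rng(seed)
    results = []
    codes = _group_codes(dm, groups)
    r, p = _anosim_stat_and_p(dm, codes, n_perm, rng)
    results.append(AnosimResult("global", r, p, n_perm, len(dm.ids)))
    if pairwise:
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                ga, gb = uniq[i], uniq[j]
                for g in (ga, gb):
                    if (labels == g).sum() < 2:
                        raise ValidationError(
                            f"group {g!r} has fewer than 2 samples")
                keep = [sid for sid, lab in zip(dm.ids, labels)
                        if lab in (ga, gb)]
                sub = dm.filter(keep)
                r, p = _anosim_stat_and_p(sub, _group_codes(sub, groups),
                                          n_perm, rng)
                results.append(AnosimResult(f"{ga} vs {gb}", r, p, n_perm,
                                            len(keep)))
    return results


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResult:
    """Per-OTU contributions to mean between-group Bray-Curtis dissimilarity.

    Contributions are non-negative and sum to ``mean_dissimilarity`` exactly
    (the decomposition identity). ``contributions`` is sorted descending
    (ties by OTU id); ``selected`` is the shortest prefix whose cumulative
    share reaches the cumulative cut.
    """

    comparison: str
    mean_dissimilarity: float
    contributions: pd.DataFrame
    selected: list[str]
    cumulative_cut: float


def _pair_contributions(x: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray,
                        ) -> np.ndarray:
    """Sum over between-group sample pairs of per-OTU |x_j - x_k| / sum(x_j + x_k)."""
    acc = np.zeros(x.shape[1])
    n_pairs = 0
    for j in rows_a:
        for k in rows_b:
            denom = x[j].sum() + x[k].sum()
            acc += np.abs(x[j] - x[k]) / denom
            n_pairs += 1
    return acc, n_pairs


def _rank_and_select(mean_contrib: pd.Series, cut: float, comparison: str,
                     ) -> SimperResult:
    total = mean_contrib.sum()
    order = sorted(mean_contrib.index,
                   key=lambda o: (-mean_contrib[o], o))
    contrib = mean_contrib.loc[order]
    pct = 100 * contrib / total if total > 0 else contrib * 0.0
    cum = pct.cumsum()
    df = pd.DataFrame({"contribution": contrib, "pct": pct,
                       "cumulative_pct": cum})
    df.index.name = "otu_id"
    selected = list(df.index[: int(np.searchsorted(
        cum.to_numpy(), 100 * cut - 1e-12) + 1)]) if total > 0 else []
    return SimperResult(comparison, float(total), df, selected, cut)


def simper(table: CommunityTable, groups: Mapping[str, str] | pd.Series,
           cumulative_cut: float = 0.50,
           normalize: bool = True) -> list[SimperResult]:
    """SIMPER decomposition per group pair plus a pooled multi-group ranking.

    For each between-group sample pair (j, k) OTU i contributes
    |x_ij - x_ik| / sum_m (x_mj + x_mk); contributions are averaged over the
    pairs, so they sum to the mean between-group Bray-Curtis dissimilarity.
    The pooled result averages over every between-group pair of all group
    combinations. Returned list: one result per unordered group pair, then
    the pooled ranking (comparison = "pooled").
    """
    groups = dict(groups) if not isinstance(groups, Mapping) else groups
    labels = np.array([groups[sid] for sid in table.sample_ids])
    uniq = sorted(set(labels))
    for g in uniq:
        if (labels == g).sum() < 1:
            raise ValidationError(f"group {g!r} is empty")
    x = (table.relative_abundance() if normalize else table.counts).to_numpy(
        dtype=float)
    results = []
    pooled_acc = np.zeros(x.shape[1])
    pooled_pairs = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows_a = np.flatnonzero(labels == uniq[i])
            rows_b = np.flatnonzero(labels == uniq[j])
            acc, n_pairs = _pair_contributions(x, rows_a, rows_b)
            pooled_acc += acc
            pooled_pairs += n_pairs
            mean_contrib = pd.Series(acc / n_pairs, index=table.otu_ids)
            results.append(_rank_and_select(
                mean_contrib, cumulative_cut, f"{uniq[i]} vs {uniq[j]}"))
    if pooled_pairs:
        mean_contrib = pd.Series(pooled_acc / pooled_pairs,
                                 index=table.otu_ids)
        results.append(_rank_and_select(mean_contrib, cumulative_cut, "pooled"))
    return results
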