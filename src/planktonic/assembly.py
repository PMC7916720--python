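"""Null-model quantification of community assembly processes.

For every pair of samples the pipeline computes the abundance-weighted beta
mean-nearest-taxon distance (betaMNTD), standardizes it against a null
distribution obtained by shuffling taxon labels across the pooled phylogeny
(999 randomizations by default) to give the beta nearest-taxon index (betaNTI),
and computes the Bray-Curtis-based Raup-Crick metric (RCbray) against a null
that preserves each sample's observed richness and read depth while drawing
membership with probability proportional to occupancy and allocating reads
proportionally to regional relative abundance.

Pairs are then classified: betaNTI > +2 -> heterogeneous (variable) selection;
betaNTI < -2 -> homogeneous selection; otherwise RCbray > +0.95 -> dispersal
limitation, RCbray < -0.95 -> homogenizing dispersal, and anything else ->
drift (not dominated by any single process).

One shared sequence of null label permutations is reused across all pairs for
a given seed, which makes runs reproducible and keeps the null-model cost
O(n_null) in tree work rather than O(n_null x pairs).
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import CommunityTable, ValidationError, derive_seed, logger

__all__ = [
    "PROCESSES",
    "cophenetic_matrix",
    "beta_mntd",
    "beta_mntd_matrix",
    "bnti",
    "rc_bray",
    "rc_scale",
    "classify_processes",
    "summarize_processes",
    "assembly_analysis",
    "AssemblySummary",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",  # alias: "undominated"
)


@dataclass
class AssemblySummary:
    percent: dict[str, float]  # process -> % of pairs (sums to 100)
    n_pairs: int
    n_null: int
    bnti_cut: float
    rc_cut: float


# ---------------------------------------------------------------------------
# phylogenetic distances
# ---------------------------------------------------------------------------

def cophenetic_matrix(tree: dendropy.Tree,
                      otu_subset: list[str] | None = None) -> DistanceMatrix:
    """Patristic (cophenetic) distances between tips, optionally subset.

    The distance between two tips is the sum of branch lengths on the path
    connecting them. OTUs requested but absent from the tree are an error
    (all missing tips are listed).
    """
    tip_labels = [t.label for t in tree.taxon_namespace]
    if otu_subset is None:
        otu_subset = tip_labels
    missing = sorted(set(otu_subset) - set(tip_labels))
    if missing:
        raise ValidationError(f"OTUs absent from the tree: {missing}")
    taxa = {t.label: t for t in tree.taxon_namespace}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(otu_subset)
    d = np.zeros((n, n))
    for i in range(n):
        ti = taxa[otu_subset[i]]
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(ti, taxa[otu_subset[j]])
    return DistanceMatrix(d, list(otu_subset))


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------

def beta_mntd(fj: np.ndarray, fk: np.ndarray, coph: np.ndarray) -> float:
    """Abundance-weighted beta mean-nearest-taxon distance for one pair.

    betaMNTD = 1/2 [ sum_{i in j} f_ij min_{i' in k} d(i, i')
                   + sum_{i in k} f_ik min_{i' in j} d(i, i') ],
    minima over taxa present (f > 0) in the other sample. A taxon present in
    both samples has nearest-neighbor distance 0, so identical supports give
    betaMNTD = 0. Symmetric in (j, k).
    """
    fj = np.asarray(fj, dtype=float)
    fk = np.asarray(fk, dtype=float)
    sj, sk = np.flatnonzero(fj), np.flatnonzero(fk)
    if sj.size == 0 or sk.size == 0:
        raise ValidationError("betaMNTD of an empty community")
    sub = coph[np.ix_(sj, sk)]
    return 0.5 * (float(fj[sj] @ sub.min(axis=1))
                  + float(fk[sk] @ sub.min(axis=0)))


def beta_mntd_matrix(weights: np.ndarray, coph: np.ndarray) -> np.ndarray:
    """betaMNTD between all sample pairs, vectorized.

    ``weights`` is samples x taxa (rows sum to 1, zeros for absent taxa)
    aligned with the cophenetic matrix. Uses the nearest-taxon-distance
    matrix M[k, i] = min_{i' present in k} d(i, i'), giving
    betaMNTD = 1/2 (W M^T + (W M^T)^T).
    """
    s, t = weights.shape
    m = np.empty((s, t))
    for k in range(s):
        sup = np.flatnonzero(weights[k])
        if sup.size == 0:
            raise ValidationError("betaMNTD of an empty community")
        m[k] = coph[:, sup].min(axis=1)
    a = weights @ m.T
    return 0.5 * (a + a.T)


def bnti(table: CommunityTable, coph: DistanceMatrix, n_null: int = 999,
         seed: int = 0, weighted: bool = True) -> pd.DataFrame:
    """Observed betaMNTD and its null z-score (betaNTI) for every pair.

    The null shuffles taxon labels across the whole cophenetic matrix (one
    shared sequence of ``n_null`` permutations for all pairs); betaNTI =
    (observed - null mean) / null sd. Degenerate nulls with zero spread
    (e.g. a star phylogeny) leave betaNTI as NaN with a logged warning.
    Returns one row per unordered pair with columns sample_j, sample_k,
    bmntd_obs, null_mean, null_sd, bnti.
    """
    missing = sorted(set(table.otu_ids) - set(coph.ids))
    if missing:
        raise ValidationError(f"OTUs absent from the tree: {missing}")
    rel = table.relative_abundance()[list(coph.ids)].to_numpy()
    if not weighted:
        pres = (rel > 0).astype(float)
        rel = pres / pres.sum(axis=1, keepdims=True)
    d = coph.data
    t = d.shape[0]
    obs = beta_mntd_matrix(rel, d)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(t)
        nb = beta_mntd_matrix(rel, d[np.ix_(perm, perm)])
        acc += nb
        acc2 += nb * nb
    mean = acc / n_null
    var = (acc2 - n_null * mean ** 2) / max(n_null - 1, 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    iu = np.triu_indices(len(table.sample_ids), k=1)
    sd_v = sd[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_v > 1e-12, (obs[iu] - mean[iu]) / sd_v, np.nan)
    if np.isnan(z).any():
        logger.warning("betaNTI undefined for %d pair(s): null spread is zero",
                       int(np.isnan(z).sum()))
    sids = table.sample_ids
    return pd.DataFrame({
        "sample_j": [sids[i] for i in iu[0]],
        "sample_k": [sids[j] for j in iu[1]],
        "bmntd_obs": obs[iu],
        "null_mean": mean[iu],
        "null_sd": sd_v,
        "bnti": z,
    })


# ---------------------------------------------------------------------------
# RCbray
# ---------------------------------------------------------------------------

def rc_scale(n_less: np.ndarray | float, n_equal: np.ndarray | float,
             n_null: int) -> np.ndarray | float:
    """Rescale Raup-Crick tail counts to [-1, 1].

    RC_raw = (#{null < obs} + 1/2 #{null = obs}) / n_null, rc = 2(RC_raw - 1/2);
    ties get half weight so rc has expectation 0 under exchangeability.
    """
    return 2.0 * ((np.asarray(n_less) + 0.5 * np.asarray(n_equal)) / n_null
                  - 0.5)


def rc_bray(table: CommunityTable, n_null: int = 999, seed: int = 0,
            tol: float = 1e-10) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick metric for every sample pair.

    Null assemblies preserve each sample's observed OTU richness and read
    total: membership is drawn without replacement with probability
    proportional to occupancy (number of samples containing the OTU), each
    drawn OTU receives one read, and the remaining reads are allocated
    multinomially with probability proportional to the OTU's share of the
    regional pool. RC_raw = (#{null < obs} + 1/2 #{null = obs}) / n_null is
    rescaled to [-1, 1] as rc = 2 (RC_raw - 1/2).
    """
    counts = table.matrix()
    s, t = counts.shape
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = counts.sum(axis=0).astype(float)
    pool_p = pool / pool.sum()
    occ_p = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if np.any(richness > t):
        raise ValidationError("sample richness exceeds pool size")
    rel = counts / totals[:, None]
    obs = pdist(rel, metric="braycurtis")
    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs)
    equal = np.zeros_like(obs)
    null_counts = np.zeros((s, t))
    for _ in range(n_null):
        null_counts[:] = 0.0
        for i in range(s):
            chosen = rng.choice(t, size=int(richness[i]), replace=False,
                                p=occ_p)
            extra = int(totals[i] - richness[i])
            alloc = np.ones(chosen.size)
            if extra > 0:
                pa = pool_p[chosen]
                alloc += rng.multinomial(extra, pa / pa.sum())
            null_counts[i, chosen] = alloc
        null_bc = pdist(null_counts / totals[:, None], metric="braycurtis")
        less += null_bc < obs - tol
        equal += np.abs(null_bc - obs) <= tol
    rc = rc_scale(less, equal, n_null)
    iu = np.triu_indices(s, k=1)
    sids = table.sample_ids
    return pd.DataFrame({
        "sample_j": [sids[i] for i in iu[0]],
        "sample_k": [sids[j] for j in iu[1]],
        "bray_curtis_obs": obs,
        "rc_bray": rc,
    })


# ---------------------------------------------------------------------------
# classification and summary
# ---------------------------------------------------------------------------

def classify_processes(bnti_values: np.ndarray, rc_values: np.ndarray,
                       bnti_cut: float = 2.0, rc_cut: float = 0.95,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Assign an assembly process to each pair from (betaNTI, RCbray).

    betaNTI > +cut -> heterogeneous_selection; betaNTI < -cut ->
    homogeneous_selection; else rc > +rc_cut -> dispersal_limitation,
    rc < -rc_cut -> homogenizing_dispersal, otherwise drift. Pairs with
    undefined (NaN) betaNTI fall through to the RCbray rules and are flagged.
    Returns (labels, flagged) arrays.
    """
    b = np.asarray(bnti_values, dtype=float)
    r = np.asarray(rc_values, dtype=float)
    labels = np.full(b.shape, "drift", dtype=object)
    labels[r > rc_cut] = "dispersal_limitation"
    labels[r < -rc_cut] = "homogenizing_dispersal"
    defined = ~np.isnan(b)
    labels[defined & (b > bnti_cut)] = "heterogeneous_selection"
    labels[defined & (b < -bnti_cut)] = "homogeneous_selection"
    return labels, ~defined


def summarize_processes(results: pd.DataFrame, n_null: int = 999,
                        bnti_cut: float = 2.0,
                        rc_cut: float = 0.95) -> AssemblySummary:
    """Percentage of sample pairs assigned to each process (sums to 100)."""
    if len(results) == 0:
        raise ValidationError("no classified pairs to summarize")
    counts = results["process"].value_counts()
    pct = {p: 100.0 * counts.get(p, 0) / len(results) for p in PROCESSES}
    return AssemblySummary(pct, len(results), n_null, bnti_cut, rc_cut)


def assembly_analysis(table: CommunityTable, tree: dendropy.Tree,
                      n_null: int = 999, seed: int = 0,
                      bnti_cut: float = 2.0, rc_cut: float = 0.95,
                      weighted: bool = True,
                      ) -> tuple[pd.DataFrame, AssemblySummary]:
    """Full per-pair assembly analysis: betaNTI + RCbray + classification.

    Returns the per-pair DataFrame (sample_j, sample_k, bmntd_obs, null_mean,
    null_sd, bnti, rc_bray, process, bnti_undefined) and the process summary.
    """
    table = table.drop_empty_otus()
    coph = cophenetic_matrix(tree, table.otu_ids)
    b = bnti(table, coph, n_null, derive_seed(seed, "bnti"), weighted)
    r = rc_bray(table, n_null, derive_seed(seed, "rcbray"))
    merged = b.merge(r[["sample_j", "sample_k", "rc_bray"]],
                     on=["sample_j", "sample_k"], validate="one_to_one")
    labels, flagged = classify_processes(
        merged["bnti"].to_numpy(), merged["rc_bray"].to_numpy(),
        bnti_cut, rc_cut)
    merged["process"] = labels
    merged["bnti_undefined"] = flagged
    return merged, summarize_processes(merged, n_null, bnti_cut, rc_cut)
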