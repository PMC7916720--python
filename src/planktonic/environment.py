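"""Environmental and geographic drivers of community dissimilarity.

Builds great-circle (haversine) and per-variable environmental distance
matrices, runs simple and partial Mantel permutation tests between them and
community Bray-Curtis matrices, and screens alpha-diversity indices or taxon
abundances against environmental variables with Spearman rank correlation.

Mantel r defaults to Pearson correlation of the off-diagonal distance vectors
(the historical form of the test); p-values are one-sided for positive
association and use the (1 + count)/(1 + n_perm) estimator, permuting rows and
columns of the second matrix jointly. Pairs of samples with missing values for
the variable under test are dropped and the retained n is reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .io import ValidationError, derive_seed

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_matrix",
    "variable_distance",
    "mantel",
    "partial_mantel",
    "mantel_screen",
    "spearman_screen",
    "MantelResult",
    "CorrelationScreenResult",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    retained_n: int  # samples used after dropping missing values
    variable: str | None = None
    subset: str | None = None
    controlled_for: str | None = None
    flagged: bool = False  # degenerate (zero variance / perfect collinearity)


@dataclass
class CorrelationScreenResult:
    """Spearman rho and p for each (series, variable) cell, with an
    alpha-level significance mask; cells with fewer than ``min_n`` paired
    observations or a constant series are NaN."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


# ---------------------------------------------------------------------------
# distance construction
# ---------------------------------------------------------------------------

def haversine_matrix(meta: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) between samples on a 6371-km sphere."""
    for col in ("latitude", "longitude"):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks a {col!r} column")
        missing = meta.index[meta[col].isna()]
        if len(missing):
            raise ValidationError(f"missing {col} for sample {missing[0]!r}")
    lat = np.radians(meta["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [str(i) for i in meta.index])


def variable_distance(meta: pd.DataFrame, variable: str,
                      transform: str = "none") -> DistanceMatrix:
    """Pairwise |v_j - v_k| for one metadata variable.

    ``transform`` is ``none``, ``zscore``, or ``log10`` (requires positive
    values). Samples with missing values are dropped; fewer than 3 remaining
    samples is an error.
    """
    if variable not in meta.columns:
        raise ValidationError(f"unknown metadata variable {variable!r}")
    series = pd.to_numeric(meta[variable], errors="coerce").dropna()
    if len(series) < 3:
        raise ValidationError(
            f"variable {variable!r} has fewer than 3 non-missing samples")
    v = series.to_numpy(dtype=float)
    if transform == "zscore":
        sd = v.std(ddof=1)
        v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
    elif transform == "log10":
        if np.any(v <= 0):
            raise ValidationError(
                f"log10 transform needs positive values for {variable!r}")
        v = np.log10(v)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(d, [str(i) for i in series.index])


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

def _aligned_square(dx: DistanceMatrix, dy: DistanceMatrix,
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if set(dx.ids) != set(dy.ids):
        raise ValidationError("Mantel matrices have mismatching labels")
    ids = list(dx.ids)
    return dx.data, dy.filter(ids).data, ids


def _rank_square(sq: np.ndarray, iu: tuple[np.ndarray, np.ndarray],
                 ) -> np.ndarray:
    """Rank-transform the off-diagonal entries in place of values.

    Relabeling samples permutes the off-diagonal multiset, so permuting the
    rank matrix is equivalent to re-ranking the permuted matrix.
    """
    r = np.zeros_like(sq)
    ranks = stats.rankdata(sq[iu])
    r[iu] = ranks
    r.T[iu] = ranks
    return r


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        return np.nan
    return float((a * b).sum() / (na * nb))


def mantel(dx: DistanceMatrix, dy: DistanceMatrix, method: str = "pearson",
           n_perm: int = 1000, seed: int = 0,
           alternative: str = "greater") -> MantelResult:
    """Simple Mantel test between two distance matrices.

    r correlates the upper-triangle vectors (Pearson by default, Spearman via
    rank transform); the null permutes rows+columns of ``dy`` jointly. A
    zero-variance distance vector yields a flagged result with r = NaN, p = 1.
    """
    x_sq, y_sq, ids = _aligned_square(dx, dy)
    n = len(ids)
    if n < 4:
        raise ValidationError("Mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    if method == "spearman":
        x_sq, y_sq = _rank_square(x_sq, iu), _rank_square(y_sq, iu)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    xv, yv = x_sq[iu], y_sq[iu]
    obs = _pearson(xv, yv)
    if np.isnan(obs):
        return MantelResult(np.nan, 1.0, n_perm, method, n, flagged=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_ = rng.permutation(n)
        r_p = _pearson(xv, y_sq[np.ix_(p_, p_)][iu])
        stat, ref = (abs(r_p), abs(obs)) if alternative == "two-sided" \
            else (r_p, obs)
        if stat >= ref - 1e-12:
            count += 1
    return MantelResult(obs, (1 + count) / (1 + n_perm), n_perm, method, n)


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    det = (1 - rxz ** 2) * (1 - ryz ** 2)
    if det <= 0:
        return np.nan
    return (rxy - rxz * ryz) / np.sqrt(det)


def partial_mantel(dx: DistanceMatrix, dy: DistanceMatrix, dz: DistanceMatrix,
                   method: str = "pearson", n_perm: int = 1000,
                   seed: int = 0,
                   alternative: str = "greater") -> MantelResult:
    """Partial Mantel test of dx ~ dy controlling for dz.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)); the permutation
    null permutes ``dy`` and recomputes the full partial statistic each time.
    Perfect collinearity with the control (|r| = 1) yields a flagged result.
    """
    x_sq, y_sq, ids = _aligned_square(dx, dy)
    _, z_sq, _ = _aligned_square(dx, dz)
    n = len(ids)
    if n < 4:
        raise ValidationError("partial Mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    if method == "spearman":
        x_sq = _rank_square(x_sq, iu)
        y_sq = _rank_square(y_sq, iu)
        z_sq = _rank_square(z_sq, iu)
    xv, zv = x_sq[iu], z_sq[iu]
    z_constant = np.ptp(zv) == 0  # all-zero/constant control: partial == simple
    rxy = _pearson(xv, y_sq[iu])
    rxz = 0.0 if z_constant else _pearson(xv, zv)
    ryz = 0.0 if z_constant else _pearson(y_sq[iu], zv)
    if any(np.isnan(v) for v in (rxy, rxz, ryz)) \
            or abs(rxz) >= 1 - 1e-12 or abs(ryz) >= 1 - 1e-12:
        return MantelResult(np.nan, 1.0, n_perm, method, n, flagged=True)
    obs = _partial_r(rxy, rxz, ryz)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_ = rng.permutation(n)
        yp = y_sq[np.ix_(p_, p_)][iu]
        r_p = _partial_r(_pearson(xv, yp), rxz,
                         0.0 if z_constant else _pearson(yp, zv))
        if np.isnan(r_p):
            continue
        stat, ref = (abs(r_p), abs(obs)) if alternative == "two-sided" \
            else (r_p, obs)
        if stat >= ref - 1e-12:
            count += 1
    return MantelResult(obs, (1 + count) / (1 + n_perm), n_perm, method, n)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def mantel_screen(community_dms: Mapping[str, DistanceMatrix],
                  meta: pd.DataFrame,
                  variables: Sequence[str],
                  controls: Sequence[str] = (),
                  method: str = "pearson",
                  n_perm: int = 1000,
                  seed: int = 0,
                  transforms: Mapping[str, str] | None = None,
                  ) -> pd.DataFrame:
    """Grid of simple (and optionally partial) Mantel tests.

    ``community_dms`` maps subset names (e.g. total/abundant/rare) to
    Bray-Curtis matrices; each variable's distance matrix is built from
    ``meta`` (the special name ``geographic`` uses haversine distance).
    For every (variable, control) combination named in ``controls`` a partial
    test is added. Returns a long DataFrame with one row per test.
    """
    transforms = dict(transforms or {})

    def var_dm(name: str, ids: Sequence[str]) -> DistanceMatrix:
        sub = meta.loc[[i for i in ids if i in meta.index]]
        if name == "geographic":
            return haversine_matrix(sub)
        return variable_distance(sub, name, transforms.get(name, "none"))

    rows = []
    for subset, dm in community_dms.items():
        for variable in variables:
            dv_full = var_dm(variable, dm.ids)
            ids = [i for i in dm.ids if i in set(dv_full.ids)]
            if len(ids) < 4:
                raise ValidationError(
                    f"variable {variable!r} retains fewer than 4 samples")
            dsub, dv = dm.filter(ids), dv_full.filter(ids)
            res = mantel(dsub, dv, method, n_perm,
                         derive_seed(seed, "mantel", subset, variable))
            res.variable, res.subset = variable, subset
            rows.append(res)
            for control in controls:
                if control == variable:
                    continue
                dc_full = var_dm(control, ids)
                ids2 = [i for i in ids if i in set(dc_full.ids)]
                if len(ids2) < 4:
                    continue
                res = partial_mantel(
                    dsub.filter(ids2), dv.filter(ids2), dc_full.filter(ids2),
                    method, n_perm,
                    derive_seed(seed, "pmantel", subset, variable, control))
                res.variable, res.subset = variable, subset
                res.controlled_for = control
                res.retained_n = len(ids2)
                rows.append(res)
    return pd.DataFrame([vars(r) for r in rows])


def spearman_screen(values: pd.DataFrame, meta: pd.DataFrame,
                    variables: Sequence[str], alpha: float = 0.05,
                    min_n: int = 5) -> CorrelationScreenResult:
    """Spearman correlation of each value series against each variable.

    ``values`` holds per-sample series (alpha indices or taxon relative
    abundances) in columns; rho uses average-rank tie handling and p the
    t-approximation on n-2 degrees of freedom (scipy). Cells with fewer than
    ``min_n`` paired observations or zero variance are NaN.
    """
    rho = pd.DataFrame(index=values.columns, columns=list(variables),
                       dtype=float)
    pv = rho.copy()
    for series_name in values.columns:
        for var in variables:
            if var not in meta.columns:
                raise ValidationError(f"unknown metadata variable {var!r}")
            joined = pd.concat([values[series_name],
                                pd.to_numeric(meta[var], errors="coerce")],
                               axis=1, join="inner").dropna()
            if len(joined) < min_n:
                continue
            a, b = joined.iloc[:, 0], joined.iloc[:, 1]
            if a.nunique() < 2 or b.nunique() < 2:
                continue
            r, p = stats.spearmanr(a, b)
            rho.loc[series_name, var] = r
            pv.loc[series_name, var] = p
    mask = (pv <= alpha) & pv.notna()
    return CorrelationScreenResult(rho, pv, mask, alpha)
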