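"""Domain types, file I/O, configuration, and seeding shared by all stages.

The central containers are :class:`CommunityTable` (samples x OTUs integer read
counts), sample metadata as a validated :class:`pandas.DataFrame`, phylogenies
as :class:`dendropy.Tree`, and labeled distance matrices as
:class:`skbio.DistanceMatrix`. Counts are always stored as integers; relative
abundances are derived views, never primary data, because rarefaction and the
Raup-Crick null both operate on integer reads.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

logger = logging.getLogger("planktonic")

__all__ = [
    "CommunityTable",
    "AnalysisConfig",
    "ValidationError",
    "derive_seed",
    "read_community_table",
    "read_metadata",
    "read_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_results",
    "METADATA_NUMERIC_COLUMNS",
]

#: metadata columns coerced to float when present (units in read_metadata docs)
METADATA_NUMERIC_COLUMNS = (
    "latitude", "longitude", "depth", "temperature", "salinity",
    "no2", "no3", "po4", "sio4", "chl_a",
    "prochlorococcus", "synechococcus", "ppes",
    "heterotrophic_prokaryotes", "vlps",
)

REAL_FORMAT = "%.10g"  # deterministic serialization; round-trips within 1e-9


class ValidationError(ValueError):
    """Raised when an input table, tree, or metadata file fails validation."""


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *tokens: Any) -> int:
    """Derive a child seed deterministically from a master seed and tokens.

    Stable across processes (SHA-256 based, unlike ``hash``); the result is
    always a non-negative int below 2**31 so it is safe for any RNG API.
    """
    key = "|".join([str(int(master_seed)), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns OTUs; values non-negative integers.
    taxonomy : dict, optional
        Map of otu_id to a ranked lineage string.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("empty community table")
        for axis, name in ((df.index, "sample"), (df.columns, "OTU")):
            dup = axis[axis.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {name} label: {dup[0]!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("community table contains non-numeric cells")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}")
        if not np.allclose(values, np.round(values), atol=0):
            i, j = np.argwhere(values != np.round(values))[0]
            raise ValidationError(
                f"non-integer count at sample {df.index[i]!r}, OTU {df.columns[j]!r}")
        self.counts = df.astype(np.int64)
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            empty = list(sums.index[sums == 0])
            raise ValidationError(f"samples with zero reads: {empty}")

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; each row sums to 1 (within 1e-12)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def subset_otus(self, otu_ids: Iterable[str], drop_empty_samples: bool = False,
                    ) -> "CommunityTable":
        """Restrict to a subset of OTUs (order preserved from this table)."""
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        if not keep:
            raise ValidationError("OTU subset is empty")
        sub = self.counts[keep]
        if drop_empty_samples:
            sub = sub.loc[sub.sum(axis=1) > 0]
        tax = {o: self.taxonomy[o] for o in keep if o in self.taxonomy} \
            if self.taxonomy else None
        return CommunityTable(sub.copy(), tax)

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return self.subset_otus(keep)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds, permutation counts, and the master seed for a full run.

    Defaults follow the study design this pipeline reproduces: rarefaction to
    the minimum sample depth (9634 reads in the original survey), abundant
    OTUs above 1% and rare below 0.01% of total reads, per-sample rare/abundant
    bands of 0.1%/1% for conditionally rare taxa, 999 null randomizations for
    the phylogenetic and Raup-Crick null models, 1000 Mantel / 999 ANOSIM
    permutations, selection called at |betaNTI| > 2 and dispersal at
    |RCbray| > 0.95, and a 50% cumulative SIMPER cut.
    """

    rarefaction_depth: int | None = None  # None -> minimum sample sum
    rarefaction_replicates: int = 100
    abundant_threshold: float = 0.01
    rare_threshold: float = 0.0001
    per_sample_rare_threshold: float = 0.001
    per_sample_abundant_threshold: float = 0.01
    n_null: int = 999
    n_perm_mantel: int = 1000
    n_perm_anosim: int = 999
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    simper_cumulative_cut: float = 0.50
    shannon_base: str = "e"  # "e" (nats) or "2" (bits)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rare_threshold < self.abundant_threshold <= 1):
            raise ValidationError(
                "need 0 < rare_threshold < abundant_threshold <= 1")
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")
        for name in ("per_sample_rare_threshold", "per_sample_abundant_threshold",
                     "bnti_cut", "rc_cut", "simper_cumulative_cut"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.shannon_base not in ("e", "2"):
            raise ValidationError("shannon_base must be 'e' or '2'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _check_duplicate_header(path: Path, sep: str = "\t") -> None:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#") and not line.startswith("#OTU ID"):
                continue  # BIOM-TSV comment line
            labels = line.split(sep)[1:]
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise ValidationError(f"duplicate label in header: {lab!r}")
                seen.add(lab)
            return


def read_community_table(path: str | Path,
                         orientation: str = "samples_as_rows",
                         ) -> CommunityTable:
    """Read an OTU count table from TSV.

    Accepts plain TSV (one header row, one label column) and the BIOM-TSV
    dialect whose header starts with ``#OTU ID`` (implies OTUs as rows).
    ``orientation`` is ``samples_as_rows`` or ``otus_as_rows``; the returned
    table is always samples x OTUs.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    _check_duplicate_header(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        if first.startswith("#OTU ID"):
            orientation = "otus_as_rows"
        else:  # leading comment, real header on a later line
            skip = 1
            with open(path) as fh:
                fh.readline()
                if fh.readline().startswith("#OTU ID"):
                    orientation = "otus_as_rows"
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate label in first column: {dup[0]!r}")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & ~df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}")
    if body.isna().to_numpy().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"missing count at row {df.index[i]!r}, column {df.columns[j]!r}")
    if orientation == "otus_as_rows":
        body = body.T
    body.index = pd.Index([str(i) for i in body.index])
    body.columns = pd.Index([str(c) for c in body.columns])
    return CommunityTable(body)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV into a DataFrame indexed by ``sample_id``.

    Recognized numeric columns (``latitude`` deg, ``longitude`` deg, ``depth``
    m, ``temperature`` degC, ``salinity`` PSU, nutrients umol/L, ``chl_a``
    ug/L, picoplankton/VLP abundances per mL) are coerced to float with blank
    cells becoming NaN (explicit missing). Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValidationError("metadata must contain a 'sample_id' column")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")
    df = df.set_index("sample_id")
    for col in METADATA_NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "latitude" in df.columns:
        bad = df.index[(df["latitude"].abs() > 90) & df["latitude"].notna()]
        if len(bad):
            raise ValidationError(f"latitude out of [-90, 90] for sample {bad[0]!r}")
    if "longitude" in df.columns:
        bad = df.index[(df["longitude"].abs() > 180) & df["longitude"].notna()]
        if len(bad):
            raise ValidationError(f"longitude out of [-180, 180] for sample {bad[0]!r}")
    if "depth" in df.columns:
        bad = df.index[(df["depth"] < 0) & df["depth"].notna()]
        if len(bad):
            raise ValidationError(f"negative depth for sample {bad[0]!r}")
    return df


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    Accepts a filesystem path or a raw Newick string. Edges without a length
    get length 0 (with a logged warning); duplicate tip labels are rejected.
    """
    s = str(path_or_string)
    try:
        if "(" in s and ";" in s:  # raw newick string
            tree = dendropy.Tree.get(data=s, schema="newick")
        else:
            tree = dendropy.Tree.get(path=s, schema="newick")
    except Exception as exc:  # dendropy reports character position
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"duplicate tip label: {exc}") from exc
        raise ValidationError(f"unparseable Newick: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
            if edge.tail_node is not None:  # ignore the root's seed edge
                n_missing += 1
        elif edge.length < 0:
            raise ValidationError("negative branch length in tree")
    if n_missing:
        logger.warning("tree had %d edges without branch length; set to 0",
                       n_missing)
    tree.is_rooted = True
    return tree


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square labeled TSV back into a DistanceMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = 0.5 * (values + values.T)  # symmetrize serialization round-off
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, [str(i) for i in df.index])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep="\t", float_format=REAL_FORMAT)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def write_frame(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=REAL_FORMAT, index=index)


def write_results(obj: Any, path: str | Path) -> None:
    """Serialize any pipeline result to a deterministic TSV.

    Dispatches on type: DistanceMatrix -> square TSV, CommunityTable -> count
    TSV, DataFrame -> TSV, list of dataclasses -> long-format TSV (one row per
    element), dataclass -> two-column field/value TSV.
    """
    if isinstance(obj, DistanceMatrix):
        write_distance_matrix(obj, path)
    elif isinstance(obj, CommunityTable):
        write_community_table(obj, path)
    elif isinstance(obj, pd.DataFrame):
        write_frame(obj, path)
    elif isinstance(obj, pd.Series):
        write_frame(obj.to_frame(), path)
    elif isinstance(obj, (list, tuple)) and obj and dataclasses.is_dataclass(obj[0]):
        write_frame(pd.DataFrame([dataclasses.asdict(o) for o in obj]),
                    path, index=False)
    elif dataclasses.is_dataclass(obj):
        items = dataclasses.asdict(obj)
        write_frame(pd.DataFrame({"field": list(items), "value":
                                  [items[k] for k in items]}), path, index=False)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")
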