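"""Reading, validation and normalization of ASV community inputs.

The canonical in-memory community object is :class:`AsvTable`, a validated
samples x ASVs integer count matrix backed by a pandas DataFrame. Input
files are plain TSV; phylogenies are newick read into scikit-bio trees.

Normalization follows common amplicon practice: ASVs whose total count
across all samples is 1 (singletons) are removed, and samples are rarefied
(subsampled without replacement) to a common read depth, by default the
smallest sample total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


class AsvTableError(ValueError):
    """Raised for structurally invalid community tables or inputs."""


@dataclass(frozen=True)
class AsvTable:
    """Samples x ASVs nonnegative integer count matrix.

    Parameters
    ----------
    data :
        DataFrame with sample identifiers as the index and ASV identifiers
        as columns. Entries must be nonnegative and integral.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise AsvTableError(f"duplicate identifier(s) in samples: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise AsvTableError(f"duplicate identifier(s) in ASVs: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise AsvTableError("non-numeric entries in count table")
        if np.isnan(values.astype(float)).any():
            raise AsvTableError("missing values in count table")
        if (values < 0).any():
            raise AsvTableError("negative count in table")
        if not np.allclose(values, np.round(values.astype(float))):
            raise AsvTableError("non-integral counts in table")
        if not np.issubdtype(values.dtype, np.integer):
            object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Integer count matrix, shape (n_samples, n_asvs)."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "AsvTable":
        """Restrict to the given samples, dropping ASVs absent from all of them."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise AsvTableError(f"unknown sample(s): {missing}")
        sub = self.data.loc[sample_ids]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return AsvTable(sub)


@dataclass(frozen=True)
class TaxonomyMap:
    """ASV -> (group, lineage, genus, species) annotation table.

    ``group`` assigns each ASV to a plankton group (e.g. phytoplankton or
    microzooplankton); ``lineage`` is a phylum-level label.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "lineage"}
        missing = required - set(self.data.columns)
        if missing:
            raise AsvTableError(f"taxonomy missing column(s): {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise AsvTableError("duplicate ASV identifiers in taxonomy")
        if self.data["group"].isna().any() or (self.data["group"] == "").any():
            raise AsvTableError("every ASV must have a group annotation")
        if self.data["lineage"].isna().any() or (self.data["lineage"] == "").any():
            raise AsvTableError("lineage labels must be non-empty")

    def group_of(self, asv_id: str) -> str:
        return str(self.data.at[asv_id, "group"])

    def lineage_of(self, asv_id: str) -> str:
        return str(self.data.at[asv_id, "lineage"])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample region label, coordinates and environmental variables.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id with columns ``region``, ``lat``,
        ``lon`` and the environmental variables named in ``env_columns``.
    env_columns :
        Names of the real-valued environmental variables.
    """

    data: pd.DataFrame
    env_columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        required = ["region", "lat", "lon", *self.env_columns]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise AsvTableError(f"metadata missing column(s): {missing}")
        if self.data.index.has_duplicates:
            raise AsvTableError("duplicate sample identifiers in metadata")
        lat = self.data["lat"].astype(float)
        lon = self.data["lon"].astype(float)
        if lat.isna().any() or lon.isna().any():
            raise AsvTableError("missing coordinates in metadata")
        if ((lat < -90) | (lat > 90)).any():
            bad = self.data.index[(lat < -90) | (lat > 90)].tolist()
            raise AsvTableError(f"latitude out of [-90, 90] for sample(s): {bad}")
        if ((lon < -180) | (lon > 180)).any():
            bad = self.data.index[(lon < -180) | (lon > 180)].tolist()
            raise AsvTableError(f"longitude out of [-180, 180] for sample(s): {bad}")
        env = self.data[list(self.env_columns)]
        if env.isna().any().any():
            raise AsvTableError("missing environmental values in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def regions(self) -> pd.Series:
        return self.data["region"]

    def env_matrix(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        """Environmental variables as a samples x variables float DataFrame."""
        df = self.data[list(self.env_columns)].astype(float)
        if sample_ids is not None:
            df = df.loc[sample_ids]
        return df

    def coords(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        df = self.data[["lat", "lon"]].astype(float)
        if sample_ids is not None:
            df = df.loc[sample_ids]
        return df


def read_asv_table(path: str | Path, orientation: str = "asvs_as_rows") -> AsvTable:
    """Read a TSV count table into an :class:`AsvTable`.

    Parameters
    ----------
    path :
        Tab-separated file. With the default orientation the first column
        holds ASV identifiers and the header row holds sample identifiers.
    orientation :
        ``"asvs_as_rows"`` (the common feature-table layout) or
        ``"samples_as_rows"``. The internal canonical form is always
        samples x ASVs.
    """
    if orientation not in ("asvs_as_rows", "samples_as_rows"):
        raise AsvTableError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # ragged rows and similar parser failures
        raise AsvTableError(f"could not parse table {path}: {exc}") from exc
    if orientation == "asvs_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise AsvTableError(f"non-numeric entries in {path}: {exc}") from exc
    return AsvTable(df)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a TSV taxonomy with columns asv_id, group, lineage, genus, species."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    for col in ("genus", "species"):
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].fillna("unknown")
    return TaxonomyMap(df)


def read_metadata(path: str | Path, env_columns: list[str]) -> SampleMetadata:
    """Read a TSV sample metadata file.

    Requires columns ``region``, ``lat``, ``lon`` and every name in
    ``env_columns``; the first column is the sample identifier.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in ["region", "lat", "lon", *env_columns] if c not in df.columns]
    if missing:
        raise AsvTableError(f"metadata file {path} missing column(s): {missing}")
    return SampleMetadata(df, tuple(env_columns))


def filter_singletons(t: AsvTable) -> AsvTable:
    """Drop ASVs whose total count across all samples is 1.

    A singleton is defined on the table-wide total, not per sample; an ASV
    seen once in each of two samples (total 2) is retained. Idempotent.
    """
    totals = t.data.sum(axis=0)
    keep = totals >= 2
    if not keep.any():
        raise AsvTableError("empty table after filtering")
    return AsvTable(t.data.loc[:, keep])


def rarefy(t: AsvTable, depth: int | str = "min", seed: int | None = None) -> AsvTable:
    """Subsample each sample without replacement to a common read depth.

    Draws are multivariate hypergeometric per sample, so every output row
    sums exactly to ``depth`` and no count exceeds its input. ``depth="min"``
    uses the smallest sample total. Reproducible given ``seed``.
    """
    row_sums = t.data.sum(axis=1)
    if depth == "min":
        depth = int(row_sums.min())
    depth = int(depth)
    if depth <= 0:
        raise AsvTableError("rarefaction depth must be positive")
    shallow = row_sums[row_sums < depth]
    if len(shallow):
        raise AsvTableError(
            f"sample(s) below rarefaction depth {depth}: "
            f"{dict(shallow.astype(int))}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(t.counts)
    for i, row in enumerate(t.counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=t.data.index, columns=t.data.columns)
    return AsvTable(df)


def split_by_group(
    t: AsvTable, tax: TaxonomyMap, on_missing: str = "error"
) -> dict[str, AsvTable]:
    """Partition the table's ASV columns by taxonomic group.

    Returns one table per group label, preserving counts and the full
    sample set. ASVs absent from the taxonomy raise an error unless
    ``on_missing="drop"``, in which case they are dropped with a warning.
    """
    if on_missing not in ("error", "drop"):
        raise AsvTableError(f"unknown on_missing mode: {on_missing!r}")
    missing = [a for a in t.asv_ids if a not in tax.data.index]
    if missing:
        if on_missing == "error":
            raise AsvTableError(f"ASV(s) missing from taxonomy: {missing[:10]}")
        warnings.warn(f"dropping {len(missing)} ASV(s) missing from taxonomy")
    annotated = [a for a in t.asv_ids if a in tax.data.index]
    groups = tax.data.loc[annotated, "group"]
    out: dict[str, AsvTable] = {}
    for g in pd.unique(groups):
        cols = groups.index[groups == g].tolist()
        out[str(g)] = AsvTable(t.data[cols])
    if len(out) == 1:
        warnings.warn("all annotated ASVs belong to a single group")
    return out


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick phylogeny.

    Missing branch lengths are set to 0 with a warning; duplicate tip
    labels are rejected.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise AsvTableError(f"could not parse newick {path}: {exc}") from exc
    tips = [tip.name for tip in tree.tips()]
    if len(tips) != len(set(tips)):
        dupes = sorted({n for n in tips if tips.count(n) > 1})
        raise AsvTableError(f"duplicate tip label(s): {dupes}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise AsvTableError(f"negative branch length at {node.name!r}")
    if n_missing:
        warnings.warn(f"{n_missing} branch length(s) missing; set to 0")
    return tree
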