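"""Input tables for microbiota GLMMs.

Reads and validates the three tables every analysis starts from — an
ASV-by-sample count matrix, per-sample metadata (host, group), and an
optional taxonomy table — and assembles them into the complete long-format
observation grid the Poisson mixed model is fitted to. Zeros are
materialised as explicit rows: the likelihood needs them, and the
zero-adequacy diagnostic counts them.

ID matching is exact-string and case-sensitive throughout; silent coercion
hides sample mix-ups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "TaxonomyTable",
    "LongObservations",
    "read_count_matrix",
    "read_metadata",
    "read_taxonomy",
    "assemble_long",
    "filter_taxa",
    "write_long",
    "read_long",
    "ValidationError",
]

#: canonical rank order, Kingdom down to Genus
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """An input table violates its contract."""


@dataclass
class CountMatrix:
    """ASV-by-sample matrix of non-negative integer read counts.

    ``counts`` is indexed by ASV id with one column per sample id; ids are
    unique and the grid has no missing cells.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.isna().any().any():
            raise ValidationError("count matrix has missing cells")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix has non-numeric cells")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at ASV {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if not np.array_equal(arr, np.floor(arr)):
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise ValidationError(
                f"non-integer count at ASV {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        df = df.astype(np.int64)
        df.index = df.index.astype(str).rename("asv_id")
        df.columns = df.columns.astype(str).rename(None)
        self.counts = df

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class SampleMetadata:
    """One row per sample: the host it came from and its group level."""

    table: pd.DataFrame  # index sample_id; columns host_id, group, ...
    group_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in ("host_id", "group"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
            if self.table[col].isna().any():
                raise ValidationError(f"metadata column {col!r} has missing values")
        if not self.group_levels:
            self.group_levels = sorted(self.table["group"].astype(str).unique())
        self.table = self.table.assign(
            host_id=self.table["host_id"].astype(str),
            group=self.table["group"].astype(str),
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class TaxonomyTable:
    """ASV id to rank labels (Kingdom..Genus); missing labels pool to
    ``unclassified`` so the observation grid stays complete."""

    table: pd.DataFrame  # index asv_id; columns a subset of RANKS, in order

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids in taxonomy: {dups}")
        ranks = [r for r in RANKS if r in self.table.columns]
        extra = [c for c in self.table.columns if c not in RANKS]
        if extra:
            raise ValidationError(f"unknown taxonomy columns: {extra} (expected {list(RANKS)})")
        tab = self.table[ranks].copy()
        for r in ranks:
            tab[r] = tab[r].astype("string").fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
            tab[r] = tab[r].astype(str)
        self.table = tab

    @property
    def ranks(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class LongObservations:
    """Complete (ASV x sample) grid in long form, one row per cell.

    Columns: asv_id, sample_id, host_id, group, count [, rank columns].
    For CLR-transformed data the response lives in a ``value`` column
    instead of ``count``.
    """

    data: pd.DataFrame
    response: str = "count"

    def __post_init__(self) -> None:
        needed = ["asv_id", "sample_id", "host_id", "group", self.response]
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValidationError(f"long table missing columns: {missing}")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def rank_columns(self) -> list[str]:
        return [r for r in RANKS if r in self.data.columns]


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a wide ASV-by-sample count table.

    TSV layout: first column is the ASV id, remaining columns are samples.
    BIOM v1 (JSON) and v2.1 (HDF5) are supported read-only.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        try:
            num = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
        return CountMatrix(num)
    if format == "biom":
        return _read_biom(path)
    raise ValidationError(f"unknown count-matrix format {format!r}")


def _read_biom(path: Path) -> CountMatrix:
    """Minimal BIOM reader: v1 JSON and v2.1 HDF5 dialects."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as h5:
            asv_ids = [x.decode() for x in h5["observation/ids"][:]]
            sample_ids = [x.decode() for x in h5["sample/ids"][:]]
            # CSR over observations
            data = h5["observation/matrix/data"][:]
            indices = h5["observation/matrix/indices"][:]
            indptr = h5["observation/matrix/indptr"][:]
            from scipy.sparse import csr_matrix

            mat = csr_matrix(
                (data, indices, indptr), shape=(len(asv_ids), len(sample_ids))
            ).toarray()
        return CountMatrix(pd.DataFrame(mat, index=asv_ids, columns=sample_ids))
    with open(path) as fh:
        doc = json.load(fh)
    asv_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    mat = np.zeros((len(asv_ids), len(sample_ids)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[r, c] = v
    return CountMatrix(pd.DataFrame(mat, index=asv_ids, columns=sample_ids))


def read_metadata(
    path: str | Path,
    sample_col: str = "sample_id",
    host_col: str = "host_id",
    group_col: str = "group",
) -> SampleMetadata:
    """Read the per-sample metadata TSV; column names are configurable."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (sample_col, host_col, group_col):
        if col not in df.columns:
            raise ValidationError(f"metadata file missing column {col!r}")
    df = df.rename(columns={sample_col: "sample_id", host_col: "host_id", group_col: "group"})
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_taxonomy(path: str | Path, asv_col: str = "asv_id") -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if asv_col not in df.columns:
        raise ValidationError(f"taxonomy file missing column {asv_col!r}")
    df = df.set_index(asv_col)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def assemble_long(
    counts: CountMatrix,
    meta: SampleMetadata,
    tax: TaxonomyTable | None = None,
) -> LongObservations:
    """Build the complete long-format observation grid.

    Every (ASV, sample) cell becomes one row — zeros included — annotated
    with the sample's host and group and, when a taxonomy is given, the
    ASV's rank labels. The grand total of counts is conserved exactly.
    """
    missing = [s for s in counts.sample_ids if s not in meta.table.index]
    if missing:
        raise ValidationError(f"samples in counts absent from metadata: {missing}")
    long = (
        counts.counts.rename_axis("asv_id")
        .reset_index()
        .melt(id_vars="asv_id", var_name="sample_id", value_name="count")
    )
    long["asv_id"] = long["asv_id"].astype(str)
    long["sample_id"] = long["sample_id"].astype(str)
    long = long.merge(
        meta.table[["host_id", "group"]].rename_axis("sample_id").reset_index(),
        on="sample_id",
        how="left",
    )
    if tax is not None:
        unknown = [a for a in counts.asv_ids if a not in tax.table.index]
        ann = tax.table.reindex(long["asv_id"])
        for r in tax.ranks:
            long[r] = ann[r].fillna(UNCLASSIFIED).to_numpy()
        if unknown:
            # grid completeness beats taxonomy completeness: pool, don't drop
            pass
    cols = ["asv_id", "sample_id", "host_id", "group", "count"]
    cols += [c for c in RANKS if c in long.columns]
    long = long[cols].sort_values(["asv_id", "sample_id"], kind="stable").reset_index(drop=True)
    obs = LongObservations(long)
    assert obs.n_rows == len(counts.asv_ids) * len(counts.sample_ids)
    assert int(long["count"].sum()) == counts.total
    return obs


def filter_taxa(
    counts: CountMatrix, min_total_reads: int = 0, min_prevalence: float = 0.0
) -> CountMatrix:
    """Abundance-threshold filter for sensitivity analyses.

    Keeps ASVs whose total read count is at least ``min_total_reads`` and
    which are present (count > 0) in at least ``min_prevalence`` of
    samples. The sample set and ASV order are unchanged.
    """
    if min_total_reads < 0:
        raise ValidationError("min_total_reads must be >= 0")
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValidationError("min_prevalence must be in [0, 1]")
    df = counts.counts
    totals = df.sum(axis=1)
    prevalence = (df > 0).mean(axis=1)
    keep = (totals >= min_total_reads) & (prevalence >= min_prevalence)
    if not keep.any():
        raise ValidationError("abundance filter removed every ASV")
    return CountMatrix(df.loc[keep])


def write_long(obs: LongObservations, path: str | Path) -> None:
    """Write the long table as TSV; reading it back is lossless."""
    obs.data.to_csv(path, sep="\t", index=False)


def read_long(path: str | Path, response: str = "count") -> LongObservations:
    df = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "sample_id": str, "host_id": str, "group": str})
    if response == "count" and "count" in df.columns:
        df["count"] = df["count"].astype(np.int64)
    return LongObservations(df, response=response)
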