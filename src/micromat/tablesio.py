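"""Tabular I/O for abundance tables, KO tables, metadata and pathway maps.

All tables are TSV, UTF-8, ``.`` decimal separator. Feature tables are
oriented taxa x samples with the first header cell ``#ID``. Metadata files
carry the columns ``sample_id  subject_id  group  age_days``; pathway maps
carry ``pathway_id  ko_id`` with one membership pair per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_REL_TOL = 1e-6


class TableValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class AbundanceTable:
    """Taxa x samples feature table of counts or relative abundances.

    Parameters
    ----------
    data:
        DataFrame indexed by taxon id with sample ids as columns. Values
        must be non-negative and finite.
    kind:
        ``"counts"`` for integer-valued count tables, ``"relative"`` for
        compositions whose columns each sum to 1.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise TableValidationError(f"unknown table kind {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableValidationError("table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableValidationError(
                "negative value at taxon "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if self.kind == "relative" and values.size:
            sums = values.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _REL_TOL)
            if bad.size:
                names = self.data.columns[bad].tolist()
                raise TableValidationError(
                    f"relative table columns do not sum to 1: {names}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence) -> "AbundanceTable":
        return type(self)(self.data.loc[:, list(sample_ids)], kind=self.kind)


class KoTable(AbundanceTable):
    """KO x samples functional-gene abundance table."""

    @property
    def ko_ids(self) -> list:
        return self.data.index.tolist()


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject, treatment group and chronologic age."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "group", "age_days")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise TableValidationError(f"metadata missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise TableValidationError(f"duplicate sample ids: {dups.tolist()}")
        ages = self.data["age_days"]
        if not (ages >= 0).all():
            raise TableValidationError("age_days must be >= 0")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return self.data["sample_id"].tolist()

    def ages_for(self, sample_ids: Sequence) -> np.ndarray:
        ser = self.data.set_index("sample_id")["age_days"]
        return ser.loc[list(sample_ids)].to_numpy(dtype=float)

    def groups_for(self, sample_ids: Sequence) -> np.ndarray:
        ser = self.data.set_index("sample_id")["group"]
        return ser.loc[list(sample_ids)].to_numpy()

    def samples_in_group(self, group: str) -> list:
        return self.data.loc[self.data["group"] == group, "sample_id"].tolist()

    def check_covers(self, table: AbundanceTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise TableValidationError(
                f"samples absent from metadata: {sorted(missing)}"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway and the set of member KO identifiers."""

    pathway_id: str
    member_kos: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.member_kos:
            raise TableValidationError(
                f"pathway {self.pathway_id!r} has no member KOs"
            )

    @property
    def k(self) -> int:
        return len(self.member_kos)


# -----------------------------------------------------------------------------
# readers / writers
# -----------------------------------------------------------------------------

def _read_feature_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "#ID"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TableValidationError(f"{path}: non-numeric table body ({exc})") from exc
    if df.isna().any().any():
        raise TableValidationError(f"{path}: missing/ragged values in table body")
    return df


def _infer_kind(values: np.ndarray) -> str:
    # integer-valued => counts; fractional columns summing to 1 => relative;
    # anything else is treated as generic (counts-kind) abundances
    if values.size == 0:
        return "counts"
    if np.allclose(values, np.round(values)):
        return "counts"
    sums = values.sum(axis=0)
    return "relative" if np.allclose(sums, 1.0, atol=_REL_TOL) else "counts"


def read_abundance_table(path, kind: str | None = None) -> AbundanceTable:
    """Read a taxa x samples TSV; ``kind`` is inferred unless given."""
    df = _read_feature_tsv(path)
    if kind is None:
        kind = _infer_kind(df.to_numpy(dtype=float))
    return AbundanceTable(df, kind=kind)


def read_ko_table(path, kind: str | None = None) -> KoTable:
    """Read a KO x samples TSV."""
    df = _read_feature_tsv(path)
    if kind is None:
        kind = _infer_kind(df.to_numpy(dtype=float))
    return KoTable(df, kind=kind)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.index.name = "#ID"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str, "group": str})
    unknown = [c for c in df.columns if c not in SampleMetadata.REQUIRED]
    if unknown:
        raise TableValidationError(f"{path}: unknown metadata columns {unknown}")
    meta = SampleMetadata(df)
    meta.data["age_days"] = meta.data["age_days"].astype(int)
    return meta


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_pathway_map(path) -> list[PathwayDefinition]:
    """Read ``pathway_id\\tko_id`` rows, aggregating into member sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["pathway_id", "ko_id"]
    if list(df.columns) != expected:
        raise TableValidationError(
            f"{path}: pathway map must have columns {expected}, got {list(df.columns)}"
        )
    if df.isna().any().any():
        raise TableValidationError(f"{path}: missing values in pathway map")
    out = []
    for pid, grp in df.groupby("pathway_id", sort=True):
        out.append(PathwayDefinition(str(pid), frozenset(grp["ko_id"])))
    return out


def write_pathway_map(pathways: Iterable[PathwayDefinition], path) -> None:
    rows = [
        {"pathway_id": p.pathway_id, "ko_id": ko}
        for p in pathways
        for ko in sorted(p.member_kos)
    ]
    pd.DataFrame(rows, columns=["pathway_id", "ko_id"]).to_csv(path, sep="\t", index=False)


# -----------------------------------------------------------------------------
# transforms
# -----------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to unit sum. Idempotent on relative input."""
    if table.kind == "relative":
        return table
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise TableValidationError(f"all-zero samples cannot be normalized: {names}")
    return AbundanceTable(table.data / sums, kind="relative")


def rarefy(
    table: AbundanceTable,
    depth: int,
    seed: int | np.random.Generator = 0,
    drop_shallow: bool = False,
) -> AbundanceTable:
    """Subsample each sample's counts without replacement to ``depth`` reads.

    Draws a multivariate hypergeometric sample per column, so every output
    column sums to exactly ``depth``. Samples with fewer than ``depth`` total
    counts raise unless ``drop_shallow`` is set, in which case they are
    excluded (and logged).
    """
    if table.kind != "counts":
        raise TableValidationError("rarefaction requires a count table")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = np.round(table.values).astype(np.int64)
    totals = counts.sum(axis=0)
    shallow = np.flatnonzero(totals < depth)
    keep = np.arange(table.n_samples)
    if shallow.size:
        names = [table.sample_ids[i] for i in shallow]
        if not drop_shallow:
            raise TableValidationError(
                f"samples below rarefaction depth {depth}: {names}"
            )
        logger.warning("dropping %d samples below depth %d: %s", len(names), depth, names)
        keep = np.setdiff1d(keep, shallow)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros((table.n_taxa, keep.size), dtype=np.int64)
    for j, col in enumerate(keep):
        if totals[col] == depth:
            out[:, j] = counts[:, col]
        else:
            out[:, j] = rng.multivariate_hypergeometric(counts[:, col], depth)
    df = pd.DataFrame(
        out, index=table.data.index, columns=[table.sample_ids[i] for i in keep]
    )
    return AbundanceTable(df, kind="counts")
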