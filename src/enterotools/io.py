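"""Abundance-table and metadata I/O.

Count tables are tab-separated, taxa in rows, samples in columns, first
header cell ``#TaxonID`` and an optional final ``lineage`` column holding
semicolon-ranked taxonomy strings (kingdom;phylum;class;order;family;genus).
Counts are kept as strict integers because rarefaction subsamples discrete
observations; relative abundances are the only real-valued representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEX_ROLE_LEVELS = ("insertive_only", "versatile", "receptive_only")
PARTNER_LEVELS = ("<=1", "2-5", "6-9", ">=10")
CONDOM_LEVELS = ("never", "sometimes", "always")
BOOL_FIELDS = ("commercial_sex", "group_sex", "std", "illicit_drug")

METADATA_COLUMNS = (
    "sample_id",
    "age",
    "bmi",
    "sex_role",
    "partners",
    "condom",
) + BOOL_FIELDS

UNCLASSIFIED = "unclassified"


class TableFormatError(ValueError):
    """Malformed abundance-table file."""


class ValidationError(ValueError):
    """Table or metadata content violates an invariant."""


@dataclass
class AbundanceTable:
    """Taxa x samples matrix of non-negative integer counts.

    Parameters
    ----------
    taxon_ids : unique row identifiers (OTU ids or genus names).
    sample_ids : unique column identifiers.
    counts : ``(n_taxa, n_samples)`` integer array.
    lineages : optional per-taxon semicolon-ranked taxonomy strings.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineages: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D taxa x samples array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValidationError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicated {name} id(s): {dupes}")
        if self.lineages is not None and len(self.lineages) != len(self.taxon_ids):
            raise ValidationError(
                "lineage list length does not match taxon list length"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class RelativeProfileSet:
    """Per-sample probability vectors over genera (the clustering substrate)."""

    genus_ids: list[str]
    sample_ids: list[str]
    profiles: np.ndarray  # (n_samples, n_genera), rows sum to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.sample_ids), len(self.genus_ids)):
            raise ValidationError("profiles shape mismatch")
        if np.any(self.profiles < 0) or np.any(self.profiles > 1):
            raise ValidationError("profile entries must lie in [0, 1]")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValidationError(f"profile of sample {bad!r} does not sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.sample_ids, columns=self.genus_ids)


def read_abundance_table(path: str | Path, transpose: bool = False) -> AbundanceTable:
    """Read a TSV count table (taxa x samples; ``transpose`` for the samples-in-rows dialect)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cells = header.split("\t")
        if not cells or cells[0] != "#TaxonID":
            raise TableFormatError(
                f"{path}:1: header must start with '#TaxonID', got {cells[0]!r}"
            )
        has_lineage = cells[-1] == "lineage"
        sample_ids = cells[1 : -1 if has_lineage else None]
        taxon_ids: list[str] = []
        lineages: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cells):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(cells)} fields, got {len(parts)}"
                )
            taxon_ids.append(parts[0])
            if has_lineage:
                lineages.append(parts[-1])
                values = parts[1:-1]
            else:
                values = parts[1:]
            row = []
            for sid, v in zip(sample_ids, values):
                try:
                    iv = int(v)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-integer count {v!r} in sample {sid!r}"
                    ) from None
                if iv < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative count {iv} in sample {sid!r}"
                    )
                row.append(iv)
            rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids))
    table = AbundanceTable(taxon_ids, sample_ids, counts, lineages if has_lineage else None)
    if transpose:
        table = AbundanceTable(
            table.sample_ids, table.taxon_ids, table.counts.T, None
        )
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        header = ["#TaxonID", *table.sample_ids]
        if table.lineages is not None:
            header.append("lineage")
        fh.write("\t".join(header) + "\n")
        for i, tid in enumerate(table.taxon_ids):
            row = [tid, *(str(int(c)) for c in table.counts[i])]
            if table.lineages is not None:
                row.append(table.lineages[i])
            fh.write("\t".join(row) + "\n")


def genus_from_lineage(lineage: str) -> str:
    """Extract the rank-6 (genus) field from a semicolon-ranked lineage.

    Rank prefixes of the RDP/Greengenes style (``g__``) are stripped; a
    lineage shorter than six ranks or with an empty genus field maps to
    ``unclassified``.
    """
    ranks = [r.strip() for r in lineage.split(";")]
    if len(ranks) < 6:
        return UNCLASSIFIED
    genus = ranks[5]
    if genus.lower().startswith("g__"):
        genus = genus[3:]
    return genus if genus else UNCLASSIFIED


def aggregate_to_genus(table: AbundanceTable, keep_unclassified: bool = True) -> AbundanceTable:
    """Sum taxon rows into one row per genus; unclassifiable taxa pool into
    a single ``unclassified`` row (dropped when ``keep_unclassified`` is False)."""
    if table.lineages is None:
        raise ValidationError(
            "table has no lineage column; supply a genus-level table directly"
        )
    order: list[str] = []
    index: dict[str, int] = {}
    for lin in table.lineages:
        g = genus_from_lineage(lin)
        if g not in index:
            index[g] = len(order)
            order.append(g)
    counts = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for i, lin in enumerate(table.lineages):
        counts[index[genus_from_lineage(lin)]] += table.counts[i]
    if not keep_unclassified and UNCLASSIFIED in index:
        keep = [i for i, g in enumerate(order) if g != UNCLASSIFIED]
        order = [order[i] for i in keep]
        counts = counts[keep]
    return AbundanceTable(order, list(table.sample_ids), counts)


def to_relative(table: AbundanceTable) -> RelativeProfileSet:
    """Convert counts to per-sample relative-abundance profiles."""
    totals = table.sample_totals()
    zero = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
    if zero:
        raise ValidationError(f"sample(s) with zero total count: {zero}")
    profiles = (table.counts / totals).T
    return RelativeProfileSet(list(table.taxon_ids), list(table.sample_ids), profiles)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample metadata CSV.

    Returns a DataFrame indexed by ``sample_id`` with categorical levels
    checked against the declared vocabularies.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample_id(s) in metadata: {dupes}")
    for col, levels in (
        ("sex_role", SEX_ROLE_LEVELS),
        ("partners", PARTNER_LEVELS),
        ("condom", CONDOM_LEVELS),
    ):
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
    for col in ("age", "bmi"):
        if (df[col] <= 0).any():
            raise ValidationError(f"{col} must be positive")
    for col in BOOL_FIELDS:
        df[col] = df[col].astype(bool)
    return df.set_index("sample_id")


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().rename(columns={"index": "sample_id"}).to_csv(path, index=False)


def align_metadata(table: AbundanceTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate that every metadata sample matches a table column; return
    metadata reindexed to the table's sample order."""
    missing = set(metadata.index) - set(table.sample_ids)
    if missing:
        raise ValidationError(
            f"metadata sample(s) not in table: {sorted(missing)}"
        )
    missing = set(table.sample_ids) - set(metadata.index)
    if missing:
        raise ValidationError(f"table sample(s) missing metadata: {sorted(missing)}")
    return metadata.loc[list(table.sample_ids)]
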