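"""Domain containers for multi-site microbial abundance time series.

A :class:`CommunityTable` holds one site's OTU x time matrix of raw read
counts (raw, never relative, abundances are what all downstream estimators
consume); a :class:`TaxonomyTable` maps OTUs to their ranked lineage
(kingdom through genus); a :class:`StudySet` bundles one pair per site.

File formats are plain TSV (UTF-8, header row); an optional BIOM v1 (JSON)
reader is provided for abundance tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    EmptyTableError,
    MissingColumnError,
    MissingFileError,
    NonNumericCellError,
    PhylumNotFoundError,
    RankOrderError,
)

#: Fixed rank order used everywhere (column order in taxonomy files, tree depth).
RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Reserved token for a missing rank assignment. Never dropped: the tree
#: builder decides placement explicitly (unique placeholder per parent lineage).
UNASSIGNED = "unassigned"


@dataclass
class CommunityTable:
    """One site's OTU x time abundance matrix of non-negative integer read counts.

    Parameters
    ----------
    site_id:
        Site label (e.g. ``"TT1"``).
    habitat:
        Habitat class label (user-defined set, e.g. ``"riverine"``).
    counts:
        DataFrame indexed by OTU id with one column per (opaque, ordered)
        time label. Time labels are never parsed as dates; only their order
        matters for the lag-1 estimators.
    """

    site_id: str
    habitat: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise EmptyTableError(
                f"community table for site {self.site_id!r} has shape "
                f"{self.counts.shape}; need at least 1 OTU and 1 time point"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate OTU ids: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise NonNumericCellError("counts matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            raise NonNumericCellError("counts matrix contains non-finite values")
        if (arr < 0).any():
            raise NonNumericCellError("counts must be non-negative read counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def otu_ids(self) -> list[str]:
        return [str(i) for i in self.counts.index]

    @property
    def times(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def n_otu(self) -> int:
        return self.counts.shape[0]

    @property
    def t(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        """Counts as an (n_otu, t) int array."""
        return self.counts.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Column-wise relative abundances, for plotting only.

        All estimators in this package work on raw counts; this helper exists
        for stacked-area style visual summaries of community composition.
        """
        totals = self.counts.sum(axis=0).replace(0, np.nan)
        return self.counts / totals

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("otu_id").to_csv(path, sep="\t")


@dataclass
class TaxonomyTable:
    """OTU -> ranked lineage map with a fixed kingdom...genus column order."""

    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        cols = [str(c) for c in self.assignments.columns]
        if set(cols) != set(RANKS):
            missing = [r for r in RANKS if r not in cols]
            if missing:
                raise MissingColumnError(f"taxonomy is missing rank column(s): {missing}")
        if tuple(cols) != RANKS:
            raise RankOrderError(
                f"taxonomy ranks must appear in order {list(RANKS)}, got {cols}"
            )
        if self.assignments.index.has_duplicates:
            dups = self.assignments.index[
                self.assignments.index.duplicated()
            ].unique().tolist()
            raise DuplicateIdError(f"duplicate otu_id in taxonomy: {dups}")
        filled = self.assignments.astype("string")
        filled = filled.fillna(UNASSIGNED)
        filled = filled.map(lambda s: UNASSIGNED if str(s).strip() == "" else str(s))
        self.assignments = filled.astype(str)

    @property
    def otu_ids(self) -> list[str]:
        return [str(i) for i in self.assignments.index]

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.assignments.index

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        """The six-rank lineage of one OTU (with explicit ``unassigned`` cells)."""
        from .errors import UnknownOTUError

        if otu_id not in self.assignments.index:
            raise UnknownOTUError(f"otu_id {otu_id!r} not in taxonomy")
        return tuple(self.assignments.loc[otu_id, list(RANKS)])

    def phylum_of(self, otu_id: str) -> str:
        return self.lineage(otu_id)[1]

    def phyla(self, otu_ids: Sequence[str] | None = None) -> list[str]:
        """Distinct phylum labels, optionally restricted to a set of OTUs."""
        sub = self.assignments
        if otu_ids is not None:
            sub = sub.loc[[o for o in otu_ids if o in sub.index]]
        return sorted(sub["phylum"].unique().tolist())

    def to_tsv(self, path: str | Path) -> None:
        self.assignments.rename_axis("otu_id").to_csv(path, sep="\t")


@dataclass
class StudySet:
    """The multi-site study container: one (community, taxonomy) pair per site."""

    sites: list[tuple[CommunityTable, TaxonomyTable]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.site_id for c, _ in self.sites]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError(f"duplicate site ids in study: {ids}")
        for community, taxonomy in self.sites:
            unknown = [o for o in community.otu_ids if o not in taxonomy]
            if unknown:
                from .errors import UnknownOTUError

                raise UnknownOTUError(
                    f"site {community.site_id!r}: OTUs missing from taxonomy: "
                    f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}"
                )

    def __iter__(self) -> Iterator[tuple[CommunityTable, TaxonomyTable]]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [c.site_id for c, _ in self.sites]


# --- readers -------------------------------------------------------------------

def _require_file(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise MissingFileError(f"no such file: {p}")
    return p


def read_abundance_table(
    path: str | Path, site_id: str, habitat: str
) -> CommunityTable:
    """Read an abundance table (TSV, or BIOM v1 JSON if the file ends in .biom).

    TSV dialect: header row of time labels, first column of OTU ids. Row and
    column order are preserved; counts are coerced to integers.
    """
    p = _require_file(path)
    if p.suffix.lower() == ".biom":
        return _read_biom_v1(p, site_id, habitat)
    df = pd.read_csv(p, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyTableError(f"{p}: abundance table has no data rows/columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        row, col = df.index[bad[0]], df.columns[bad[1]]
        raise NonNumericCellError(
            f"{p}: non-numeric cell {df.iloc[bad[0], bad[1]]!r} "
            f"at OTU {row!r}, time {col!r}"
        )
    counts = numeric.round().astype(np.int64)
    counts.index = counts.index.astype(str)
    return CommunityTable(site_id=site_id, habitat=habitat, counts=counts)


def _read_biom_v1(path: Path, site_id: str, habitat: str) -> CommunityTable:
    """Minimal BIOM v1 (JSON, sparse or dense) abundance reader."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otus = [str(r["id"]) for r in doc["rows"]]
        times = [str(c["id"]) for c in doc["columns"]]
        shape = doc["shape"]
        data = doc["data"]
        mtype = doc.get("matrix_type", "sparse")
    except (KeyError, TypeError) as exc:
        raise NonNumericCellError(f"{path}: malformed BIOM v1 document: {exc}") from exc
    if shape[0] == 0 or shape[1] == 0:
        raise EmptyTableError(f"{path}: BIOM table has empty shape {shape}")
    mat = np.zeros((shape[0], shape[1]), dtype=float)
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=float)
    else:
        for r, c, v in data:
            mat[int(r), int(c)] = v
    counts = pd.DataFrame(mat, index=otus, columns=times)
    return CommunityTable(site_id=site_id, habitat=habitat, counts=counts)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV with columns otu_id + the six ranks.

    Blank cells become the explicit ``unassigned`` token.
    """
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    cols = [str(c) for c in df.columns]
    if not cols or cols[0] != "otu_id":
        raise MissingColumnError(f"{p}: first column must be 'otu_id', got {cols[:1]}")
    if df.shape[0] == 0:
        raise EmptyTableError(f"{p}: taxonomy has no rows")
    df = df.set_index("otu_id")
    df.index = df.index.astype(str)
    return TaxonomyTable(assignments=df)


def subset_by_phylum(
    table: CommunityTable, taxonomy: TaxonomyTable, phylum: str
) -> CommunityTable:
    """Restrict a community to the OTUs of one phylum (time axis unchanged)."""
    known = taxonomy.phyla(table.otu_ids)
    if phylum not in known:
        raise PhylumNotFoundError(
            f"phylum {phylum!r} absent at site {table.site_id!r}; present: {known}"
        )
    keep = [o for o in table.otu_ids if taxonomy.phylum_of(o) == phylum]
    return CommunityTable(
        site_id=table.site_id, habitat=table.habitat, counts=table.counts.loc[keep]
    )
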