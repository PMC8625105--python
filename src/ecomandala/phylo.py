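"""Taxonomy-rank trees and effective phylogenetic distances.

Trees are built from taxonomic classifications, not gene sequences: each
OTU hangs from the chain root -> kingdom -> phylum -> class -> order ->
family -> genus -> tip, shared prefixes merge, and every edge has length
1.0 (a dimensionless rank step). Tips therefore sit at uniform depth 7,
and the patristic (branch-length-sum) distance between two tips whose
lineages agree on their first L ranks is 2 * (7 - L).

An ``unassigned`` cell becomes a placeholder node unique to its parent
lineage, so two OTUs unassigned at the same rank under different parents do
NOT merge; this keeps tip depth uniform and distances comparable across
sites with uneven annotation quality.

Community-level summary: the effective phylogenetic distance D is the MEAN
over unordered distinct tip pairs (deliberately not the conventional sum).
Per-phylum Dp averages the distances attributed to phylum p; the default
pair set is between-phylum (i in p, j not in p), with an ``all_others``
convention (ordered pairs i in p, j != i) available — under the latter the
phylum pair sets partition all ordered pairs, so the pair-count-weighted
mean of Dp equals D.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import RANKS, UNASSIGNED, TaxonomyTable
from .errors import NoPairsError, PhylumNotFoundError, UnknownOTUError

#: Tip depth of a taxonomy-rank tree: root->kingdom...genus->tip = 7 edges.
TIP_DEPTH = len(RANKS) + 1

PairSet = Literal["between", "all_others"]


@dataclass
class TaxTree:
    """Rooted taxonomy-rank tree with unit branch lengths; tips are OTUs.

    ``paths`` maps each tip to its resolved six-name lineage; node identity
    is the full path prefix (so equal deep names under different ancestors
    are distinct nodes, and placeholders are unique to their parent lineage).
    """

    tip_ids: list[str]
    paths: dict[str, tuple[str, ...]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def to_newick(self) -> str:
        """Newick string with branch length 1.0 on every edge."""
        root: dict = {}
        for otu in self.tip_ids:
            node = root
            for name in self.paths[otu]:
                node = node.setdefault(name, {})
            node[otu] = None  # tip marker

        def clean(label: str) -> str:
            for ch in " ,:;()[]'":
                label = label.replace(ch, "_")
            return label

        def render(name: str, children: dict | None) -> str:
            if children is None:
                return f"{clean(name)}:1.0"
            inner = ",".join(render(k, v) for k, v in children.items())
            return f"({inner}){clean(name)}:1.0"

        inner = ",".join(render(k, v) for k, v in root.items())
        return f"({inner})root;"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def build_taxonomy_tree(
    taxonomy: TaxonomyTable, otu_ids: Sequence[str]
) -> TaxTree:
    """Build the taxonomy-rank tree for the OTUs ever observed at a site."""
    tips = [str(o) for o in otu_ids]
    if len(set(tips)) != len(tips):
        from .errors import DuplicateIdError

        raise DuplicateIdError("duplicate otu_ids passed to build_taxonomy_tree")
    paths: dict[str, tuple[str, ...]] = {}
    for otu in tips:
        if otu not in taxonomy:
            raise UnknownOTUError(f"otu_id {otu!r} not present in taxonomy")
        lineage = taxonomy.lineage(otu)
        resolved: list[str] = []
        for rank, name in zip(RANKS, lineage):
            if name == UNASSIGNED:
                parent = resolved[-1] if resolved else "root"
                name = f"{rank}__unassigned__{parent}"
            resolved.append(name)
        paths[otu] = tuple(resolved)
    return TaxTree(tip_ids=tips, paths=paths)


@dataclass
class TipDistanceMatrix:
    """Symmetric matrix of patristic tip distances (zero diagonal)."""

    otu_ids: list[str]
    values: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.otu_ids, columns=self.otu_ids).rename_axis(
            "otu_id"
        ).to_csv(path, sep="\t", float_format="%.10g")


def tip_distance_matrix(tree: TaxTree) -> TipDistanceMatrix:
    """Patristic distances between every tip pair of a taxonomy-rank tree.

    For uniform-depth unit-length trees the branch-length sum along the
    unique i-j path is 2 * (TIP_DEPTH - L) with L the shared lineage prefix
    length; prefix identity is full-path identity, which is what the tree
    stores.
    """
    n = tree.n_tips
    if n < 2:
        raise NoPairsError(f"need >= 2 tips for a distance matrix, got {n}")
    # Cumulative integer coding: equal codes at rank r imply equal prefixes
    # through r, so the shared-prefix length is a sum of equality tests.
    prev = np.zeros(n, dtype=np.int64)
    shared = np.zeros((n, n), dtype=np.int64)
    for r in range(len(RANKS)):
        keys = {}
        codes = np.empty(n, dtype=np.int64)
        for i, otu in enumerate(tree.tip_ids):
            key = (int(prev[i]), tree.paths[otu][r])
            codes[i] = keys.setdefault(key, len(keys))
        shared += codes[:, None] == codes[None, :]
        prev = codes
    d = 2.0 * (TIP_DEPTH - shared)
    np.fill_diagonal(d, 0.0)
    return TipDistanceMatrix(otu_ids=list(tree.tip_ids), values=d)


def effective_distance(matrix: TipDistanceMatrix) -> float:
    """Effective community distance D: mean over unordered distinct pairs."""
    n = len(matrix.otu_ids)
    if n < 2:
        raise NoPairsError("no tip pairs to average")
    iu = np.triu_indices(n, k=1)
    return float(matrix.values[iu].mean())


def _phylum_members(
    matrix: TipDistanceMatrix, taxonomy: TaxonomyTable, phylum: str
) -> np.ndarray:
    member = np.array(
        [taxonomy.phylum_of(o) == phylum for o in matrix.otu_ids], dtype=bool
    )
    if not member.any():
        raise PhylumNotFoundError(
            f"phylum {phylum!r} has no OTU among the matrix tips"
        )
    return member


def phylum_distance(
    matrix: TipDistanceMatrix,
    taxonomy: TaxonomyTable,
    phylum: str,
    pair_set: PairSet = "between",
) -> float:
    """Per-phylum effective distance Dp.

    ``pair_set="between"`` (default) averages d(i, j) over i in phylum p and
    j outside p; ``"all_others"`` averages over ordered pairs (i in p,
    j != i), including same-phylum partners.
    """
    member = _phylum_members(matrix, taxonomy, phylum)
    n = len(matrix.otu_ids)
    if pair_set == "between":
        other = ~member
        if not other.any():
            raise NoPairsError(
                f"phylum {phylum!r} covers every tip; no between-phylum pairs"
            )
        block = matrix.values[np.ix_(member, other)]
        return float(block.mean())
    if pair_set != "all_others":
        raise ValueError(f"unknown pair_set {pair_set!r}")
    rows = matrix.values[member]
    mask = np.ones((int(member.sum()), n), dtype=bool)
    mask[np.arange(mask.shape[0]), np.where(member)[0]] = False
    if not mask.any():
        raise NoPairsError("no counterpart OTUs")
    return float(rows[mask].mean())


@dataclass
class DistanceSummary:
    """Community D plus per-phylum Dp with the pair counts used."""

    D: float
    per_phylum: dict[str, float]
    n_pairs: dict[str, int]
    pair_set: PairSet
    n_pairs_total: int = 0

    def to_tsv(self, path: str | Path, site_id: str = "") -> None:
        with open(path, "w") as fh:
            fh.write("site\tphylum\tdistance\tn_pairs\tpair_set\n")
            fh.write(
                f"{site_id}\t__community__\t{self.D:.10g}"
                f"\t{self.n_pairs_total}\t{self.pair_set}\n"
            )
            for ph in sorted(self.per_phylum):
                fh.write(
                    f"{site_id}\t{ph}\t{self.per_phylum[ph]:.10g}"
                    f"\t{self.n_pairs[ph]}\t{self.pair_set}\n"
                )


def distance_summary(
    matrix: TipDistanceMatrix,
    taxonomy: TaxonomyTable,
    pair_set: PairSet = "between",
) -> DistanceSummary:
    """D and Dp for every phylum present among the matrix tips."""
    D = effective_distance(matrix)
    per: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    n = len(matrix.otu_ids)
    for phylum in taxonomy.phyla(matrix.otu_ids):
        member = _phylum_members(matrix, taxonomy, phylum)
        k = int(member.sum())
        try:
            per[phylum] = phylum_distance(matrix, taxonomy, phylum, pair_set)
        except NoPairsError:
            continue
        n_pairs[phylum] = k * (n - k) if pair_set == "between" else k * (n - 1)
    return DistanceSummary(
        D=D, per_phylum=per, n_pairs=n_pairs, pair_set=pair_set,
        n_pairs_total=n * (n - 1) // 2,
    )
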