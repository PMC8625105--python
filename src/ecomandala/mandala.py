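"""Assembly of the Eco-Evo Mandala: (D, lambda, epsilon) per community/phylum.

Each community (or phylum) is reduced to three traits:

* D — effective phylogenetic distance (evolutionary axis; high = diverse),
* lambda — exponential rate of its pooled transfer-entropy distribution
  (functional axis; low = scale-free, organized interactions),
* epsilon — power-law exponent of its abundance distribution (structural
  axis; low = scale-free, organized structure).

Values are rescaled axis-wise to the maximum observed in the plotted set
(x / xmax, so the max maps to exactly 1), normalized to a unit-sum
barycentric triplet for ternary placement, and scored by their Euclidean
divergence in rescaled space from the theoretically optimal vertex
(D_s, lambda_s, epsilon_s) = (1, 0, 0): high diversity with scale-free
structure and interactions.

Taylor's nu is computed and carried for the pairwise association panels but
deliberately excluded from the Mandala axes (it encodes nearly the same
signal as epsilon).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig
from .core import CommunityTable, StudySet, TaxonomyTable, subset_by_phylum
from .errors import (
    AxisValueError,
    DegenerateTailError,
    EmptyTableError,
    IncalculableError,
    NoPairsError,
    SeriesLengthError,
    TooFewPointsError,
    TooFewTailPointsError,
    ZeroVarianceError,
)
from .interactions import pairwise_te
from .phylo import (
    build_taxonomy_tree,
    effective_distance,
    phylum_distance,
    tip_distance_matrix,
)
from .tails import fit_exponential, fit_powerlaw, taylor_exponent

import numpy as np

_FIT_ERRORS = (
    TooFewTailPointsError,
    DegenerateTailError,
    EmptyTableError,
    TooFewPointsError,
    ZeroVarianceError,
    SeriesLengthError,
    NoPairsError,
)

#: Optimal vertex in rescaled (D_s, lambda_s, epsilon_s) space.
OPTIMAL_VERTEX = (1.0, 0.0, 0.0)


def _abundance_values(community: CommunityTable, config: PipelineConfig) -> np.ndarray:
    """Abundance sample entering the epsilon fit (pooled or per-OTU means)."""
    if config.fits.abundance_pooling == "otu_means":
        means = community.values().mean(axis=1)
        return means[means > 0]
    counts = community.values()
    return counts[counts > 0].astype(float)


def rescale_axis(values) -> np.ndarray:
    """Divide a series of axis values by its maximum (max maps to 1).

    NaN entries are carried through (missing values stay missing); the
    maximum is taken over the finite entries, which must include at least
    one positive value.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise AxisValueError("no finite axis value to rescale")
    vmax = arr[finite].max()
    if vmax <= 0:
        raise AxisValueError(f"axis maximum must be positive, got {vmax}")
    return arr / vmax


def ternary_coordinates(d_s: float, lambda_s: float, epsilon_s: float
                        ) -> tuple[float, float, float]:
    """Barycentric triplet (sum 1) in fixed axis order (D, lambda, epsilon)."""
    comps = np.array([d_s, lambda_s, epsilon_s], dtype=float)
    if not np.isfinite(comps).all() or (comps < 0).any():
        raise AxisValueError(f"ternary components must be finite and >= 0: {comps}")
    total = comps.sum()
    if total == 0:
        raise AxisValueError("all-zero triplet has no ternary position")
    t = comps / total
    return (float(t[0]), float(t[1]), float(t[2]))


def optimality_divergence(d_s: float, lambda_s: float, epsilon_s: float) -> float:
    """Euclidean distance in rescaled space from the optimal vertex (1, 0, 0)."""
    return math.sqrt(
        (d_s - OPTIMAL_VERTEX[0]) ** 2
        + (lambda_s - OPTIMAL_VERTEX[1]) ** 2
        + (epsilon_s - OPTIMAL_VERTEX[2]) ** 2
    )


@dataclass
class MandalaPoint:
    """One community's (or phylum's) position on the Mandala."""

    site: str
    habitat: str
    phylum: str | None = None  # None => community-level point
    D_raw: float | None = None
    lambda_raw: float | None = None
    epsilon_raw: float | None = None
    nu: float | None = None
    D_s: float | None = None
    lambda_s: float | None = None
    epsilon_s: float | None = None
    ternary: tuple[float, float, float] | None = None
    divergence: float | None = None
    flags: list[str] = field(default_factory=list)
    #: fit provenance: quantity name ("abundance" | "te") -> TailFit
    fits: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.site if self.phylum is None else f"{self.site}:{self.phylum}"

    @property
    def complete(self) -> bool:
        return None not in (self.D_raw, self.lambda_raw, self.epsilon_raw)


@dataclass
class MandalaSet:
    """Points computed against a common per-axis maximum (recorded)."""

    points: list[MandalaPoint]
    axis_max: dict[str, float]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def complete_points(self) -> list[MandalaPoint]:
        return [p for p in self.points if p.ternary is not None]

    def to_tsv(self, path: str | Path) -> None:
        cols = (
            "scope\tsite\tphylum\thabitat\tD_raw\tlambda_raw\tepsilon_raw\tnu\t"
            "D_s\tlambda_s\tepsilon_s\ttern_D\ttern_lambda\ttern_epsilon\t"
            "divergence\tflags\n"
        )

        def fmt(v) -> str:
            return "NA" if v is None else f"{v:.10g}"

        with open(path, "w") as fh:
            fh.write(cols)
            for p in self.points:
                scope = "community" if p.phylum is None else "phylum"
                tern = p.ternary or (None, None, None)
                fh.write(
                    "\t".join(
                        [
                            scope, p.site, p.phylum or "NA", p.habitat,
                            fmt(p.D_raw), fmt(p.lambda_raw), fmt(p.epsilon_raw),
                            fmt(p.nu), fmt(p.D_s), fmt(p.lambda_s), fmt(p.epsilon_s),
                            fmt(tern[0]), fmt(tern[1]), fmt(tern[2]),
                            fmt(p.divergence), ";".join(p.flags) or "ok",
                        ]
                    )
                    + "\n"
                )

    def sidecar(self, seed: int | None = None, config_hash: str | None = None) -> dict:
        return {
            "axis_max": self.axis_max,
            "excluded": [list(e) for e in self.excluded],
            "seed": seed,
            "config_hash": config_hash,
        }

    def write_sidecar(self, path: str | Path, **kwargs) -> None:
        Path(path).write_text(json.dumps(self.sidecar(**kwargs), indent=2) + "\n")


def _community_traits(
    community: CommunityTable,
    taxonomy: TaxonomyTable,
    config: PipelineConfig,
) -> MandalaPoint:
    """Raw (D, lambda, epsilon, nu) for one community, with failure flags."""
    point = MandalaPoint(site=community.site_id, habitat=community.habitat)
    if community.t < 10:
        point.flags.append("short_series")
    pooled = _abundance_values(community, config)

    try:
        fit = fit_powerlaw(
            pooled,
            xmin_policy=config.fits.abundance_xmin_policy,
            n_min=config.fits.n_min,
        )
        point.epsilon_raw = fit.exponent
        point.fits["abundance"] = fit
    except _FIT_ERRORS:
        point.flags.append("missing_epsilon")

    try:
        te = pairwise_te(
            community,
            history=config.te.history,
            kernel_width=config.te.kernel_width,
        )
        fit = fit_exponential(
            te.pooled_values(),
            xmin_policy=config.fits.te_xmin_policy,
            n_min=config.fits.n_min,
        )
        point.lambda_raw = fit.exponent
        point.fits["te"] = fit
    except _FIT_ERRORS:
        point.flags.append("missing_lambda")

    try:
        tree = build_taxonomy_tree(taxonomy, community.otu_ids)
        point.D_raw = effective_distance(tip_distance_matrix(tree))
    except _FIT_ERRORS:
        point.flags.append("missing_D")

    try:
        point.nu = taylor_exponent(community).nu
    except _FIT_ERRORS:
        point.flags.append("missing_nu")
    return point


def finalize_set(
    points: list[MandalaPoint],
    excluded: list[tuple[str, str]] | None = None,
) -> MandalaSet:
    """Rescale axes over a point set, attach ternary coordinates and divergence.

    Points missing an axis keep what they have (e.g. D_s and epsilon_s with a
    ``missing_lambda`` flag) and get no ternary position; they are never
    silently dropped.
    """

    def axis(name: str) -> np.ndarray:
        return np.array(
            [getattr(p, name) if getattr(p, name) is not None else np.nan
             for p in points],
            dtype=float,
        )

    axis_max: dict[str, float] = {}
    scaled: dict[str, np.ndarray] = {}
    for raw_name, key in (("D_raw", "D"), ("lambda_raw", "lambda"),
                          ("epsilon_raw", "epsilon")):
        raw = axis(raw_name)
        if np.isfinite(raw).any():
            scaled[key] = rescale_axis(raw)
            axis_max[key] = float(np.nanmax(raw))
        else:
            scaled[key] = raw
            axis_max[key] = float("nan")
    for i, p in enumerate(points):
        d_s, l_s, e_s = scaled["D"][i], scaled["lambda"][i], scaled["epsilon"][i]
        p.D_s = None if np.isnan(d_s) else float(d_s)
        p.lambda_s = None if np.isnan(l_s) else float(l_s)
        p.epsilon_s = None if np.isnan(e_s) else float(e_s)
        if p.complete:
            p.ternary = ternary_coordinates(p.D_s, p.lambda_s, p.epsilon_s)
            p.divergence = optimality_divergence(p.D_s, p.lambda_s, p.epsilon_s)
    return MandalaSet(points=points, axis_max=axis_max, excluded=excluded or [])


def community_mandala(
    study: StudySet, config: PipelineConfig | None = None
) -> MandalaSet:
    """Mandala over the communities of a multi-site study.

    Per site, epsilon comes from the pooled abundance power-law fit, lambda
    from the exponential fit of pooled pairwise transfer entropies, D from
    the taxonomy tree; axes are then rescaled across sites. Sites whose
    lambda fit refuses are flagged ``missing_lambda`` and carried without a
    ternary position.
    """
    if len(study) == 0:
        raise EmptyTableError("empty study: no sites")
    config = config or PipelineConfig()
    points = [_community_traits(c, tax, config) for c, tax in study]
    return finalize_set(points)


def phylum_mandala(
    community: CommunityTable,
    taxonomy: TaxonomyTable,
    config: PipelineConfig | None = None,
) -> MandalaSet:
    """Per-phylum Mandala for one site, plus the community-average point.

    Only phyla for which all three traits are calculable receive a ternary
    position; the others are listed in ``excluded`` with the reason (e.g. a
    single-OTU phylum has no interaction pairs, so lambda is not
    calculable).
    """
    config = config or PipelineConfig()
    excluded: list[tuple[str, str]] = []
    points: list[MandalaPoint] = []
    for phylum in taxonomy.phyla(community.otu_ids):
        sub = subset_by_phylum(community, taxonomy, phylum)
        point = MandalaPoint(
            site=community.site_id, habitat=community.habitat, phylum=phylum
        )
        pooled = _abundance_values(sub, config)
        try:
            fit = fit_powerlaw(
                pooled,
                xmin_policy=config.fits.abundance_xmin_policy,
                n_min=config.fits.n_min,
            )
            point.epsilon_raw = fit.exponent
            point.fits["abundance"] = fit
        except _FIT_ERRORS:
            point.flags.append("missing_epsilon")
        if sub.n_otu < 2:
            point.flags.append("missing_lambda:single_otu")
        else:
            try:
                te = pairwise_te(
                    sub, history=config.te.history,
                    kernel_width=config.te.kernel_width,
                )
                fit = fit_exponential(
                    te.pooled_values(),
                    xmin_policy=config.fits.te_xmin_policy,
                    n_min=config.fits.n_min,
                )
                point.lambda_raw = fit.exponent
                point.fits["te"] = fit
            except _FIT_ERRORS:
                point.flags.append("missing_lambda")
        try:
            tree = build_taxonomy_tree(taxonomy, community.otu_ids)
            point.D_raw = phylum_distance(
                tip_distance_matrix(tree), taxonomy, phylum,
                pair_set=config.phylo.pair_set,
            )
        except _FIT_ERRORS:
            point.flags.append("missing_D")
        try:
            point.nu = taylor_exponent(sub).nu
        except _FIT_ERRORS:
            point.flags.append("missing_nu")
        points.append(point)
        if not point.complete:
            excluded.append((phylum, ";".join(point.flags)))
    if not any(p.complete for p in points):
        raise IncalculableError(
            f"site {community.site_id!r}: no phylum has all three traits calculable"
        )
    points.append(_community_traits(community, taxonomy, config))
    return finalize_set(points, excluded=excluded)
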