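"""Mandala and pairwise-axis figures (headless, deterministic SVG output).

The ternary projection maps a barycentric triplet (a, b, c) in the fixed
axis order (D, lambda, epsilon) onto the plane spanned by the triangle
D = (0, 0), lambda = (1, 0), epsilon = (1/2, sqrt(3)/2); the Mandala is
read counter-clockwise starting from the D vertex. SVG output is made
byte-reproducible by fixing the hash salt and stripping the date metadata.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .mandala import MandalaSet

_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3.0) / 2.0]])
_AXIS_LABELS = ("D (genetic dissimilarity)", "λ (interactions)", "ε (abundance)")

_HABITAT_CYCLE = (
    "#1f77b4", "#2ca02c", "#d62728", "#9467bd", "#8c564b", "#e377c2", "#7f7f7f",
)


def _ternary_xy(triplet: tuple[float, float, float]) -> tuple[float, float]:
    p = np.asarray(triplet, dtype=float) @ _CORNERS
    return float(p[0]), float(p[1])


def _habitat_colors(habitats: list[str]) -> dict[str, str]:
    uniq = sorted(set(habitats))
    return {h: _HABITAT_CYCLE[i % len(_HABITAT_CYCLE)] for i, h in enumerate(uniq)}


def _deterministic_save(fig, path: str | Path) -> None:
    plt.rcParams["svg.hashsalt"] = "ecomandala"
    path = Path(path)
    if path.suffix.lower() == ".svg":
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)


def render_mandala(mset: MandalaSet, path: str | Path, title: str = "Eco-Evo Mandala") -> None:
    """Render the ternary Mandala of every complete point in the set."""
    points = mset.complete_points()
    if not points:
        raise ValueError("no complete points to render")
    fig, ax = plt.subplots(figsize=(6.0, 5.5))
    tri = np.vstack([_CORNERS, _CORNERS[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1.0)
    for frac in (0.25, 0.5, 0.75):  # light ternary grid
        for a, b in ((0, 1), (1, 2), (2, 0)):
            p1 = _CORNERS[a] * (1 - frac) + _CORNERS[b] * frac
            p2 = _CORNERS[a] * (1 - frac) + _CORNERS[3 - a - b] * frac
            ax.plot([p1[0], p2[0]], [p1[1], p2[1]], color="0.85", lw=0.5, zorder=0)
    offsets = [(-0.04, -0.04), (0.04, -0.04), (0.0, 0.05)]
    for corner, label, off in zip(_CORNERS, _AXIS_LABELS, offsets):
        ax.text(corner[0] + off[0], corner[1] + off[1], label,
                ha="center", va="center", fontsize=9)
    colors = _habitat_colors([p.habitat for p in points])
    seen: set[str] = set()
    for p in sorted(points, key=lambda q: q.label):
        x, y = _ternary_xy(p.ternary)
        ax.scatter(
            [x], [y], s=60 if p.phylum is None else 30,
            color=colors[p.habitat], edgecolor="black", linewidth=0.5,
            label=p.habitat if p.habitat not in seen else None, zorder=3,
        )
        seen.add(p.habitat)
        ax.annotate(p.label, (x, y), textcoords="offset points",
                    xytext=(4, 4), fontsize=6)
    ax.legend(loc="upper right", fontsize=7, frameon=False)
    ax.set_title(title, fontsize=11)
    ax.set_aspect("equal")
    ax.axis("off")
    _deterministic_save(fig, path)


def render_pairwise(
    mset: MandalaSet,
    path: str | Path,
    taylor: dict[str, float] | None = None,
) -> None:
    """Pairwise raw-axis panels (D-lambda, D-epsilon, epsilon-lambda) and,
    when Taylor exponents are supplied or present on the points, a
    nu-epsilon-lambda association panel."""
    points = [p for p in mset.points]
    if not points:
        raise ValueError("no points to render")
    nu = {p.label: (taylor or {}).get(p.label, p.nu) for p in points}
    have_nu = any(v is not None for v in nu.values())
    ncols = 4 if have_nu else 3
    fig, axes = plt.subplots(1, ncols, figsize=(3.2 * ncols, 3.2))
    colors = _habitat_colors([p.habitat for p in points])
    panels = [("D_raw", "lambda_raw", "D", "λ"),
              ("D_raw", "epsilon_raw", "D", "ε"),
              ("epsilon_raw", "lambda_raw", "ε", "λ")]
    for ax, (fx, fy, lx, ly) in zip(axes, panels):
        for p in sorted(points, key=lambda q: q.label):
            x, y = getattr(p, fx), getattr(p, fy)
            if x is None or y is None:
                continue
            ax.scatter([x], [y], color=colors[p.habitat], s=25,
                       edgecolor="black", linewidth=0.4)
        ax.set_xlabel(lx, fontsize=9)
        ax.set_ylabel(ly, fontsize=9)
    if have_nu:
        ax = axes[-1]
        for p in sorted(points, key=lambda q: q.label):
            v = nu[p.label]
            if v is None or p.epsilon_raw is None:
                continue
            ax.scatter([p.epsilon_raw], [v], color=colors[p.habitat], s=25,
                       marker="o", edgecolor="black", linewidth=0.4)
            if p.lambda_raw is not None:
                ax.scatter([p.lambda_raw], [v], color=colors[p.habitat], s=25,
                           marker="^", edgecolor="black", linewidth=0.4)
        ax.set_xlabel("ε (circles) / λ (triangles)", fontsize=9)
        ax.set_ylabel("ν", fontsize=9)
    fig.tight_layout()
    _deterministic_save(fig, path)


def render_composition(community, path: str | Path, taxonomy=None) -> None:
    """Stacked relative-abundance time series of a community (by phylum if a
    taxonomy is given, else by OTU)."""
    rel = community.relative_abundance()
    if taxonomy is not None:
        rel = rel.groupby(
            [taxonomy.phylum_of(o) for o in community.otu_ids]
        ).sum()
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.stackplot(range(rel.shape[1]), rel.to_numpy(), labels=list(rel.index))
    ax.set_xlabel("time point")
    ax.set_ylabel("relative abundance")
    ax.set_title(community.site_id)
    if rel.shape[0] <= 12:
        ax.legend(fontsize=6, ncol=2, frameon=False)
    _deterministic_save(fig, path)
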