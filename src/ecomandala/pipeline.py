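"""End-to-end pipeline: inputs -> TE -> tail fits -> distances -> Mandala.

``run_pipeline`` wires the stages together and writes the full artifact
bundle (TE edge lists, fit report, distance summaries, Mandala TSV/JSON,
optional figures) plus a run manifest that suffices to reproduce the run:
config echo, config hash, seed and package version, with per-site flags.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import RunConfig, config_hash, config_to_dict
from .core import CommunityTable, StudySet, TaxonomyTable, read_abundance_table, read_taxonomy
from .errors import ConfigError, EcoMandalaError, IncalculableError
from .interactions import pairwise_te
from .mandala import MandalaSet, community_mandala, phylum_mandala
from .phylo import build_taxonomy_tree, distance_summary, tip_distance_matrix
from .synth import SynthConfig, generate_study
from .tails import select_family

logger = logging.getLogger("ecomandala")


def _load_study(config: RunConfig) -> tuple[StudySet, dict | None]:
    if config.synth is not None:
        synth_cfg = SynthConfig(**{"seed": config.seed, **config.synth})
        return generate_study(synth_cfg)
    if not config.sites:
        raise ConfigError("config needs either a 'sites' list or a 'synth' block")
    pairs = []
    shared = read_taxonomy(config.taxonomy) if config.taxonomy else None
    for site in config.sites:
        community = read_abundance_table(site.abundance, site.site_id, site.habitat)
        taxonomy = read_taxonomy(site.taxonomy) if site.taxonomy else shared
        if taxonomy is None:
            raise ConfigError(f"site {site.site_id!r}: no taxonomy given")
        pairs.append((community, taxonomy))
    return StudySet(sites=pairs), None


def _write_fit_report(path: Path, mset: MandalaSet, phylum_sets: dict[str, MandalaSet]) -> None:
    """TSV of every tail fit with full provenance (xmin, n_tail, ks, loglik)."""
    rows = [
        "scope\tsite\tphylum\tquantity\tfamily\texponent\txmin\tn_tail\tks\tloglik\tflags"
    ]

    def emit(scope: str, p) -> None:
        ph = p.phylum or "NA"
        flags = ";".join(p.flags) or "ok"
        for quantity in ("abundance", "te"):
            fit = p.fits.get(quantity)
            if fit is None:
                continue
            rows.append(
                f"{scope}\t{p.site}\t{ph}\t{quantity}\t{fit.family}"
                f"\t{fit.exponent:.10g}\t{fit.xmin:.10g}\t{fit.n_tail}"
                f"\t{fit.ks:.6g}\t{fit.loglik:.10g}\t{flags}"
            )
        if p.nu is not None:
            rows.append(
                f"{scope}\t{p.site}\t{ph}\ttaylor\tlinear\t{p.nu:.10g}"
                f"\tNA\tNA\tNA\tNA\t{flags}"
            )

    for p in mset.points:
        emit("community", p)
    for mset_ph in phylum_sets.values():
        for p in mset_ph.points:
            if p.phylum is not None:
                emit("phylum", p)
    path.write_text("\n".join(rows) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the output bundle under config.out_dir.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    study, truth = _load_study(config)
    if truth is not None:
        (out / "synthetic_truth.json").write_text(json.dumps(truth, indent=2))
        for community, taxonomy in study:
            community.to_tsv(out / f"abundance_{community.site_id}.tsv")
        study.sites[0][1].to_tsv(out / "taxonomy.tsv")

    site_flags: dict[str, list[str]] = {}
    # per-site artifacts
    for community, taxonomy in study:
        sid = community.site_id
        logger.info("site %s: %d OTUs, t = %d", sid, community.n_otu, community.t)
        te = pairwise_te(community, history=config.te.history,
                         kernel_width=config.te.kernel_width)
        te.to_edgelist_tsv(out / f"te_edges_{sid}.tsv")
        tree = build_taxonomy_tree(taxonomy, community.otu_ids)
        tree.write_newick(out / f"tree_{sid}.nwk")
        if community.n_otu >= 2:
            matrix = tip_distance_matrix(tree)
            distance_summary(matrix, taxonomy, config.phylo.pair_set).to_tsv(
                out / f"distances_{sid}.tsv", site_id=sid
            )
        sel = select_family(te.pooled_values(), n_min=config.fits.n_min,
                            threshold=config.fits.family_threshold)
        logger.info("site %s: TE family verdict %s (Δloglik=%.2f)",
                    sid, sel.verdict, sel.delta_loglik)

    mset = community_mandala(study, config)
    mset.to_tsv(out / "mandala_communities.tsv")
    mset.write_sidecar(out / "mandala_communities.json", seed=config.seed,
                       config_hash=config_hash(config))
    for p in mset.points:
        site_flags[p.site] = list(p.flags)

    phylum_sets: dict[str, MandalaSet] = {}
    for community, taxonomy in study:
        try:
            pset = phylum_mandala(community, taxonomy, config)
        except IncalculableError as exc:
            logger.warning("phylum mandala skipped: %s", exc)
            site_flags[community.site_id].append("phylum_mandala_incalculable")
            continue
        phylum_sets[community.site_id] = pset
        pset.to_tsv(out / f"mandala_phyla_{community.site_id}.tsv")
        pset.write_sidecar(out / f"mandala_phyla_{community.site_id}.json",
                           seed=config.seed, config_hash=config_hash(config))

    _write_fit_report(out / "fit_report.tsv", mset, phylum_sets)

    if config.figures:
        from .plotting import render_mandala, render_pairwise

        if mset.complete_points():
            render_mandala(mset, out / "mandala_communities.svg")
        render_pairwise(mset, out / "pairwise_axes.svg")
        for sid, pset in phylum_sets.items():
            if pset.complete_points():
                render_mandala(pset, out / f"mandala_phyla_{sid}.svg",
                               title=f"Phylum Mandala — {sid}")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "config_hash": config_hash(config),
        "sites": {
            c.site_id: {"n_otu": c.n_otu, "t": c.t, "habitat": c.habitat,
                        "flags": site_flags.get(c.site_id, [])}
            for c, _ in study
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
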