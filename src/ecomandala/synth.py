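"""Synthetic multi-site microbial community generator with known ground truth.

Emulates the shape of a multi-site bacterioplankton monitoring study (seven
sites in four habitat classes, monthly series of length 3-17, raw integer
read counts, a shared taxonomy) while controlling the quantities every
pipeline stage estimates:

* mean abundances follow a Pareto law with density exponent ``epsilon_true``;
* per-time counts carry multiplicative log-normal noise tuned so that
  Var(X_i) ~ noise_cv^2 * mean_i^nu_true (Taylor coupling);
* a random directed coupling graph imposes lag-1 dependence between OTU
  series (linear influence on the latent Gaussian innovations, with an
  optional saturating nonlinearity), whose edges are returned as ground
  truth for transfer-entropy validation; per-edge strengths are drawn from
  an exponential law whose rate ``lambda_scale`` shapes the interaction-
  strength distribution.

Everything is driven by a single mandatory seed through spawned NumPy
generators: no global random state, fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import RANKS, UNASSIGNED, CommunityTable, StudySet, TaxonomyTable
from .errors import ConfigError


@dataclass(frozen=True)
class Archetype:
    """Generating parameters of one habitat class."""

    epsilon_true: float
    nu_true: float
    coupling_density: float
    coupling_strength: float
    lambda_scale: float

    def __post_init__(self) -> None:
        if self.epsilon_true <= 1:
            raise ConfigError(f"epsilon_true must be > 1, got {self.epsilon_true}")
        if not (1.0 <= self.nu_true <= 2.0):
            raise ConfigError(f"nu_true must lie in [1, 2], got {self.nu_true}")
        if not (0.0 <= self.coupling_density <= 1.0):
            raise ConfigError("coupling_density must lie in [0, 1]")
        if self.coupling_strength < 0:
            raise ConfigError("coupling_strength must be >= 0")
        if self.lambda_scale <= 0:
            raise ConfigError("lambda_scale must be > 0")


def default_archetypes() -> dict[str, Archetype]:
    """Four habitat classes with trait orderings matching the study system:

    the riverine habitat is the most organized (lowest epsilon, strongest /
    heaviest-tailed interactions), estuarine inshore reefs are structurally
    organized but functionally noisy, and open marine habitats show the
    weakest structural organization.
    """
    return {
        "estuarine-inshore-reef": Archetype(1.9, 1.6, 0.08, 0.3, 10.0),
        "lagoon": Archetype(2.35, 1.55, 0.08, 0.35, 9.0),
        "marine-inshore-reef": Archetype(2.6, 1.5, 0.10, 0.5, 5.0),
        "riverine": Archetype(1.74, 1.7, 0.15, 0.8, 2.4),
    }


@dataclass
class SynthConfig:
    """Study-level generator configuration (defaults emulate the 7-site design)."""

    seed: int
    n_sites: int = 7
    habitat_archetypes: Mapping[str, Archetype] = field(default_factory=default_archetypes)
    site_ids: Sequence[str] = ("TT1", "TT2", "TT3", "TT4", "FI", "RI", "TR")
    site_habitats: Sequence[str] = (
        "estuarine-inshore-reef", "estuarine-inshore-reef", "estuarine-inshore-reef",
        "lagoon", "marine-inshore-reef", "marine-inshore-reef", "riverine",
    )
    n_otus: Sequence[int] = (150, 150, 150, 140, 130, 120, 60)
    t: Sequence[int] = (15, 17, 17, 15, 10, 9, 3)
    n_phyla: int = 20
    master_pool: int = 400
    noise_cv: float = 1.0
    mean_cutoff: float = 3.0  # Pareto xmin of the mean-abundance law
    mean_max: float = 1.0e6  # truncation: no OTU mean exceeds this read count
    p_unassigned: float = 0.05
    saturating: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_sites < 1:
            raise ConfigError(f"n_sites must be >= 1, got {self.n_sites}")
        for name in ("site_ids", "site_habitats", "n_otus", "t"):
            seq = getattr(self, name)
            if len(seq) != self.n_sites:
                raise ConfigError(
                    f"{name} has length {len(seq)}, expected n_sites={self.n_sites}"
                )
        for habitat in self.site_habitats:
            if habitat not in self.habitat_archetypes:
                raise ConfigError(f"no archetype defined for habitat {habitat!r}")
        if any(tt < 3 for tt in self.t):
            raise ConfigError("every site needs t >= 3")
        if any(n < 2 for n in self.n_otus):
            raise ConfigError("every site needs n_otus >= 2")
        if self.n_phyla < 1:
            raise ConfigError("n_phyla must be >= 1")
        if self.master_pool < max(self.n_otus):
            raise ConfigError("master_pool must be >= the largest site n_otus")
        if self.noise_cv <= 0:
            raise ConfigError("noise_cv must be > 0")


def generate_taxonomy(
    n_otus: int,
    n_phyla: int,
    seed: int | np.random.Generator,
    p_unassigned: float = 0.0,
) -> TaxonomyTable:
    """Random taxonomy with a heavy-tailed phylum-size distribution.

    Phylum sizes follow Zipf-like weights; lower ranks form a random nested
    hierarchy with 1-3 children per node. Every one of the ``n_phyla``
    phylum labels occurs at least once (requires n_phyla <= n_otus). With
    probability ``p_unassigned`` the genus cell is the explicit
    ``unassigned`` token.
    """
    if n_phyla < 1 or n_otus < 1:
        raise ConfigError(f"invalid sizes: n_otus={n_otus}, n_phyla={n_phyla}")
    if n_phyla > n_otus:
        raise ConfigError(f"n_phyla={n_phyla} exceeds n_otus={n_otus}")
    rng = np.random.default_rng(seed)
    phyla = [f"Phylum_{k + 1:02d}" for k in range(n_phyla)]
    kingdoms = {
        ph: ("Archaea" if k < max(1, n_phyla // 8) and n_phyla > 2 else "Bacteria")
        for k, ph in enumerate(phyla)
    }
    weights = 1.0 / np.arange(1, n_phyla + 1) ** 1.2
    weights /= weights.sum()
    assignment = list(phyla)  # guarantee every phylum appears
    if n_otus > n_phyla:
        assignment += list(rng.choice(phyla, size=n_otus - n_phyla, p=weights))
    # random nested hierarchy: number of children per parent drawn once
    n_children: dict[str, int] = {}

    def child(parent: str, rank: str) -> str:
        if parent not in n_children:
            n_children[parent] = int(rng.integers(1, 4))
        k = int(rng.integers(n_children[parent]))
        return f"{parent}|{rank[0]}{k + 1}"

    rows = []
    for i, phylum in enumerate(assignment):
        cls = child(phylum, "class")
        order = child(cls, "order")
        fam = child(order, "family")
        genus = child(fam, "genus")
        if p_unassigned > 0 and rng.random() < p_unassigned:
            genus = UNASSIGNED
        rows.append(
            {
                "kingdom": kingdoms[phylum],
                "phylum": phylum,
                "class": cls,
                "order": order,
                "family": fam,
                "genus": genus,
            }
        )
    index = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    df = pd.DataFrame(rows, index=index, columns=list(RANKS))
    return TaxonomyTable(assignments=df)


@dataclass
class CommunityTruth:
    """Ground truth recorded for one generated community."""

    site_id: str
    habitat: str
    archetype: Archetype
    means: np.ndarray
    edges: list[tuple[str, str, float]]  # (source, target, strength)
    mean_cutoff: float

    def as_json(self) -> dict:
        from dataclasses import asdict

        return {
            "site_id": self.site_id,
            "habitat": self.habitat,
            "archetype": asdict(self.archetype),
            "means": [float(m) for m in self.means],
            "edges": [[s, t, float(w)] for s, t, w in self.edges],
            "mean_cutoff": self.mean_cutoff,
        }


def _spectral_radius(w: np.ndarray, rng: np.random.Generator,
                     n_iter: int = 100) -> float:
    """Largest singular value by power iteration on w^T w: an upper bound on
    the spectral radius, so clipping against it guarantees stability."""
    v = rng.standard_normal(w.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        v = w.T @ (w @ v)
        norm = np.linalg.norm(v)
        if norm == 0:
            return 0.0
        v /= norm
    return float(np.sqrt(norm))


def _pareto_means(rng: np.random.Generator, n: int, epsilon: float,
                  cutoff: float) -> np.ndarray:
    """Means from the density f(m) ~ m^-epsilon above ``cutoff`` (inverse CDF)."""
    u = rng.random(n)
    return cutoff * (1.0 - u) ** (-1.0 / (epsilon - 1.0))


def generate_community(
    config: SynthConfig,
    site_index: int,
    taxonomy: TaxonomyTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CommunityTable, CommunityTruth]:
    """Generate one site's abundance table plus its ground-truth bundle.

    The latent log-abundance innovations are standard Gaussian; a directed
    coupling edge (i -> j) with strength rho mixes source innovation at
    time t-1 into target innovation at time t (variance-preserving), which
    is what the transfer-entropy stage is meant to detect. Counts are
    ``round(mean * exp(sigma z - sigma^2/2))`` floored at zero.
    """
    if not (0 <= site_index < config.n_sites):
        raise ConfigError(f"site_index {site_index} out of range")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(config.n_sites + 1)[site_index + 1]
        )
    site_id = str(config.site_ids[site_index])
    habitat = str(config.site_habitats[site_index])
    arch = config.habitat_archetypes[habitat]
    n = int(config.n_otus[site_index])
    t = int(config.t[site_index])
    if taxonomy is None:
        taxonomy = generate_taxonomy(
            config.master_pool, config.n_phyla, rng, config.p_unassigned
        )
    otus = sorted(rng.choice(taxonomy.otu_ids, size=n, replace=False).tolist())

    means = np.minimum(
        _pareto_means(rng, n, arch.epsilon_true, config.mean_cutoff), config.mean_max
    )
    # sigma per OTU so that Var ~ noise_cv^2 * mean^nu for the lognormal factor
    sigma2 = np.log1p(config.noise_cv**2 * means ** (arch.nu_true - 2.0))
    sigma = np.sqrt(sigma2)

    # directed coupling graph (no self loops)
    adj = rng.random((n, n)) < arch.coupling_density
    np.fill_diagonal(adj, False)
    strengths = np.zeros((n, n))
    n_edges = int(adj.sum())
    if n_edges and arch.coupling_strength > 0:
        raw = rng.exponential(scale=1.0 / arch.lambda_scale, size=n_edges)
        signs = rng.choice([-1.0, 1.0], size=n_edges)  # competitive or cooperative
        strengths[adj] = signs * np.clip(arch.coupling_strength * raw, 0.0, 0.95)

    eps_innov = rng.standard_normal((n, t))
    z = np.empty((n, t))
    z[:, 0] = eps_innov[:, 0]
    # incoming mixing weights per target, rescaled if total variance > 0.9
    w = strengths.T.copy()  # w[j, i] = signed strength of edge i -> j
    var_in = (w**2).sum(axis=1)
    over = var_in > 0.9
    if over.any():
        w[over] *= np.sqrt(0.9 / var_in[over])[:, None]
        var_in[over] = 0.9
    # guarantee a stable latent recursion: clip the spectral radius of w
    if n_edges:
        radius = _spectral_radius(w, rng)
        if radius > 0.95:
            w *= 0.95 / radius
            var_in = (w**2).sum(axis=1)
    own = np.sqrt(1.0 - var_in)
    for step in range(1, t):
        drive = z[:, step - 1]
        if config.saturating:
            drive = np.tanh(drive)
        z[:, step] = w @ drive + own * eps_innov[:, step]

    x = means[:, None] * np.exp(sigma[:, None] * z - sigma2[:, None] / 2.0)
    counts = np.maximum(np.rint(x), 0.0).astype(np.int64)
    frame = pd.DataFrame(
        counts, index=otus, columns=[f"t{k + 1:02d}" for k in range(t)]
    )
    community = CommunityTable(site_id=site_id, habitat=habitat, counts=frame)
    edges = [
        (otus[i], otus[j], float(strengths[i, j]))
        for i, j in zip(*np.nonzero(strengths != 0))
    ]
    truth = CommunityTruth(
        site_id=site_id, habitat=habitat, archetype=arch, means=means,
        edges=edges, mean_cutoff=config.mean_cutoff,
    )
    return community, truth


def generate_study(config: SynthConfig) -> tuple[StudySet, dict]:
    """Generate the full multi-site study plus a JSON-serializable truth bundle.

    All sites share one master taxonomy; each site's community is a random
    subset of the master OTU pool, so communities overlap the way repeated
    surveys of one region do.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_sites + 1)
    master_rng = np.random.default_rng(streams[0])
    taxonomy = generate_taxonomy(
        config.master_pool, config.n_phyla, master_rng, config.p_unassigned
    )
    pairs: list[tuple[CommunityTable, TaxonomyTable]] = []
    truths: dict[str, dict] = {}
    for k in range(config.n_sites):
        rng = np.random.default_rng(streams[k + 1])
        community, truth = generate_community(config, k, taxonomy=taxonomy, rng=rng)
        pairs.append((community, taxonomy))
        truths[community.site_id] = truth.as_json()
    bundle = {
        "seed": config.seed,
        "n_sites": config.n_sites,
        "noise_cv": config.noise_cv,
        "mean_cutoff": config.mean_cutoff,
        "sites": truths,
    }
    return StudySet(sites=pairs), bundle


def two_archetype_config(seed: int) -> SynthConfig:
    """The seeded 7-site validation study with two well-separated archetypes.

    A sheltered, organized archetype (low epsilon, strong heavy-tailed
    coupling) against an exposed, disorganized one (high epsilon, weak
    coupling); four and three sites respectively, 60 OTUs per site, t = 15.
    Used to check that between-archetype Mandala distances exceed
    within-archetype distances.
    """
    archetypes = {
        "sheltered": Archetype(1.8, 1.7, 0.12, 0.7, 2.5),
        "exposed": Archetype(2.7, 1.5, 0.08, 0.2, 8.0),
    }
    return SynthConfig(
        seed=seed,
        n_sites=7,
        habitat_archetypes=archetypes,
        site_ids=tuple(f"S{k + 1}" for k in range(7)),
        site_habitats=("sheltered",) * 4 + ("exposed",) * 3,
        n_otus=(60,) * 7,
        t=(15,) * 7,
        n_phyla=12,
        master_pool=200,
    )
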