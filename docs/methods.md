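# Methods

This note documents the models, estimators, conventions and design choices
implemented in `ecomandala`, and what the synthetic-data validation does and
does not establish about real data.

## Problem setting

The package condenses a multi-site microbial (bacterioplankton) monitoring
study — per site, an OTU × time matrix of raw sequence-read counts and an
OTU taxonomy (kingdom…genus) — into three community-level traits:

* **ε** (structure): the power-law density exponent of the abundance
  distribution. A scale-free (Zipfian) abundance spectrum, with low ε, is
  read as a signature of self-organized, well-balanced community structure.
* **λ** (function): the exponential rate of the distribution of pairwise
  transfer-entropy (TE) values. Low λ means a heavy, slowly decaying tail of
  interaction strengths — an organized, scale-free interaction network.
* **D** (evolution): the effective phylogenetic distance, the mean patristic
  distance between tips of a taxonomy-rank tree. High D means a genetically
  dissimilar, functionally redundant community.

Communities (or phyla, using the phylum-restricted versions of all three)
are placed on a ternary "Mandala"; their Euclidean distance in rescaled
trait space from the theoretically optimal vertex — high D, low λ, low ε —
is reported as a divergence-from-optimality score. Taylor's-law ν is
computed and reported alongside, but deliberately excluded from the Mandala
axes because it encodes nearly the same signal as ε.

All analyses use raw read counts, never relative abundances (a
relative-abundance helper exists for plotting only). Time labels are opaque
and ordered; only order matters to the lag-1 estimators.

## Transfer entropy (interactions module)

For source X and target Y with history length 1,

    TE(X→Y) = Σ p(y_t, y_{t−1}, x_{t−1}) log2 [ p(y_t | y_{t−1}, x_{t−1}) / p(y_t | y_{t−1}) ]

estimated by a plug-in box-kernel (Heaviside kernel, max-norm) estimator:
each series is z-normalized (sample sd, so the kernel radius is in sd
units), the t−1 embedded observations are formed, and each probability is
the fraction of embedded observations within the kernel radius of the query
point in the relevant 1-/2-/3-dimensional space. Defaults: history 1,
radius 0.5 normalized units, log base 2 (bits).

Conventions chosen for bit-reproducibility and honesty:

* points at distance exactly the radius count as inside (closed ball);
* counts include the query point, so no logarithm is ever undefined;
* TE involving a zero-variance series is exactly 0 (a constant series
  carries no information);
* raw estimates may be slightly negative (finite-sample noise) and are
  returned as-is; they are floored at 0 only when pooled for tail fitting;
* no Theiler window or dynamic-correlation exclusion: the intended inputs
  are short monthly samples;
* the estimator is fully deterministic.

The permutation-surrogate helper (TE after randomly permuting the source)
provides the null distribution used in validation; no significance
filtering is applied before λ fitting — all positive pooled TE values enter
the fit. This is an interpretation choice: the alternative (fitting only
surrogate-significant edges) would change λ's meaning from "rate of the
interaction-strength distribution" to "rate of the detected-interaction
distribution".

Known bias: the plug-in estimator is positively biased for continuous data
at short t; the bias shrinks with t (tested) but at t ≤ 17 the TE values
are dominated by it. λ comparisons across sites with similar t remain
meaningful; comparisons across very different t should be read cautiously.

## Tail fits (tails module)

The exceedance function P(Y ≥ y) of a positive sample is characterized by
one of two pure limiting families above a cutoff `xmin`:

* power law: density f(y) = ((ε−1)/xmin)(y/xmin)^(−ε), closed-form MLE
  ε̂ = 1 + n / Σ ln(y_i/xmin);
* shifted exponential: f(y) = λ e^(−λ(y−xmin)), MLE λ̂ = 1/(ȳ − xmin).

A hybrid (exponentially truncated power law) is *not* fitted by default:
each quantity is characterized by a single family, chosen by
`select_family`. `xmin` is either fixed (default: minimum positive value —
used for TE fits so λ stays comparable across sites) or chosen by scanning
observed values for the minimal Kolmogorov–Smirnov distance between fitted
and empirical tail (default for abundances, whose noisy head is not
power-law). Fits refuse (rather than return garbage) below `n_min = 8` tail
points; this operationalizes "not calculable" for small phyla and short
sites.

`select_family` fits the power law with a scanned xmin, re-fits the
exponential at that same xmin, and compares log-likelihoods on the common
tail; |Δ log L| < 2 natural-log units is inconclusive. One deliberate
deviation from plain KS scanning: for the *comparison* (not for exponent
estimation) the scan only considers cutoffs retaining at least half of the
positive sample. A likelihood contest on a tiny extreme tail discards most
of the evidence and routinely ends inconclusive even at n = 500; with the
half-sample floor the generating family is identified essentially always at
that size (validated in the acceptance suite).

Abundance ε is fitted, by default, to the pooled (OTU, time) observations;
a config switch (`fits.abundance_pooling: otu_means`) fits per-OTU time
means instead. Both are defensible readings of "the distribution of
abundances"; pooling uses all data and is the default. The continuous MLE
is used even for integer counts (they span orders of magnitude); a discrete
zeta-normalized MLE is available behind a flag.

Taylor's law ⟨x²⟩ ∼ ⟨x⟩^ν is fitted by OLS of log2(variance) on log2(mean),
one point per OTU, population (divide-by-n) variance, OTUs with zero mean
or variance excluded and counted. The population-variance convention is
stated so ν is bit-reproducible.

## Taxonomy trees and distances (phylo module)

Trees are built from taxonomic classifications, not sequences: root →
kingdom → … → genus → tip, shared prefixes merged, every edge length 1.0
(a dimensionless rank step — no meaningful branch lengths exist for
rank trees, so unit lengths are the declared convention). Tips sit at
uniform depth 7; `unassigned` cells become placeholder nodes unique to
their parent lineage, which keeps depth uniform so that a site with poorer
annotation does not get systematically shorter distances. Patristic
distances are therefore 2·(7 − L) for a shared lineage prefix of length L,
computed exactly (validated against brute-force path walks and against
dendropy on the exported newick).

D is the **mean** over unordered distinct tip pairs (deliberately not the
conventional sum, which scales with n²). Per-phylum Dp averages distances
from phylum members to counterparts. The definition "all other OTUs j"
admits two readings; the default is between-phylum pairs (i ∈ p, j ∉ p),
matching the interpretation of high-Dp phyla as unrelated *to other phyla*;
`phylo.pair_set: all_others` switches to ordered pairs (i ∈ p, j ≠ i),
under which phylum pair sets partition all ordered pairs and the
pair-count-weighted mean of Dp equals D exactly (tested).

## Mandala (mandala module)

Per axis, values are rescaled to the maximum of the plotted set (x/x_max,
so the maximum maps to exactly 1); maxima are recorded in the output so the
rescaling is auditable. The rescaling reference set is the plotted set
itself (all communities of a study; all phyla plus the community point of a
site). The constant-sum ternary triplet is obtained by normalizing the
rescaled triplet to unit sum, in fixed axis order (D, λ, ε) read
counter-clockwise; raw and rescaled values are preserved alongside, so the
projection loses no information. Axis polarity: D as-is (high = good), λ
and ε as-is (low = good); the optimal vertex in rescaled space is
(1, 0, 0) and the divergence score is the Euclidean distance to it.

Entities whose λ (or any axis) is not calculable are carried with explicit
flags, excluded from the ternary but retained in tabular output and
pairwise panels — never silently dropped. The phylum Mandala displays only
phyla with all three traits calculable, lists the rest with reasons, and
includes the community-average point.

## Synthetic communities (synth module)

The generator emulates the shape of the motivating study design — 7 sites
in 4 habitat classes, series lengths t ∈ {3, …, 17}, a shared master
taxonomy pool, integer read counts — with controlled ground truth:

* per-OTU mean abundances from a Pareto density with exponent
  `epsilon_true` above a cutoff of 3 reads (truncated at 10⁶ so counts fit
  machine integers);
* per-time counts `round(mean · exp(σ z − σ²/2))` with σ² = ln(1 +
  noise_cv²·mean^(ν−2)), giving Var ≈ noise_cv²·mean^ν (Taylor coupling);
* a random directed coupling graph (density, strength per archetype) whose
  signed per-edge weights (competitive or cooperative) are exponential with
  rate `lambda_scale`, injected as lag-1 mixing of latent Gaussian
  innovations; row variances are capped and the weight matrix's largest
  singular value is clipped below 1, so the latent recursion is stable by
  construction. The edge list is returned as ground truth for TE
  validation. A saturating (tanh) nonlinearity on the drive is optional.

Default archetype parameters (ε 1.74–2.6, ν 1.5–1.7, λ_scale 2.4–10) were
fixed once to mirror the qualitative habitat orderings of the motivating
system: the riverine habitat most organized, estuarine reefs structurally
organized but functionally noisy, open marine habitats least structurally
organized. Site richness defaults (60–150 OTUs) are representative
mid-range values for per-site free-living bacterioplankton OTU tables.
The two-archetype validation study (`two_archetype_config`) is 4 + 3 sites,
60 OTUs per site, t = 15, contrasting a sheltered/organized archetype
(ε = 1.8, strong heavy-tailed coupling) with an exposed/disorganized one
(ε = 2.7, weak coupling).

What passing synthetic tests shows — and does not. The generator produces
lognormal-noise, lag-1-coupled, stationary series with exact Pareto means.
Real read-count data add compositional constraints from sequencing depth,
overdispersed count noise, non-stationarity (seasonality), and coupling
through unobserved drivers; recovery of ε, ν and coupling direction here
validates the estimators' correctness, not their robustness to those
real-data features. The short-series regime (t = 3…17) is exercised for
robustness (runs complete, flags raised); recovery tests run at larger n
and t where the estimators' sampling error is small compared to the stated
tolerances.

## Numerical conventions and degenerate inputs

* z-normalization uses the sample (ddof = 1) standard deviation.
* Exceedance curves are over positive support; zeros are dropped before
  tail fitting, negative TE estimates floored at 0.
* KS-scan ties break toward the smaller xmin (larger tail).
* Constant series: TE = 0 by convention; constant tails: fits refuse with
  a named error.
* t = 3 is the minimum admissible series length (one embedded pair plus
  one); t < 10 raises a short-series warning.
* Every failure mode raises a distinct named exception
  (`ecomandala.errors`); the pipeline converts per-entity failures into
  flags, never silent drops.
* All randomness (generator only — the estimators are deterministic) flows
  through seeded NumPy generators spawned from a single mandatory seed.

## Validation problem sizes

The automated checks run at: n = 2000 samples for ε and λ recovery
(20 seeds), 200 OTUs × 100 time points for ν, 200 simulations at n = 500
for family selection, t = 1000 for the analytic one-bit TE copy process,
100 replicates at t = 200 (100 surrogates each) for the TE null and
directionality rates, up to 200 tips for distance-oracle agreement, and the
7-site two-archetype study for Mandala behavior.
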