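# Methods

## Scope and model

sonic4c analyses sonication-based 4C-seq libraries: one fixed bait locus,
genome-wide detection of its ligation partners.  The pipeline starts at
paired-end reads (or a pre-aligned end-tag table) and ends at enriched
interacting domains plus anchor-centric association statistics.  Wet-lab
steps, external alignment (BWA) and RNA-seq quantification are consumed as
inputs, not reimplemented.

Coordinates are 0-based half-open throughout (BED native); strand is
ignored in every analysis.  All randomized operations take an explicit
seed and are byte-reproducible.

## Junction calling

* End tags are the first 20 bp of each mate; pairs with a mate shorter
  than the tag length are dropped and counted.
* A pair survives filtering iff both tags are uniquely mapped **and** both
  have MAPQ strictly greater than 20.  "Uniquely mapped" uses the
  aligner's explicit flag when present.
* Bait membership means the tag *start* lies inside the bait interval;
  distances from a tag to the bait are measured start-to-nearest-boundary.
  With exactly one tag in the bait, the partner tag classifies the pair:
  different chromosome → inter-chromosomal junction; same chromosome
  > 10 kb from the bait → distal intra-chromosomal; > 300 bp → proximal
  junction (recorded, excluded from all downstream statistics); otherwise
  non-junction.  Both-in-bait (self-ligation) and neither-in-bait pairs
  are non-junctions.
* The 100-bp merge is single-linkage chaining of sorted distal tag
  positions (gap ≤ 100 bp joins), not fixed genomic bins: it matches the
  "one ligation event" semantics, is order-independent, and the number of
  sites is monotone non-increasing in the merge window.  The site position
  is the cluster median (rounded down) — robust to asymmetric PCR stacks —
  and the read count is the cluster size.  Single-read sites are removed
  as background noise.

## Domain calling

The background model treats interacting sites as uniform within each
chromosome.  For site *i* on chromosome *W* (length `L_W`, `N_W` sites),
`C` counts sites within a closed distance `l_w/2` of the site (the site
itself included; windows truncate at chromosome ends without rescaling):

* `z = (C − μ_w)/√μ_w` with `μ_w = N_W·l_w/L_W` — Poisson
  standardization, the default;
* `z = (C − μ_w)/√(μ_w(1 − l_w/L_W))` — binomial variance, behind
  `model="binomial"`.

Because windows are centred on an observed site, `E[C] = 1 + (N_W−1)l_w/L_W`
exceeds `μ_w` by `1 − l_w/L_W`; the permutation null shares this offset, so
the FDR is unaffected (the unit tests pin this property down).

The permutation FDR redraws site *positions* uniformly per chromosome
(preserving `N_W`) and recomputes z, rather than shuffling z labels —
label shuffling would leave the z multiset unchanged and make the
estimator degenerate.  With ≥ on both sides,

    FDR(z*) = [mean over permutations of #{null z ≥ z*}] / #{observed z ≥ z*},

clipped to [0, 1] and monotonized q-value-style (running minimum from the
top z down), so significance is a threshold on z.  Defaults: 2 Mb window,
100 permutations, FDR ≤ 0.05, ±1 Mb merge flank.  Each significant site
seeds a ±1 Mb interval; overlapping or book-ended seeds merge
transitively, and every site inside a merged seed (significant or not)
becomes a domain member.  Region-overlap counts between two domain lists
use Venn semantics: one connected component of the bipartite overlap graph
counts once.

## Concordance

Bin counts tile each chromosome (2 Mb bins, last bin truncated); the
replicate correlation is Pearson's r over all aligned bins including
zeros (a nonzero-only mode exists).  Zero-variance input yields NaN, never
a silent 0.  The relative distance of a query site between its two
flanking reference sites is `min(d_left, d_right)/(d_left + d_right)` ∈
[0, 0.5]; queries before the first or after the last reference on a
chromosome are skipped and counted.  Uniformity against Uniform(0, 0.5)
is a one-sample Kolmogorov–Smirnov test.

## Association analyses

Every test compares sites against matched shuffled sites drawn uniformly
with per-chromosome counts preserved — conditioning the null on the
chromosomal distribution removes chromosome-size confounding (a
genome-wide-uniform mode and an optional exclusion mask exist).  Anchor
windows truncate at chromosome ends without rescaling, so observed and
shuffled anchors face identical edge effects.

* **Peak enrichment** (±0.5 Mb default): Wilcoxon rank-sum, one-sided
  "greater" by default, exact null for tie-free samples under n = 50,
  normal approximation with tie correction otherwise; degenerate all-equal
  input returns p = 1.  One matched shuffle is the default comparison
  sample (a pooled multi-draw mode exists).
* **TF tag enrichment** (±1 kb): raw counts × (10⁷ / library size), minus
  the identically normalized input count when provided, floored at 0.
  Doubling every library and every raw count leaves normalized values
  unchanged.
* **Replication timing** (±50 kb): length-weighted mean of segment values
  over the window (equal to the exact integral of the piecewise-constant
  track divided by covered length; verified against a brute-force
  integrator).  The genome-wide baseline defaults to the *same window
  statistic at shuffled sites*: observed and baseline values are then
  exchangeable under the null, which keeps the rank-sum test calibrated —
  comparing means-of-several-segments against raw segment values would
  mix unequal variances.  A length-weighted raw-segment sample is
  available via `baseline="segments"`.  Segments with value > 0 are
  early-replicating.
* **Distance density**: signed distance to the nearest TSS/CpG anchor
  (0 inside an element, positive downstream, ties to the lower
  coordinate), clipped to ±1 Mb for display; fixed-bandwidth Gaussian
  kernel density (robust to zero-variance degenerate samples); peak
  "steepness" is operationalized as a one-sided rank-sum test of
  |distance|, observed smaller than random.
* **Expression**: genes overlapping each site, else the single nearest
  gene; the deduplicated set's FPKM against an equally sized uniform
  random gene draw, Welch's two-sample t-test (one-sided greater).
  Random genes are not matched for length or chromosome.

## The simulator

The generator defines the study conditions.  Defaults: a 3×10 Mb genome;
a 600-bp bait mid-chr1; 5 non-overlapping 50-kb hotspots of 20 sites each
over 1,000 background sites; every site ≥ 10 kb from the bait (all sites
are distal by construction).  Reads per site are 1 + Geometric(1/2)
(minimum 2, mean 3): the minimum of 2 guarantees every planted site can
clear the singleton filter, so the clean configuration is exactly
recoverable; the truth table additionally stores each site's *expected
surviving support* (emitted + duplicates − MAPQ-degraded) so noisy
configurations compare against detectable sites.  Junction tags jitter
uniformly within ±50 bp of their site, and planted sites keep a minimum
separation of 500 bp so jitter can never chain two sites into one 100-bp
cluster.  Noise pairs (10%) have both tags outside the bait or both
inside; duplicates (5%) are exact copies; a 5% MAPQ-degraded fraction
falls below the filter.  70% of background sites are placed within ±5 kb
of a random TSS, reflecting the promoter-proximal preference of enhancer
interactomes; the rest is uniform.

Feature tracks plant co-localization by multiplying placement density by
`track_enrichment` (default 10) within ±50 kb of true sites.  The ±50 kb
placement scale is deliberate: regulatory features cluster with their
elements at the tens-of-kb scale, and a placement zone as wide as the
±0.5 Mb *analysis* window would cover nearly the whole genome at realistic
site densities, leaving nothing to detect.  Densities mirror real
catalogues scaled to the synthetic genome: histone-mark peaks 3×10⁻⁵/bp,
DHS 10⁻⁴/bp, 5-hmC 2×10⁻⁵/bp (peak width 400 bp); ChIP tag libraries
5×10⁻³ tags/bp (a ~10-million-read library at mammalian genome scale) with
a uniform input library of the same depth.  Repressive-mark tracks
(H3K27me3, H3K9me3) ignore the sites.  Replication timing tiles the
genome in 40-kb segments with value ~ Normal(+1, 0.4) near sites and
Normal(0, 0.4) elsewhere.  Genes whose body ±10 kb touches a site are the
interacting set and draw FPKM from lognormal(meanlog 2.5, sdlog 1)
(median ≈ 12) versus lognormal(0, 1) (median 1) for the rest — a
realistic active-gene versus genome-pool contrast.  `null_config()`
switches every planted effect off (no hotspots, enrichment 1, flat
timing, equal FPKM, no TSS bias) and is the null for every downstream
test.

What the simulator does **not** model: sonication fragment-size
distributions, ligation biochemistry, sequencing errors, mappability or
repeat structure, assembly gaps, and enzyme-based 4C fragment logic.  It
generates data at the abstraction the pipeline consumes (end tags that
are genuine genomic substrings), so passing tests demonstrate the
pipeline's statistical and algorithmic correctness — not robustness to
alignment artifacts in real repetitive genomes.

## Study designs used by the tests and the acceptance script

* **Truth recovery**: default 1,100-site interactome, clean
  (noise/duplicates/degradation off) and noisy (20% noise, 10% degraded)
  configurations.
* **FDR calibration**: 200 (tests) / 100 (script) null simulations of
  1,100 uniform sites on the 30 Mb genome at the full-scale defaults
  (2 Mb window, 100 permutations, FDR ≤ 0.05).
* **Domain-recovery power**: 50/30 simulations of the default interactome
  with a window scaled to the genome — 100 kb with a 50 kb merge flank,
  preserving both the expected sites-per-window of the full-genome
  setting (μ ≈ 3–4) and the flank:window ratio.  A 2 Mb window on a 30 Mb
  chromosome would hold μ ≈ 74 expected sites, burying a 20-site hotspot
  at z ≈ 1.4; window scaling is part of the scaled study design, while
  2 Mb remains the package default for full-size genomes.
* **Association study**: a 3×30 Mb genome with 180 background sites and
  1,800 genes — the same densities (2 sites/Mb, 20 genes/Mb) on a genome
  wide enough to hold ~90 quasi-independent ±0.5 Mb anchor windows.  On
  30 Mb the ~30 available windows cap the achievable rank-sum z near 4
  regardless of effect size.  Calibration uses 200/100 null replicates
  (fraction of p < 0.05 expected in [0.02, 0.09]); power uses 60/30
  planted replicates (p < 1e-3 expected in ≥ 95% of seeds).

## Numerical choices and degenerate inputs

Window membership uses closed distance ≤ l_w/2 (boundary sites included).
Equidistant nearest-feature ties break to the lower coordinate.  Merging
treats book-ended intervals (end == start) as overlapping.  The FDR
denominator uses ≥ on the observed side (z* is itself observed, so it is
never 0).  Rank-sum and t statistics on all-identical samples return
p = 1; undefined correlations return NaN; anchors with no same-chromosome
features return a NaN sentinel, never a silent 0.  Chromosomes with no
sites receive no scores.  Exact-match alignment pools forward and
reverse-complement hits for the uniqueness call and reports the
forward-strand start.

## Known limitations

The z model assumes within-chromosome homogeneity of background contact
frequency; real 4C data decays with genomic distance from the bait, which
this model does not capture (the headline analyses focus on
inter-chromosomal interactions, where the assumption is mildest).  The
permutation FDR is a plug-in estimator: at FDR ≤ 0.05 roughly 5% of
called sites are expected to be false, which bounds the specificity of
domain calls.  The Wilcoxon comparisons treat per-anchor values as
exchangeable; heavily overlapping anchor windows reduce the effective
sample size, which is why the study designs above keep site densities at
the sparse, realistic scale.
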