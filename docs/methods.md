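# Methods

This note records the statistical procedures `coexqtl` implements, the
choices made where the design was genuinely open, and what the synthetic
panel does and does not emulate.

## Network construction

The network is weighted and unsigned.  Pearson correlations are computed
across strains; constant genes (zero variance) get correlation 0 to every
other gene with a logged warning (the upstream variance filter normally
removes them).  The soft-power adjacency is a_ij = |r_ij|^β with unit
diagonal.  β defaults to 6; `pick_soft_power` implements the scale-free
topology criterion: for each candidate β, connectivities k_i = Σ_j a_ij are
binned into 10 equal-occupancy bins, log10 p(k) is regressed on log10 k̄ per
bin, and the R² is signed negative when the slope is positive (a scale-free
degree distribution must fall).  The smallest candidate reaching signed
R² ≥ 0.8 wins; if none does, the best-fitting candidate is returned with a
warning.  Binning and the signed-R² convention are our choices; raising β
weakly decreases every off-diagonal adjacency, so mean connectivity is
monotone decreasing in β (property-tested).

The topological overlap of genes i ≠ j is
TO_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), with
ℓ_ij = Σ_{u∉{i,j}} a_iu a_uj and k_i excluding the diagonal; TO_ii = 1.
When the denominator is 0 (an isolated pair with a_ij = 1) the overlap is
defined as 1.  The vectorized implementation is checked against an O(n³)
triple loop to 1e-12 on random matrices.

## Dynamic tree cut

Genes are clustered by average linkage on 1 − TO (scipy's implementation;
an independent hand-rolled agglomeration serves as the test oracle).  Module
detection is adaptive:

1. **Static start.** Cut the dendrogram at `cut_height_quantile` (default
   0.99) of the maximum merge height; branches of at least
   `min_module_size` (default 30) genes are initial clusters, smaller pieces
   are fragments.
2. **Decomposition.** Each cluster is re-clustered and its sorted merge
   heights are scanned for the largest gap.  The cluster splits at the gap
   midpoint when the gap indicates nested structure: gap ≥ 0.07 × the
   cluster's root height, **or** gap ≥ 45 × the median spacing of its merge
   heights.  A coherent module fills its height range densely (measured
   relative gaps ≤ 0.054, gap/spacing ratios ≤ 35 on planted data), while a
   branch hiding nested modules shows one outsized gap (relative gaps
   ≥ 0.063, ratios ≥ 63); the OR of the two criteria, each with margin,
   separates the regimes.  A split is accepted only if it yields ≥ 2 pieces
   with at least one of module size.
3. **Combination.** Fragments are absorbed into the nearest cluster by
   average dissimilarity, gated on that cluster's internal scale (gate =
   mean internal dissimilarity + 0.5 × headroom to the static cut height),
   so loosely attached background genes stay out.
4. Steps 2–3 iterate until the cluster set is stable (cycle-guarded,
   max 10 rounds).  Leftover genes are labelled `unassigned`; modules get
   colour names from a fixed palette in descending size order, with grey
   reserved for the unassigned class.

Degenerate inputs behave sensibly: all-equal dissimilarities give zero
modules (everything unassigned); noise-free planted blocks are recovered
exactly; blocks below the minimum size are absorbed or left unassigned,
never reported as modules.

## Module–trait statistics

GS is the absolute Pearson correlation between a gene and a strain-level
trait, aligned by strain-id intersection (mismatches dropped with a logged
count); MS is the unweighted mean GS over a module (unassigned genes
excluded).  The MS p-value treats the MS magnitude as a single correlation
of n strains — t = r√((n−2)/(1−r²)) against t(n−2), two-sided, the default
behaviour of the R routine this convention follows; a Fisher-z variant
(z = atanh(r)·√(n−3) against the standard normal) is available via
`method="z"`.  No averaging correction is applied to MS and no
multiple-testing correction across module×trait pairs; only raw p-values are
reported.  The analytic two-sided critical |r| at p = 0.05 for 27 strains is
0.381, consistent with (and slightly below) the 0.40 MS rule of thumb used
in this field.  Module eigengenes are the first right singular vector of the
per-gene standardized module matrix, oriented to correlate positively with
the mean standardized module expression, with variance explained reported.

## eQTL mapping and hotspots

Crosses are merged to one panel by renaming D and H calls to N and dropping
markers absent from any cross (BXN coding); U becomes missing.  The
single-point statistic is the normal-likelihood LRS of two-group marker
regression, LRS = n·ln(TSS/RSS), identical to −2×Δlog-likelihood of explicit
two-normal-means fits (test-verified to 1e-9).  Interval positions between
markers are not modelled: hotspot counting uses single-point statistics
only.  RSS is floored at 1e-12×TSS under perfect separation; markers that
are monomorphic or have a genotype class smaller than 3 are recorded as
missing with a reason.  LOD = LRS/4.6 exactly.  Per-transcript genome-wide
thresholds come from permutations of the expression strain labels with
genotypes fixed, p = (1 + #{perm max ≥ observed max})/(n_perm + 1) (the
plus-one rule avoids zero p-values); each gene draws from its own pre-split
seed stream, so results are independent of gene order and thread count.

Hotspot counting uses the strict inequality LRS > cutoff (default 13.8,
i.e. LOD 3).  The empirical p for a marker redraws module-sized gene sets
without replacement from the pool — the network genes present in the LRS
matrix, the only set with defined LRS values — and applies the plus-one
rule; the hypergeometric p is the exact upper tail with pool hits recomputed
from the same LRS column at the same cutoff.  `hotspot_table` shares one
sequence of permutation gene draws across markers: each marker's p is
marginally identical to an isolated run, and restricting the marker set does
not change per-marker values.  `call_hotspots` flags markers with both
p ≤ α and collapses consecutive flagged markers on a chromosome to the one
with the maximal count (ties broken by larger mean LRS); this collapse rule
is our convention.

## Synthetic panel

The generator emulates the study design the pipeline targets: 27 strains
from two crosses (16 BXD-like + 11 BXH-like), 19 chromosomes × 20 evenly
spaced markers, homozygous genotypes from a two-state Markov chain with
per-interval switch probability 0.15 (RI map expansion is not modelled —
downstream statistics only need block structure; heterozygous calls are
never simulated), 1200 genes with six planted 120-gene modules, and four
bone traits averaged over five replicate mice per strain.

Each module m has a latent strain factor f_m ~ N(0, 1); gene g in module m
is λ_g·f_m + ε with λ_g ~ U(0.6, 0.95) and ε ~ N(0, 0.3²); background genes
are pure noise with SD 0.5 (below the module-gene variance, so variance
filtering prefers signal).  The trait module's factor is shifted by
eqtl_effect × coded hotspot genotype before re-standardization, with
homozygous classes coded ±1 — the usual additive-effect parametrization in
RI-panel mapping, so the genotype-class means of the factor differ by twice
the allelic effect (default effect 1.5).  Mouse-level trait draws are
ρ·f + ε with ε scaled so the five-mouse strain means hit the target
correlation ρ = 0.6 (per-trait targets configurable; a fixed mouse-level
noise SD can be requested instead, in which case replicate averaging
visibly shrinks residual variance).  Trait units are plausible for adult
mouse femurs (≈15.5 ± 0.4 mm length, ≈0.065 ± 0.004 g/cm² BMD); the
within-strain spread of replicate means is chosen for testability, not
measured biology.  Detection p-values follow a two-component mixture:
expressed genes draw Beta(0.2, 60) (detected in essentially every strain at
α = 0.01), and a configurable share of background genes draws Uniform(0, 1).
All randomness flows from one seed through named substreams, one per
operation, so stages regenerate independently and byte-identically.

What the generator does **not** emulate: microarray probe effects, batch
structure, technical replicates, variance-stabilizing normalization,
cis-eQTL architecture, RI map expansion, or realistic linkage disequilibrium
beyond Markov blocks.  Passing recovery tests therefore show that the
pipeline's statistics behave correctly on data with the assumed factor/block
structure, not that they are robust to array artefacts.

## Null-calibration designs

Two calibration checks exercise the permutation machinery under the null.
The genome-scan check uses 500 *independent* noise genes (no modules):
with a continuous statistic the permutation p is exactly discrete-uniform,
and the Kolmogorov–Smirnov test presumes independent draws — genes sharing a
module factor have strongly dependent permutation outcomes and would
invalidate the KS comparison, which is a statement about the test design,
not the statistic.  The empirical-hotspot-p check must cope with an
integer-valued count statistic whose permutation p is discrete and
tie-conservative; the calibration therefore simulates fresh null expression
for every repetition (independent p-values), draws half-pool-sized modules
(maximizing the count spread and hence minimizing tie probability) and
varies the exceedance cutoff quantile per repetition (blurring the discrete
p grid).  Under this design the p-values are indistinguishable from uniform
at n = 500 repetitions.

## Problem sizes

Tests and the acceptance script run the full default panel (27 strains,
1200 genes, 380 markers) for recovery checks — ten seeds in about half a
minute — and down-scaled panels (240–300 genes, 36–64 markers) for
smoke/determinism checks.  Hotspot permutation counts default to 10,000 in
the pipeline and use 2,000 in the repeated recovery suite; scan permutation
thresholds default to 1,000 per transcript and are turned off where only
the LRS matrix is needed.  These sizes are the package's own test design
choices; all constants of the analysis itself (β = 6, cutoff 13.8, LOD
divisor 4.6, top-3600 variance filter, ≥50 % detection) keep their
field-standard defaults.

## Known limitations

- The dynamic tree cut's split thresholds (0.07 relative gap, 45× median
  spacing) were designed on factor-model TOM structure; very unbalanced or
  strongly nested real modules may need tuning via `split_gap`/`gap_ratio`.
- MS p-values ignore the averaging over module genes and the correlation
  among them; they are reference values in the field's convention, not
  calibrated family-wise error rates.
- Single-point mapping only; no interval mapping, composite mapping,
  epistasis, X-chromosome handling or marker imputation.
- The empirical hotspot p is conservative at its discrete atoms (ties count
  against significance); with 10,000 permutations and module sizes ≥ 40 the
  effect is negligible at conventional α.
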