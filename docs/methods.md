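# Methods

## Scope and model

`coregmap` analyses a two-factor regulatory study: genome-wide occupancy
of factors A and B from replicated two-colour tiling-array ChIP,
loss-of-function expression timecourses for both factors' mutants, and
dual-luciferase titrations of shared enhancers. The pipeline links the
three layers: bound regions → direct target genes → per-enhancer
co-regulation logic. All genomic intervals are 0-based half-open (BED
convention); GFF3 input is converted on read.

## ChIP enrichment calling

Each IP replicate ranks fragments by log2(IP/reference) descending
(rank 1 = most enriched; ties take average ranks). The rank product is
the geometric mean of a fragment's per-replicate ranks; enrichment is
treated as one-sided (upward) by default since ChIP pulls down bound
DNA — a `two_sided` option admits the symmetric fold bound
(|log2| > 0.58) as well.

The FDR is estimated by permutation: each replicate's rank vector is
shuffled independently, null rank products are pooled, and for the
fragment with the i-th smallest observed RP the FDR is the expected
null count at or below it divided by i, clipped to [0, 1] and made
monotone non-decreasing in i by a step-up pass (so significance is
nested in RP order). When (n!)^k ≤ 10,000 the null is enumerated
exhaustively instead of sampled; tests verify the sampled estimator
against this enumeration. Default n_perm = 1000 with an explicit seed.

A fragment is significantly enriched iff FDR < 2 % and mean fold > 1.5
(both configurable). Fragments must be significant with **both**
antibodies at a timepoint to be called bound (the intersection is taken
at fragment level, before merging); bound fragments from all timepoints
are then single-linkage merged into unique regions wherever they
overlap by ≥ 1 bp — abutting half-open intervals stay separate. Each
region records its contributing timepoints and minimum FDR.
Co-occupancy counts A-regions overlapping ≥ 1 B-region by ≥ 1 bp;
percentages are rounded only at rendering.

Mock IPs are simulated and carried in the matrices but do not enter the
enrichment statistic; the reference channel already plays that role.

## Expression timecourse

Two-colour arrays hybridise mutant against stage-matched wild-type
cDNA directly, giving M = log2(mutant/wt) per spot. Print-tip loess
normalisation subtracts a tricube-weighted local linear fit of M on A
(span 0.4, no robustness iterations) within each print-tip group;
groups under 30 spots fall back to a global fit with a warning.

Per timepoint and mutant, the one-class SAM statistic is
d = m̄/(se + s0) with se = sd/√n. s0 is chosen by scanning percentiles
of the per-gene standard errors for the value minimising the
coefficient of variation of d's spread across ten se-ordered windows;
with fewer than 50 genes the deterministic fallback (median se) is
used.

The permutation null flips the signs of each gene's **centred**
replicate residuals, rescaled by √(n/(n−1)) to restore the variance
absorbed by the mean. Centring matters: flipping raw replicate vectors
lets strongly regulated genes re-enter the null (the all-plus and
all-minus patterns reproduce |d| exactly), which places a floor of
about 2/2ⁿ on attainable q-values — with n = 4 replicates no gene
could ever reach q < 1 % in a study with many true positives. The
centred null is immune to this contamination while remaining exact for
null genes up to the variance correction. q-values are median null
counts over observed counts, clipped and made monotone non-increasing
in |d|; the 2ⁿ sign patterns are enumerated exhaustively on small
matrices and tests verify the estimator against that enumeration.

A gene is differentially regulated at a timepoint iff q < 1 % and
|mean log2 FC| > 0.7, and "genetically downstream" of a factor if
significant at ≥ 1 timepoint in that factor's mutant. No
cross-timepoint correction is applied beyond the per-analysis
q-values, mirroring the per-timepoint treatment with a gene-level
union.

## Target integration

Bound regions are assigned to genes by a documented stand-in for the
published assignment procedure (which is not restated in the source):
candidate genes overlap the region or have their TSS within 10 kb;
candidates rank by (differentially expressed in the relevant mutant,
tissue-annotated, TSS distance, gene id) and the top candidate wins.
Manually curated reassignments are supported through an override
table. A direct target requires bound ∧ DE-in-matching-mutant ∧
tissue-annotated.

Overlap significance is the upper hypergeometric tail
P(X ≥ overlap) for |A| draws from a universe containing |B| successes;
the universe defaults to all genes on the array and is a configuration
field. Response profiles (mean log2 FC over A-mutant then B-mutant
timepoints) are clustered with k-means (k-means++ seeding, best of 50
restarts) and relabelled by ascending centroid mean so cluster 0 is
always the most downregulated group. k = 4 by default (three
behaviours — down in both, up, divergent — with the divergent group
often splitting); k = 3 is supported. Missing profile entries are
zero-imputed with the mask recorded on the profile; masked entries are
not excluded from the k-means objective because the complete-profile
case is the only one the pipeline produces, and a masked WCSS would
have required abandoning the standard estimator.

## Reporter co-regulation logic

Replicate activities are firefly/Renilla ratios normalised to the
reporter-only mean; standard errors of fold changes combine both
conditions' replicate variances by the delta method. The
baseline-corrected additive expectation E_add = f_A + f_B − 1 is used
(excess activities over the baseline of 1 add); it exactly reproduces
the published worked example (3.6, 2.4 → 5.0), which a plain sum does
not. The uncorrected sum remains available as a configuration option.

Classification on the primary dose combination (highest combined dose
with matched singles): a factor is an activator iff its alone-fold
exceeds 1 with p < α (unpaired two-tailed Welch t on log activities
against the reporter-only replicates — logs stabilise the
multiplicative variance). Cooperative: f_AB above E_add with p < α (t
against E_add with delta-method se). Repressive X-on-Y: X inactive, Y
active, f_AB significantly below f_Y; dose dependence is a one-sided
Welch t showing lower combined activity at the higher repressor dose.
Additive: ≥ 1 activator and f_AB statistically indistinguishable from
E_add; sub-additive combinations with both factors active also resolve
to additive rather than to a repression call, since repression is
defined by an inactive factor antagonising an active one. Zero-variance
degenerate inputs (noise-free data) are handled by exact comparison
with a relative tolerance of 1e-9. The reported p-value is the decisive
test's (cooperative/repressive: the interaction test; additive /
single-factor / inactive: the strongest activation test), and stars
follow the fixed 0.05/0.01/0.001 tiers.

Ectopic-induction sufficiency is a decision table over the three
induction booleans (A alone, B alone, both) plus an explicit
attenuation flag, because three booleans cannot encode "induced but
weaker than the single factor": attenuated (given an active single
factor) → attenuated_by_X; else A alone → A_sufficient; else B alone →
B_sufficient; else both → both_required; else never_induced.

## Synthetic data generator

The generator emulates the study design, not the organism: a single
synthetic chromosome (2 Mb by default) tiled by overlapping 3 kb
fragments at 1.5 kb steps (count = floor((L − tile)/step) + 1), genes
on a regular grid, and planted bound sites (1 kb) centred in host-gene
slots so sites never collide and region-to-gene assignment has an
unambiguous truth. Per-gene response classes are drawn i.i.d. from a
mixture (defaults: 10 % down in both mutants, 5 % up in the A mutant,
5 % divergent, 5 % down in A only, 75 % null); site hosts are drawn
from the classes that respond in the matching mutant, co-bound sites
from classes responding in both, and hosts always carry the tissue
annotation (other genes carry it with probability 0.6). Each site is
active at both timepoints with probability 0.4, or at one timepoint
(0.3 each).

ChIP signal: a tile's IP log2 ratio sums effect × fractional site
overlap × antibody efficiency over planted sites, plus N(0, sd) noise;
mocks are pure noise; each antibody carries an independent off-target
site set that the dual-antibody rule removes. Defaults: effect 1.2
log2 units (≈2.3-fold), antibody efficiencies (1.0, 0.8), noise sd
0.25 — typical two-colour replicate noise, and chosen (as the paper
gives no noise magnitudes) so the weaker antibody's per-tile z-score
(≈7.7 with 4 replicates) clears the genome-wide detection threshold
the way the real experiment's enrichments did.

Expression: class-specific mean trajectories (e.g. down-in-both genes
at −1.5 log2 units from timepoint 3 onward in both mutants) plus
N(0, 0.5) replicate noise.

Reporters: doses {0, 1, 10} ng per factor in all combinations with ≥ 3
replicates (default 9). Single-factor dose response is linear in the
excess fold (half effect at 1 ng). Generative means — additive:
f_A + f_B − 1; cooperative: (f_A + f_B − 1)(1 + γ), γ = 1 by default,
with low single-factor maxima (1.3–2.0) as cooperative enhancers show
weak single-factor activation; repressive: factor A stays at baseline
and f_AB = 1 + (f_B − 1)·exp(−κ·dose_A), κ = 0.3, giving ≈26 %
attenuation at 1 ng and ≈95 % at 10 ng (clearly dose-dependent).
Replicate noise is multiplicative lognormal with coefficient of
variation 0.1 on the firefly/Renilla ratio (Gaussian on log2 ratios
for the array data) — standard noise models for these assay types; the
source study reports none.

All randomness flows from one integer seed through SeedSequence spawn
keys (layout, ChIP, expression, reporters), so stages can be
re-simulated independently and a fixed seed reproduces byte-identical
fixture bundles.

What the generator does **not** emulate: array spatial artifacts and
print-tip bias (expression fixtures are emitted post-normalisation;
the loess step is exercised on separately constructed M/A tables), dye
swaps beyond a sign convention, embryo staging variability, chromatin
accessibility structure, and correlated probe noise. Passing recovery
tests therefore demonstrate the statistics recover planted structure
under the design's replication and noise model, not performance on raw
scanner data.

## Problem sizes and numerical choices

Default analyses run in seconds on one CPU: 1332 tiles × 8 analyses
(2 factors × 2 antibodies × 2 timepoints) at 1000 permutations, 1000
genes × 12 SAM analyses at 1000 sign-flip draws, 500 enhancers for
mode-recovery benchmarks, and 20 repeats of 300-gene/600-kb all-null
studies for calibration. Report values are rounded only at rendering;
percentages to one decimal. Permutation estimators switch to exact
enumeration when the null space is ≤ 10,000 rank assignments (ChIP) or
≤ 20,000 gene-patterns (SAM). Stage timings are logged but excluded
from the rendered report so identical config + seed runs give
byte-identical files.

## Known limitations

- The rank-product FDR is a permutation estimator, not the
  expected-false-positives formula from the original rank-product
  literature; the two agree on calibration but can differ in finite
  samples.
- The region-to-gene assignment rule is a documented stand-in for a
  procedure published elsewhere; with real annotations its ranking
  weights may need adjustment.
- The sampled SAM q-value uses the median null count (robust to
  outlying permutations) while the exhaustive mode uses the exact mean;
  they converge but are not identical estimators.
- Mode classification assumes the combination condition shares doses
  with the assayed singles; unmatched titration grids raise an error
  rather than extrapolating.
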