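# Methods

This note records the models behind `modfoot`, the parameter choices
that matter, what the simulator does and does not emulate, and the
numerical conventions. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Data model and coordinates

The atomic record is a per-read, per-adenine modification probability
(`read_id`, `chrom`, `strand`, 0-based `pos`, `mod_prob` in [0, 1]),
the output dialect of a nanopore modified-base caller. Records are
grouped into `Molecule` objects — single sequenced fibers — whose span
is `[min pos, max pos + 1)`. All coordinates are 0-based half-open
everywhere internally (BED convention); any 1-based display is
formatting only. A read reported on several chromosomes (supplementary
alignments upstream) is split into one molecule per chromosome with a
warning, since a single span across chromosomes is undefined.
Duplicate (read_id, pos, strand) rows keep the first occurrence and
warn: silently taking a max or mean would hide upstream corruption.

Both strands' adenines are carried with per-call strand labels.
Ratio computations pool strands by default — the assay methylates
both strands and pooling doubles the per-bin call count — with a
per-strand option for forward-strand-only analyses. Whether upstream
callers pool strands before binning is not standardized; pooling is
this package's documented default.

## Threshold model

Pooled call probabilities from a labeled sample are bimodal: a sharp
component near zero (unmodified adenines, basecaller noise) and a
broad high component (truly modified adenines). We fit a plain
two-component Gaussian mixture on [0, 1] by EM — no logit transform,
no truncation-renormalization. Plain Gaussians slightly leak mass
outside [0, 1]; we accept that for fidelity to the standard model, and
clipping in the generator mirrors what a probability-valued caller
emits.

EM details: input is sorted before fitting, making the fit exactly
invariant to input order; the first restart initializes component
means at the 25th/75th percentiles, two further restarts draw random
quantiles from the seeded generator; tolerance 1e-6 on the mean
log-likelihood, at most 500 iterations, component sd floored at 1e-4
to prevent collapse; best final log-likelihood wins; components are
reported in ascending-mean order. Requires at least 10·k observations
and a non-degenerate (non-constant) sample.

The binarization cut-off is the point strictly between the two means
where the *weighted* component densities are equal — the posterior-0.5
decision boundary. This is the most standard reading of "fit the
distribution to find the threshold"; published pipelines in this assay
family report thresholds (≈0.5 for bulk, 0.8 for high-confidence
single-molecule work) without stating the rule, so the rule is exposed
and overridable (`--fixed-cutoff`), and a second calibration —
a high quantile of a no-antibody control's probability distribution
(`cutoff_from_control`, default 99th percentile) — is provided as an
alternative, not a default. If the weighted densities do not cross
between the means (near-coincident components or extreme weights), a
`NoBoundaryError` asks for a manual cut-off rather than guessing.

Binarization is strict: methylated iff `prob > cutoff`. Ties at the
cut-off are measure-zero but must be deterministic; they count as
unmethylated.

Confusion metrics follow the usual definitions (sensitivity
TP/(TP+FN), precision TP/(TP+FP), specificity TN/(TN+FP)); zero
denominators yield NaN plus an explicit `undefined` flag, never a
silent 0 or 1. ROC/AUC wraps scikit-learn's implementation (the
standard tool for this step); the returned AUC equals the trapezoidal
integral of the returned points, which a test asserts.

## Signal tracks

Bins default to 50 bp sliding by 5 bp from position 0 of each
chromosome. Trailing bins are clipped to the chromosome end and kept
with their true width (ratios are per-call, so no width correction is
needed); a chromosome shorter than one bin width yields the single bin
[0, length). Steps larger than the width (gapped tilings) are
unsupported.

The methylation ratio of a bin is flagged calls over total adenine
calls pooled across every read overlapping the bin. A bin with no
adenine call is *undefined* (NaN) — distinct from ratio 0 in every
output, because a coverage gap is not evidence of absence. Undefined
bins are skipped (and counted) when writing bedGraph.

Count normalization is counts-per-million by default:
`Nm_i = C_i / Σ C_i × scale`, `scale = 1e6`, exposed as a parameter.
The output sums to `scale` exactly and is invariant to rescaling the
input counts.

Meta-profiles average the ratio in offset windows around centers
(defaults ±1000 bp in 100-bp bins for peak centers; use ±500 bp for
motif centers). The bin step defaults to the bin width
(non-overlapping), with a `step` parameter for sliding variants.
Minus-strand centers have offsets mirrored so negative offsets always
mean upstream. Each profile point reports the number of contributing
centers; centers with no covered window contribute nothing.

Replicate concordance is the Pearson correlation of
`log2(ratio + 1e-3)` over bins defined in both replicates (dropped
bins are counted; fewer than 3 shared bins is an error). The
pseudocount keeps ratio-0 bins finite; 1e-3 sits two decades below
typical background ratios so it compresses only true zeros.

## Single-molecule states

Per fiber, the region is tiled with non-sliding 50-bp bins from the
region start and scored from that molecule's calls only. A bin is
methylated iff its ratio is strictly greater than 0.5 AND it carries
at least 2 flagged sites — one stray high-probability call can never
methylate a bin. Bins without an adenine call are undefined and are
excluded from the density denominator by default; `strict=True`
instead counts undefined bins inside the molecule's span as
unmethylated, for sensitivity analysis. The methylation bin density
maps to a state: light on [0, 0.25), medium on [0.25, 0.75], heavy on
(0.75, 1]. The boundaries belong to medium — the heavy/light
definitions are strict inequalities — and an undefined density returns
an `unclassified` sentinel, never a default state. The recommended
single-molecule cut-off is 0.80 (high-confidence calls).

Per-gene heterogeneity rows sort the defined molecule densities
ascending and linearly interpolate the sorted vector onto a
fixed-length quantile grid (default 50 points, endpoints preserved),
making genes with unequal molecule counts comparable; this is the
simplest order-preserving resampling. Rows are clustered by
agglomerative clustering with Euclidean distance and average linkage
(scipy linkage/fcluster) — deterministic, with labels renumbered by
first occurrence; metric and linkage are parameters because the
underlying method is stated only as "hierarchical clustering" in this
assay family. The number of clusters is a required user parameter.
Cluster summaries report mean TPM over genes present in the supplied
expression table, with explicit counts of genes lacking expression.

## Co-labeling coefficient

Windows of width w (default 50 bp) tile a region; only full windows
are used. Per molecule, `A_i` is the count of flagged calls in window
i; a window with no adenine call from that molecule is masked
undefined. A fully-binarized mode (A ∈ {0, 1} by the methylated-bin
rule) is available behind the `binary` flag.

The local coefficient is `cc = 0.5 − |A_i − A_j| / (A_i + A_j)`:
0.5 iff the counts are equal and positive, −0.5 iff exactly one is
zero, symmetric, and dependent only on the count ratio. A molecule
with `A_i = A_j = 0` is *excluded* from that pair's average rather
than scored 0.5 — the single most consequential convention in this
module: mutual absence (uncovered or unlabeled fiber) is no evidence
of co-labeling, and scoring it as perfect concordance would let
unlabeled fibers dominate every matrix.

Matrix entry (i, j) is the mean of per-molecule coefficients over
spanning molecules (both windows defined, not mutually zero); its
support is the contributor count, and entries below the minimum
support (default N = 1) are undefined. The region-level aggregate is
the sum of defined entries over the full double index (both triangles
plus the diagonal) — the double-sum form of the aggregate score is
read as summation over window indices, not molecules. The
distance-dependent variant multiplies each entry by
`(|L_i − L_j|/n + 1)` (L = window starts, n = region length), a factor
in [1, 2) that amplifies distant values of either sign, implemented
literally.

The promoter-upstream scan takes, per gene, the w-bp anchor window at
the promoter's upstream (TSS-proximal) edge and computes its CC
against each window of the 2-kb span further upstream, strand-aware.
Genes are ranked by row variance (ties broken by gene id so the
ranking is order-invariant); the upper quartile is retained, retained
rows are clustered with the same hierarchical settings (undefined
entries filled with 0 for the distance computation only), and
contiguous runs of windows with CC ≥ `high_cc` (default 0.25) are
reported as candidate cis-regulators. The anchor choice is this
package's convention; the method family does not name one.

## Peak calling

Candidate regions are non-overlapping bins of a configurable width
(default 200 bp) rather than sliding bins, so the BH correction
operates on approximately independent tests. Each covered bin is
tested with the exact upper tail `P(X ≥ k | Binomial(n, p0))` where k
is the flagged-call count, n the adenine-call count, and p0 the IgG
control's genome-wide flagged/total ratio (a ratio of pooled counts,
never a mean of per-molecule ratios; clamped to [1e-6, 1−1e-6]). The
test runs on call counts, not read counts: the null probability is a
per-call methylation ratio, so per-call counts are the consistent
unit. After BH correction, adjacent significant bins are merged
(touching or overlapping, same chromosome) and a merged region passes
iff adj-p < 0.01 (strict) and width > 50 bp (strict) — the width
filter is only meaningful after merging when bins are wider than
50 bp. Merged records carry summed counts and the minimum member
adj-p; merging can be disabled.

Peak-set comparison counts any-bp overlaps in both directions and,
when per-peak reference signal is supplied, compares overlapping vs
non-overlapping reference peaks with a two-sided Wilcoxon rank-sum
test (scipy `mannwhitneyu`: exact for small tie-free samples, normal
approximation otherwise).

The Hi-C proximity comparison expands each interaction end by ±2.5 kb,
keeps pairs with *exactly one* end overlapping a peak (both-end and
no-end pairs are counted in an attrition report), and takes the mean
of defined track ratios over the non-peak end's flank. Background
regions of 5 kb are sampled with a seeded generator, rejecting any
overlap with pair flanks or peaks, until the requested count or a try
budget is reached. The two mean-ratio sets are compared two-sided by
rank sum.

## Simulator

The generator emulates the post-basecalling view of a footprinting
run: single-strand molecules with seeded uniform starts and log-normal
lengths (median 2 kb, shape 0.35 — the read-length scale typical of
these libraries), each covered adenine of the molecule's strand
emitting one call. Call probabilities come from a two-component
emission: unmodified N(0.15, 0.08), modified N(0.80, 0.12), clipped to
[0, 1] — a sharp near-zero peak and a broad high peak, the
qualitative shape reported for this assay family; the parameters are
config fields, not constants, and `noiseless=True` collapses them to
exact 0/1 for end-to-end identity checks. Endogenous background m6A
is represented only by the low component's upper tail, as it is
orders of magnitude below the artificial signal in mammalian DNA.
Truth (per-call modified flags plus per-mode latents) is recorded for
every call; all randomness flows from the single config seed.

Labeling modes and their declared conditions:

* **footprint** — adenines inside truth intervals modified at
  `p_fg = 0.6`, elsewhere `p_bg = 0.05`. These defaults are the
  planted-power conditions used throughout the tests (tethered-enzyme
  labeling is efficient but incomplete; background reflects off-target
  activity).
* **dam_motif** — only GATC adenines (offset +1 on the plus strand,
  +2 on the minus strand; GATC is its own reverse complement) are
  modifiable, each molecule-site at `motif_efficiency = 0.85`,
  emulating a Dam-treated control.
* **state_mixture** — each molecule draws a target density from
  {0.05, 0.5, 0.95} (equal weights); `round(density × n_bins)` of its
  molecule-local 50-bp bins are planted methylated with *all* their
  adenines truly modified, background bins at `p_bg`. Planting whole
  bins makes the per-molecule density exact — the generator's
  definition of a molecule's state — so classification error comes
  only from the emission noise, which is the quantity of interest.
  The truth table records each molecule's planting frame so
  evaluations can bin on the same grid.
* **correlated_windows** — fixed genome windows toggle on/off per
  molecule (on-probability 0.5); designated pairs share a latent with
  copy probability `p_shared = 0.9`. On-windows are fully labeled
  (`p_fg = 1.0`, symmetric with the state-mode planting semantics:
  a labeled regulatory window is heavily methylated on that fiber),
  off-windows at `p_bg = 0.01`. These conditions, with eight planted
  pairs in a 2-kb region at 500 spanning molecules, are the declared
  co-labeling recovery setting.

What the simulator does **not** emulate: basecalling and alignment
error, sequence-context-dependent caller bias, mappability,
chromatin-accessibility bias of the enzyme (heterochromatin is labeled
as readily as euchromatin here), fragment-end effects, duplex reads,
and endogenous 5mC. Passing tests therefore demonstrate correctness
of the statistics under the declared generative model, not robustness
to those real-data artifacts.

## Problem sizes in tests and acceptance

The suite and `scripts/acceptance.py` use desk-scale problems chosen
to make every statistical check well-powered: 50,000 calls × 20 seeds
for mixture recovery (oracle: 1e-4 grid search of the generating
mixture's density crossing); 1,000 random instances each for the
confusion and BH hand oracles; the full A ∈ [0, 20]² grid for CC
exactness; 500 molecules × 20 seeds for planted co-labeling; 300
(noiseless) and 1,000 (noisy) molecules for state recovery, the noisy
arm deriving its cut-off from a 100k-call subsample fit; 20 null
genomes of 200 kb at 4× plus one 20-kb, 30× planted-footprint genome
for peak calibration and power; ~100-kb, 30× Dam simulations giving
>10⁴ motif-site calls. Each acceptance quantity is recomputed from
scratch at run time from the supplied seed.

## Known limitations

* The mixture model is unpenalized plain-Gaussian; heavily imbalanced
  samples (modified weight ≪ 5%) can push the density crossing close
  to the high mean, where the boundary is flat and the fitted cut-off
  less stable — the control-quantile calibration is the better tool
  there.
* CC support decays with window distance (few molecules span distant
  pairs); entries at low support are reported with their support
  rather than smoothed.
* The peak caller assumes bin-level independence under the null; with
  sliding bins the BH correction would be anti-conservative, which is
  why candidate bins are non-overlapping by default.
* `strict` density mode and the fully-binarized CC mode are provided
  for sensitivity analysis but are not the defaults, and the package's
  guarantees are stated for the defaults.
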