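# Methods

`archdelta` reimplements, as a tested library, the downstream statistics of
an integrative chromatin-architecture study comparing two conditions
(wild-type vs a knockout that removes a repressive histone mark).  This
note describes the models, the conventions and tunable parameters, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinate and unit conventions

All genomic coordinates are 0-based half-open (BED convention); contact
bins are indexed from 0 as `floor(start / bin_size)`.  Strand is ignored
everywhere — no operation in the pipeline is stranded.  The stage
resolutions are 100 bp (ChIP/methylation quantification), 5 kb
(co-occupancy windows), 25 kb (compartments, directionality index, loop
counting), with 10 kb and 5 kb appearing as finer interaction resolutions
in the multi-resolution merge.

ChIP signal is quantified as RPKM per 100 bp bin,
`count / (bin_kb * library_total/1e6)`, with a matched input track
subtracted (input-RPKM).  Negative input-subtracted values are retained,
never clipped: clipping would bias window means upward.  Window signal is
the *mean* of member bins (the sum is available via `mode="sum"`); the
mean was chosen because it is invariant to window size and keeps units
interpretable.

## Differential binding and expression

The core statistic is a Poisson pairwise comparison.  For a unit with
counts `(count_ref, count_obs)` and library totals `(total_ref,
total_obs)` the expected observed count under no change is

    lambda = (count_ref + alpha) * total_obs / total_ref

with pseudocount `alpha = 1` by default (guarding zero references;
`alpha = 0` reproduces the closed forms, e.g. p = e^-5 for ref 5, obs 0,
decrease).  One-tailed p-values are exact Poisson tails at `lambda`; the
two-sided p doubles the smaller tail, capped at 1.  Scaled (real-valued)
counts are rounded to the nearest integer for the observed value while
`lambda` stays real — the least surprising discretization, and it is
logged.  Fold changes are pseudocounted and library-normalized:
`FC = ((obs+alpha)/total_obs) / ((ref+alpha)/total_ref)`.

An alternative one-tailed Fisher's exact test on the 2x2 table
`[[obs, total_obs-obs], [ref, total_ref-ref]]` is provided for
increased-peak calling (`method="fisher"`, the default; the result table
records the method).  The two formulations differ statistically in an
important way discussed under *Calibration*, below.

Benjamini-Hochberg adjustment runs within each test family separately
(peaks; genes; repeats; loops; interactions) — never pooled — matching
the per-analysis q thresholds.  Default thresholds: increased-peak tiers
q < 5e-4 / 1e-5 / 1e-7 (nested low/medium/high sets); dysregulated genes
q < 0.001 with FC > 2; dysregulated repeats q < 0.01 with FC > 2, the
symmetric FC < 1/2 rule defining "down"; loops and interactions q < 0.1
with FC > 2 or < 1/2.

Number-matched random controls are uniform draws without replacement from
the eligible universe (universe minus the observed set, matched on
coordinates), deterministic under a seed that is always logged.

## Mutual exclusivity of marks

The exclusivity of the repressive mark and the architectural protein is
summarized over 5 kb windows that contain peaks of both marks in at least
one sample: (i) the Pearson correlation of the two window signals and
(ii) the fraction of windows jointly above each signal's 0.9 quantile
("double-high fraction").  These are deliberately minimal summaries of a
scatter-plot claim; no single standard statistic exists for it.

## A/B compartments

Per chromosome, the observed/expected matrix divides each cell by the
mean of all cells at its genomic distance (diagonal included, no
smoothing).  The Pearson-correlation matrix of the O/E rows is
eigendecomposed; the three unit-norm eigenvectors of largest
absolute eigenvalue are kept.  Bins with no usable contacts are dropped
before correlation and re-inserted as missing; isolated masked O/E cells
fall back to the neutral value 1.  The compartmentalization score is the
eigenvector whose entries best correlate (largest |r|, ties to the lowest
index) with accessibility (ATAC) on the same 25 kb grid, sign-oriented
per chromosome so that r > 0.  Positive scores are A, negative B; the
unclassified band epsilon defaults to 0 (no dead zone) and exists for
robustness experiments.  Each condition is oriented against its own ATAC
track by default; a single track can be pinned by passing it for both.

A global sign flip of any eigenvector leaves the output unchanged — the
ATAC orientation fixes the gauge.  Switch classes (A->B, B->A, unchanged,
unclassified) follow from the label pair alone, so swapping conditions
maps A->B to B->A exactly.  Feature/switch-bin overlap is tested with an
exact two-tailed hypergeometric (minimum-likelihood two-sided convention:
sum of all outcome probabilities not exceeding the observed one).

## Matrix balancing, directionality index, boundaries

Knight-Ruiz balancing (inner-outer Newton iteration with conjugate-
gradient inner solves, ported from the published algorithm) scales each
chromosome's matrix to unit row sums on unmasked rows; rows with zero
marginal are masked first.  Defaults: relative tolerance 1e-6, 3,000
outer iterations; non-convergence raises with diagnostics.

The directionality index per bin contrasts upstream (A) and downstream
(B) contact sums within a +/-2 Mb window (configurable, a multiple of the
bin size):

    E = (A + B) / 2
    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

DI is 0 when A = B, flips sign and order under mirroring, and scales
linearly with counts (so only its sign is scale-invariant).  DI is
computed on the balanced matrix by default; raw-matrix DI is a flag away.

Boundaries are called by a deterministic thresholded sign-transition
scan — **not** an HMM, and not equivalent to HMM-based callers: a
boundary sits at the first bin of a positive DI run whose preceding
negative run reached `-threshold`, with runs allowed to bridge single
zero-DI bins.  The default threshold is 0.4 x the standard deviation of
nonzero DI per chromosome, which separates boundary spikes (quadratic in
the contact step) from within-domain noise by an order of magnitude on
balanced maps.  Boundary sets from several samples merge within a
positional tolerance (default 1 bin, cluster midpoint rounded down), with
a pairwise conservation table.

## Loops and significant interactions

Loops called per sample merge on *exact* anchor coordinates (provenance
retained).  Per-loop counts are rectangle sums of contact-map cells over
anchor1 x anchor2.  Counts are scaled to the smallest library
(`factor_s = min(totals)/total_s`), preserving within-sample proportions
exactly, then tested with the two-sided Poisson pairwise statistic and
BH-adjusted within the loop family.  Significant interactions are
declared inputs (their upstream callers are out of scope): records with
q < 0.1 in any sample are kept, and a lower-resolution record is dropped
only when both anchors of a retained higher-resolution record are fully
contained in its anchors; partial overlaps keep both.  The differential
core is shared with loops but forms its own BH family.

Anchor classification gives "increased" precedence over "unchanged"
binding (a single increased peak at either anchor decides), then "none".
A feature "falls into" a loop iff it overlaps (>= 1 bp) the closed span
from the start of anchor1 to the end of anchor2; features spanning loops
of several classes count once per class.  The anchor interval is used
as-is (no padding).

## Enrichment

Peak composition assigns each peak the class of its largest-overlap
repeat (ties: longer overlap, then smaller annotation start), or
"unannotated"; proportions sum to 1.  Exact hypergeometric tails use the
minimum-likelihood two-sided convention.  Bootstrap enrichment p-values
use the add-one empirical formula `p = (1 + #extreme) / (1 + n_sim)` with
10,000 simulations by default; the simulated vector is retained so the
null density can be inspected, but the density itself is never used for
p — kernel-density tails are bandwidth-dependent and irreproducible.

## Synthetic data

The generator plants machine-readable truth and then adds only Poisson
noise, so every recovery test has an unambiguous oracle.  Defaults are
the study conditions exercised by the acceptance suite:

* genome — 2 chromosomes x 50 Mb; 2,000 non-overlapping genes; 3,000
  repeats with an exact class mixture (SINE B2 0.40, SINE Alu 0.15,
  SINE B4 0.10, ERVL-MaLR 0.15, LINE L1 0.20);
* ChIP — 5,000 architectural-protein peaks (500 bp, rate 10/bin over
  background 0.2/bin at 100 bp), 200 planted 4x gains; 3,000
  repressive-mark peaks (2 kb, rate 5/bin).  Every gained peak sits
  inside a mark peak whose KO rate is divided by the gain ratio
  (scaled by the coupling strength).  Stable co-occupied sites (30% of
  the remaining peaks) draw a latent exclusivity t, mark rate ~ 2t and
  protein rate ~ 2(1-t), mixed by the coupling strength — coupling 1
  plants the full anticorrelation pattern, coupling 0 makes occupancy
  independent;
* expression — lognormal base rates (median 100 for genes, 50 for
  repeats, sigma 0.5); 100/50 genes and 150/75 repeats planted up/down
  at 4x;
* contacts — 2,000 bins/chromosome at 25 kb; expected cell rate
  `depth * (d+1)^-alpha` with depth 100 and alpha 1, times a compartment
  checkerboard factor (25-bin blocks, same-label 1.6 / cross-label 0.6),
  a within-TAD boost of 2.5 (20 boundaries), and focal loop spikes of
  15x (500 loops at 250 kb-2.5 Mb, 50 planted 3x gains).  The KO map
  flips labels in 20 planted 10-bin switch blocks and scales changed
  loop spikes.  Planted loop anchors avoid switch blocks so the two
  perturbations stay identifiable.

Noise is Poisson throughout, matching the test assumption; a
gamma-Poisson overdispersion knob exists for robustness experiments only.
Everything is deterministic under `(config, seed)`: per-stage,
per-condition generators are derived from independent seed sequences, so
outputs are byte-identical across runs.

What the generator does **not** emulate: mappability and GC biases,
copy-number structure, fragment-level Hi-C artifacts, overdispersed
biological replicates, correlated peak shapes, sequence content, or
genome-scale mammalian chromosome counts.  Passing recovery tests
therefore demonstrates the statistics and bookkeeping are correct under
the stated noise model — not that real-data effect sizes would be
recovered at the same rates.

The null-calibration configuration used by the false-discovery test runs
20 seeds at a reduced size (1 chromosome x 20 Mb, 2,000 peaks, 1,000
genes, 500 repeats, 200 loops) with every planted effect ratio set to 1.

## Calibration and known limitations

* **The Poisson pairwise test is conditional.**  Its p-values are exact
  when the reference is a known rate (the calibration check: observed ~
  Poisson(20) against a fixed reference of 20 rejects at ~4.4% for
  alpha = 5%).  When *both* conditions are noisy samples — as in any real
  pairwise comparison — conditioning on the sampled reference understates
  the null variance of the difference by a factor of two, and the
  resulting p-values are anti-conservative.  Under an all-effects-null
  simulation the gene/repeat/loop stages therefore exceed their nominal
  BH levels (the dedicated test records this), while the Fisher
  formulation — which conditions on the table margins and is exactly
  valid for two-sample count comparisons — keeps the peak stage at zero
  false discoveries.  Users who need strict null calibration should
  prefer the Fisher path where counts are integers; the Poisson path is
  retained as the specified method for scaled counts.
* The boundary caller is a simplified substitute for HMM-based domain
  callers and will differ from them near weak or nested boundaries.
* Compartment calls assume the checkerboard signal dominates the O/E
  correlation structure; very small switch blocks (a few bins) at low
  depth may fall below eigenvector resolution.
* The bootstrap empirical p cannot go below `1/(n_sim+1)`; report the
  bound, not zero.
* k-means row clustering is seeded and deterministic, but cluster labels
  are arbitrary across different seeds.
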