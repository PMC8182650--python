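# Methods

This note documents the models and procedures implemented in `zevphen`, the
defaults that matter, and what the synthetic-data tests do and do not
establish about real screens.

## The synthetic-data generator

The generator exists so that every downstream stage can be tested against
known ground truth. It emulates a β-estradiol-titration screen at three
levels: colony growth tables, plate images, and pooled BAR-seq runs.

**Strain panel.** Each strain carries a unique 12-nt barcode, a dose-response
archetype, an auxotrophy flag, a toxicity effect, a native expression level
(log-normal TPM, median 30, ln-σ 1.2), and a baseline fitness multiplier
(log-normal, ln-σ 0.1, wild type fixed at 1 — allele construction never
yields perfectly isogenic growth, and without this spread regressions of
growth on growth are degenerate). Barcodes are rejection-sampled to a minimum
pairwise Hamming distance of 5 = 2·2 + 1, which makes two-mismatch assignment
provably unambiguous. The default archetype mix (dependent 49%,
dependent-toxic 4.7%, constitutive 33%, constitutive-toxic 9.2%,
nonfunctional 4.2%) mirrors the behavior-class frequencies reported for
essential-gene collections of this kind. Exactly one wild-type spike-in
strain is appended; it doubles as the plate reference.

**Growth model.** Colony area follows a logistic curve
A(t) = K / (1 + (K−A₀)/A₀ · e^(−rt)) with A₀ = 5 px, r = 0.45 h⁻¹, and a
dose-dependent carrying capacity K = f(d) · 200 px · fitness. The capacity
fraction f(d) is built from two Hill terms — induction
h(d) = d^1.5/(d^1.5 + 1^1.5) (EC50 1 nM) and toxicity
g(d) = d²/(d² + 30²) (EC50 30 nM) — combined per archetype: constitutive
f = 1; constitutive-toxic f = 1 − e·g; nonfunctional f = 0.02; dependent
f = 0.02 + 0.98·h; dependent-toxic the product of the last two. Toxicity
effects e are uniform on [0.6, 0.9]: called toxic genes in screens of this
kind lose at least half their growth. Auxotrophs follow the dependent
response on minimal (YNB) medium and the constitutive one on complete (SC)
medium. This machinery is invented plumbing — any generative model producing
the five archetype shapes would serve; no parameter is a measured quantity.

**Noise.** Colony sizes get multiplicative log-normal noise with ln-σ chosen
so the relative standard deviation equals `noise_sd` (default 0.05) exactly.
The noise structure of real colony sizes is not documented anywhere we could
anchor it; multiplicative log-normal is a declared modeling choice.

**Plate images.** Colonies are rendered as hard intensity disks
(radius √(A/π)) at lattice positions (pitch 24 px), over a background plane
with a configurable left-to-right gradient (default 20%) and Gaussian pixel
noise (σ 30 on a 1,000-count 16-bit background). The realized (discretized)
pixel count of every disk is recorded alongside the requested area, so
measurement accuracy can be judged independently of rendering quantization.

**BAR-seq runs.** Each read is `[up flank][barcode][down flank][filler]` with
independent per-base substitution errors (default 0.5%); indels are not
simulated, which keeps the assignment oracle exact. Per-sample counts are
multinomial over relative abundances at the requested depth. Abundances start
log-normal (ln-σ 1.0), the wild-type spike-in starts at 3% of the pool, and
planted effects deplete linearly in time to a terminal log2FC of −1.2:
auxotrophs in YNB without inducer, toxic strains in induced arms. Samples are
pre-demultiplexed; multiplexing indices and quality-aware calling are out of
scope.

## Colony quantification

Grid detection projects the foreground mask (global median + 3·MAD threshold)
onto each axis, finds the periodic peaks, fits the lattice
position ≈ offset + pitch·k by least squares, and refines each center by
local centroid. A blank or aperiodic image raises a detection error rather
than returning a grid.

Measurement counts pixels above a local threshold inside each grid cell (half
pitch around the center). The threshold is the median + 3·MAD of a window
spanning two grid pitches — robust as long as colonies cover less than half
the window, which holds for the rendered geometry and for standard
1536-format plates. By construction the measurement is invariant to adding a
constant to the image.

Normalization per plate, in order: (1) divide by the plate's interior median
size; (2) divide by a 7×7 moving-median spatial surface and by interior
row/column medians; (3) cap colonies that exceed their 7×7 neighborhood
median while having ≥ 2 empty 8-neighbors (competition artifact); (4) flag
the outermost row/column as edge and exclude it. A final rescale pins the
interior median at exactly 1. The pipeline is invariant to global rescaling
of raw sizes. Plates with under 50% measurable interior colonies are marked
low-quality with a warning. Window sizes and thresholds are parameters; the
published screens do not state theirs, so ours are declared defaults
validated against synthetic ground truth, not reproductions.

## Growth curves and AUGC

Replicate colonies are pooled per (strain, medium, dose) and LOESS-smoothed
over time. The default span is 0.3: local-linear smoothing with a 0.5 span on
an hourly logistic biases the knee by about 6.5% of the dynamic range,
whereas 0.3 keeps the worst-case pointwise error near 2%; the span is
configurable. Groups with fewer than three timepoints are flagged
unsmoothable and keep their raw means. Negative fitted values are clipped to
zero.

AUGC is the trapezoidal integral of the smoothed curve over the intersection
of all curves' time windows. Each strain's AUGC is divided by the wild-type
reference strain's AUGC at the same dose and medium (falling back to the
per-dose median with a warning if the reference is missing); the scaling is
recorded in the matrix metadata. Averaging over replicate colonies happens
before scaling, by pooling; the replicate count is carried per cell.

## Dose-response clustering and labels

Profiles are clustered with the Chebyshev (L∞) metric and average linkage,
and the tree is cut at k = 5. Chebyshev groups strains by their worst-case
disagreement across doses, which separates behaviors that differ strongly at
any single dose (e.g. toxicity at the top dose). Linkage is not stated for
the published clustering; average linkage is used for consistency with the
same study's expression clustering. Cluster indices are relabeled by
ascending mean profile at dose 0 so numbering is reproducible, and rows are
sorted by strain id so input order never matters.

Labels are rule-based on cluster means relative to the reference scale:
"low" is < 0.2, a "fall" is a > 30% drop from the profile peak to the final
dose. Uniformly low → nonfunctional; low start with a rise → dependent (with
a fall → dependent-toxic); high start → constitutive (with a fall →
constitutive-toxic); anything else is labeled unclassified rather than
forced.

Expression association bins strains into six equal-count bins on
log-expression (the binning rule for the published analysis is unstated;
equal-count on log scale is the natural default), compares the extreme bins
by a two-sample KS test, reports Spearman's ρ on unbinned pairs, and a
Welch t-test between the bottom and top expression deciles. The linear model
of maximal induced vs native expression is ordinary least squares restricted
to genes under 250 TPM native expression, with the excluded genes reported.

## Phenotype scores

The Aux score, reversibility cutoffs (boundary 0.55 inclusive to reversible,
0.75 inclusive to partially reversible), the toxicity procedure (trim top 2%
and bottom 4% of x and y separately with union removal; OLS fit y = mx + b;
y_corr = (y − b)/m; distance |x − y_corr|/√2; threshold 2,000), and the SDL
2-of-2 rule are implemented exactly as printed for the original screens.
Three points needed decisions:

- The toxicity correction formula is printed inconsistently at its source;
  mapping the 100 nM measurement onto the 0 nM scale, y_corr = (y − b)/m, is
  the only reading under which the subsequent diagonal-distance test is
  meaningful, and is what we implement. Toxicity additionally requires being
  *below* the diagonal; improved growth is never flagged.
- The 2,000-unit distance threshold is absolute, tied to the imaging scale of
  the original screens; the synthetic toxicity-screen generator emits growth
  totals on a matching ~10⁴ pixel-unit scale (log-normal baseline, median
  10,000, ln-σ 0.25; measurement noise 5%) so the default threshold is
  exercised as-is.
- The SDL per-replicate "score" is not given a formula at its source; a raw
  size ratio can never be < −0.08, so the score must be on a log or
  difference scale. We default to log2(ratio), with ratio − 1 selectable.
- Dependence classes (constitutive / dependent / partially dependent /
  no growth) have no published thresholds; defaults are 0 nM growth ≥ 75% of
  maximum → constitutive, ≤ 25% → dependent, profile maximum < 0.1 →
  no growth. These are declared, configurable, and echoed into outputs.

In the end-to-end pipeline, the toxicity regression is fit only over strains
whose 0 nM total is at least 20% of the screen's upper (90th-percentile)
growth scale: inducer-dependent alleles gain growth with estradiol, violate
the caller's 1:1 assumption, and flip the fitted slope on archetype-mixed
panels. The caller itself is unchanged by this input selection.

## BAR-seq

Barcode assignment precomputes every variant within two substitutions of
each barcode (a Hamming ball; 631 variants per 12-mer). A read's extracted
barcode is assigned by a single lookup: inside exactly one ball → that
strain; inside several → ambiguous (discarded, never fractionally assigned);
otherwise unassigned. This is mathematically identical to an exhaustive
Hamming scan, which the tests retain as an independent oracle. Flank
handling — exact preferred, one mismatch tolerated, upstream position
searched within ±2 — is a declared default; the published pipeline's
internals are not specified. The mismatch budget applies to the barcode
only, with flank tolerance separate. Per-sample accounting always satisfies
assigned + ambiguous + unassigned = total.

Fitness: counts are floored at the 5th percentile of the pooled time-0
count distribution (the published description says only that a background
level was derived from the t0 distribution); each strain's count is divided
by the wild-type spike-in count in the same sample; and the ratio is divided
by the *geometric* mean of the strain's t0 ratios in the same medium, then
log2-transformed. The geometric mean is chosen because it is the unique
choice under which each strain's t0 columns average to exactly zero in log
space; an arithmetic mean would make that only approximate. The fitness math
assumes no particular spike-in fraction.

Fitness profiles are clustered with average linkage on Euclidean distance.
A correlation metric is available but not the default: screens are dominated
by neutral strains whose profiles are near-constant noise, and the
correlation between two near-constant profiles is essentially random, so a
correlation metric cannot hold the neutral class together. Euclidean
distance keeps neutral strains near the origin and separates depletion
patterns by both shape and magnitude. Clusters are annotated from their mean
profile: depleted only in minimal medium without inducer → auxotroph-like;
depleted only in induced arms → overexpression-toxic-like.

## Reproducibility

All randomness flows from one global seed through named per-stage substreams
(SHA-256 of `seed:stage`), so adding a stage never perturbs another's draws.
Configs are strict (unknown keys rejected) and round-trip losslessly through
YAML/JSON; the pipeline manifest records the config echo, its hash, and
SHA-256 checksums of every output, and a re-run with the same config and
seed reproduces identical checksums.

## Problem sizes and scope of validation

The test suite validates at desk scale: 8 plates in 384 format for
quantification recovery; 500 strains × 12 doses for archetype recovery
(ARI ≥ 0.9); 5,000 strains with 5% planted toxicity for the caller
(sensitivity ≥ 0.9, FDP ≤ 0.1); 1,000 strains at 10⁶ reads per sample for
log2FC recovery (RMSE ≤ 0.1 for strains with t0 counts ≥ 200); and a
60-strain end-to-end determinism run. These sizes were chosen as the
smallest at which the statistical claims are meaningful.

What passing these tests shows is that the *implementations* are correct
against ground truth under the generator's assumptions. What they cannot
show: robustness to real-plate artifacts the generator omits (lens
distortion, agar drying, pinning offsets, colony morphology), to sequencing
indels or quality pathologies, or to biological effects outside the planted
patterns (e.g. slow-growth compensation in pools). Real-data headline
numbers from published screens (gene counts, cluster fractions, correlation
coefficients) depend on the original images and libraries and are not
reproduction targets here.
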