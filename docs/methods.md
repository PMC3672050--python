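# Methods

## The model

A whole-tissue expression profile is a cellularity-weighted mixture: the
measured signal of transcript *t* at day *d* is (up to noise) the sum over
cell types of per-cell expression × the share of the RNA pool that cell
type contributes at *d*.  After spermatogonia-killing irradiation the germ
lineage empties and refills stage by stage, so a transcript expressed
specifically in one germ stage follows a smooth trough whose day of
minimum is the day that stage is maximally depleted, and a somatic
transcript follows an apparent peak (its per-cell expression is constant;
its *share* of the pool rises while germ RNA is missing).  The pipeline's
job is to find transcripts whose profiles are consistent with this
mixture model and group them by cell type of origin.

## Selection statistic

For a profile x₁..xₙ (log2 of the normalised, probe-collapsed signal):

    ES = Σ_{i=1}^{n−1} |x_i − x_{i+1}|  /  Σ_{i=1}^{n} (x_i − x̄)²

The numerator uses absolute neighbour differences: a squared numerator
would carry the same units as the denominator and lose the intended
first-order/second-order contrast.  The statistic is deliberately **not**
scale-free — ES(c·x + b) = ES(x)/|c| — so larger-amplitude smooth profiles
score lower; constant profiles hit the 0/0 case and return +∞ (never
selectable, which also keeps undefined correlations out of the distance
matrix later).

Significance: the day columns are shuffled (default 10 shuffles, one
shared random ordering per shuffle so cross-transcript correlation is
preserved; per-transcript orderings are available as an option) and every
transcript's ES recorded under every shuffle.  The raw FDR at threshold t
is `[(1/P)·#{null ≤ t}] / max(1, #{observed ≤ t})`; the cumulative minimum
taken from the largest observed ES downward yields monotone q-values
(no +1 pseudo-count in the numerator).  Default cut-off q ≤ 30%.

Reliability filter: at the day where |collapsed − mean| is largest, the
sample SD of the probe-level values as a percent of the collapsed value
(a probe-level CV, computed on the intensity scale where a percent is
meaningful) must be ≤ 15%.  Single-probe transcripts return 0 — no
dispersion is measurable — and a collapsed value of exactly 0 at the
extreme day returns +∞.  On a one-array-per-day design the probes are the
only replicate structure available, which is why the filter reads the
"SD of the most extreme expression value" at probe level.

## Pre-processing

Quantile normalisation equalises the per-day intensity distributions
(reference = per-rank mean of the sorted columns; ties receive the mean of
the reference values at the ranks they occupy).  Probes are then collapsed
per transcript by the median, retaining the probe values for the CV
filter.  The order is fixed — normalise at probe level, then collapse —
and all downstream statistics run on log2(signal + 1); both scales are
exposed because processed one-colour intensities are conventionally
log-transformed before profile statistics.

## Clustering and k choice

Selected profiles are z-scaled per transcript (shape, not level, carries
the cell-type signal) and compared by correlation distance d = 1 − r:
uncorrelated pairs sit at 1, identical shapes at 0, opposite at 2.
(1 − r)² and 1 − r² were considered and rejected as defaults: both fold
anti-correlated shapes onto correlated ones, which would merge germ
troughs with the somatic peak.

PAM runs with greedy BUILD initialisation and best-single-exchange SWAP
passes until no medoid/non-medoid swap lowers the total cost; ties break
toward the lowest transcript index, so results are fully deterministic.
SWAP converges to a single-swap-optimal configuration; on unstructured
instances this can sit marginally above the exhaustive optimum (the
canonical R implementation lands on the same configurations), while on
data with genuine group structure and k equal to the group count it
attains the optimum — both behaviours are pinned by tests.

k is chosen by the uniqueness rule: for each k in 2..10, cluster and
compute per-cluster median z-profiles; k is admissible when every pair of
medians has r < 0.8; the largest admissible k wins.  Splitting a real
cluster produces two near-identical medians (r ≈ 1), so the rule caps k at
the true structure.  If nothing is admissible the function returns 2 with
a warning.  The searched range 2..10 reflects that beyond the true k,
clusters only split into sub-clusters with very similar profiles.

## Annotation

Marker symbols are matched case-insensitively with whitespace stripped; no
alias or ortholog resolution is attempted (a synonym-expanded marker table
can be supplied instead).  The somatic cluster is the one holding the
majority of Leydig + PTM + Sertoli markers (falling back to the cluster
with the highest profile peak if no somatic marker maps).  Germ clusters
are ordered by trough day, computed as the argmin of the median z-profile
on the sampling grid — no interpolation, because the day grid is coarse
and interpolated troughs would claim precision the data lacks.  A
late-spermatid archetype centred on day 27 therefore reports its trough at
grid day 28.  Marker votes that contradict the trough ordering lose, with
a logged warning: marker expression genuinely spans consecutive germ
stages, whereas the trough ordering is the depletion wave itself.

## Over-representation

Exact upper hypergeometric tails (scipy) per gene set, Bonferroni
multiplied by the number of sets tested for that list, significance at
corrected p ≤ 0.01.  The EASE-score dialect (k replaced by k − 1 in the
tail, more conservative for small counts) is behind a flag because popular
annotation servers report it; the exact tail is the default.

## Histology quantification

Pixel classification is a Gaussian naive Bayes over RGB with equal priors,
fitted to labelled swatches (defaults mimic AEC red-brown, haematoxylin
blue, and white background; real scans should supply their own swatches).
Red connected components (8-connectivity by default — stain blobs are
irregular; 4-connectivity available) with area strictly below 20 µm² are
re-assigned to blue; the boundary case (exactly 20 µm²) is kept.  The
red:blue ratio excludes background from both terms.  The µm²-per-pixel
calibration must come from the scanner; results on real scans are
calibration-dependent by design.

## Synthetic data: what it emulates, and what it does not

Defaults (the study conditions):

| parameter | value | rationale |
| --- | --- | --- |
| sampling days | 3,7,10,14,17,21,24,28,31,35,38,42,45,48,52,56,59 | the arrayed schedule (17 occasions) |
| archetype troughs/peak | 10 / 17 / 24 / 27 germ, 26 somatic | depletion-wave order; spermatogonia trough day is a convention (earlier than the spermatocyte day-17 trough), the others follow the reported trough days |
| archetype widths (days) | 4.0 / 4.0 / 3.0 / 4.5 germ, 6.0 somatic | recovery to < 2% residual by ~day 40 (45 for the somatic artefact); widths also satisfy the uniqueness contract — all pairwise archetype correlations < 0.8, so the five shapes are separable by the same rule the k search uses |
| trough depth | 0.95 | cell-type-specific transcripts fall near array floor when the cell type is absent |
| somatic peak height | 3.0 (4-fold apparent rise) | germ cells contribute most of the RNA pool; their loss several-fold inflates the somatic share |
| planted counts | 109/164/246/273/196 | the five reported cluster sizes (total 988) |
| probes per transcript | 4 | 10,988 transcripts × 4 ≈ a 44K probe array |
| planted baselines | log2 ~ N(9.5, 1.0) | expressed transcripts are bright |
| probe replicate SD | 0.05 (log2) | probes of an expressed transcript agree closely |
| background | 10,000 transcripts, baselines log2 ~ N(7.5, 2.0), per-probe-day SD 1.5 | dim, broad, erratic — unexpressed/unreliable probes |

Two generator design points matter and were fixed by contract, not by
observation of any downstream result:

* **The background must be dim and broadly spread.**  Quantile
  normalisation maps ranks; if the low-intensity range is sparsely
  populated, deep planted troughs land in a thin tail and get
  rank-distorted (an array-floor effect), inflating their ES and probe
  CV.  A dim, broad background — which is also what real arrays look
  like — keeps the bottom of the distribution dense so troughs survive
  normalisation.
* **Power contract.**  At the defaults, the largest planted ES sits below
  the 5th percentile of the background ES distribution, every planted
  transcript passes both filters, and the expected number of background
  transcripts passing jointly is ≪ 1; these are asserted as tests.

What the generator does **not** emulate: biological replicate mice,
amplification chemistry, probe-specific affinity biases, spatial array
artefacts, correlated background transcripts, or mixed-stage expression of
single genes (a real transcript can be expressed in two consecutive
stages).  Passing the planted-recovery tests therefore shows the
*arithmetic* of the pipeline is right under the stated mixture model — it
does not certify performance on real arrays, where the selection margins
are unknowable without deposited data.

The section-image generator draws non-overlapping red disks on a flat blue
field with a white margin and samples colours from the swatch
distributions; ground-truth areas are pixel-exact (rasterised counts, not
the requested disk areas).  It does not emulate stain gradients, blob
irregularity, or chromatic aberration.

## Numerical and interface choices

* Quantile-normalisation ties: "ties = average" dialect (mean of the
  reference values over the occupied ranks), matching the common R
  implementation on tie-free data exactly.
* FDR: pooled across transcripts by default (all transcripts' shuffled
  scores form one null); a per-transcript option exists but with 10
  shuffles per transcript it is far noisier.
* The k-choice rule returns the largest admissible k; a secondary
  silhouette tie-break is unnecessary because a maximum cannot tie.
* Writers round-trip at 6 significant digits; the pipeline manifest
  records package version, config, seeds and SHA-256 checksums of all
  inputs and outputs, and a rerun with the same inputs and seed is
  bit-identical.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the PAM implementation draws no random
  numbers at all.

## Limitations

* With data never deposited, the reported real-data numbers (988 selected;
  cluster sizes 109/164/246/273/196) can only be reproduced as
  planted-recovery results on the synthetic study, whose per-population
  counts are transcribed from the report.
* The dissimilarity actually used in the original analysis is not
  recoverable from its description ("pair-wise correlation variances …
  centred around 1"); d = 1 − r matches the stated centring and is the
  standard choice, but it is an interpretation.
* The extreme-point SD filter reads probe dispersion; an alternative
  reading (SD across biological replicates) is not implementable on a
  one-array-per-day design.
* Histology results depend on the colour swatches and the µm²-per-pixel
  calibration, neither of which is standardised here.
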