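# Methods

## Survival model and the S/L statistic

Survival curves are estimated with the product-limit (Kaplan–Meier)
estimator. Ties between deaths and censorings at the same time are
resolved deaths-first (a subject censored at *t* is still at risk for a
death at *t*), the standard convention. The AUC of a curve is computed
as the exact rectangle sum of the right-continuous step function — no
trapezoids — from 0 to the time survival reaches zero. When censoring
leaves S(t) > 0 at the last observed time, integration stops there and
the curve is flagged `fully_observed = False`; this is the restricted-
mean-survival convention, and downstream consumers can see the flag.
Rectangle integration is exact for step functions, and in the common
assay design where animals are scored until all are dead there is no
censoring at all, in which case the AUC equals the arithmetic mean of
death times to machine precision (asserted at 1e-12 in the tests).

S/L is the ratio of the stressed cohort's AUC to the unstressed
control's AUC. Classification uses a tie tolerance of 1e-9 around 1:
below is "loss", above is "gain", within is "neutral". The tolerance
exists only to keep exactly-equal curves from being classified by
floating-point noise; scientifically the comparison is on a continuous
ratio. Literature records that report only mean spans (not curves) are
handled by the identity AUC = mean survival for fully observed curves,
so S/L = mean_stress / mean_lifespan for such records.

Uncertainty on S/L is a percentile bootstrap (default 1,000
replicates): subjects are resampled with replacement within each group,
curves re-estimated, and the 2.5/97.5 percentiles of the ratio taken.
The seed is mandatory; there is no silent default.

The log-rank (Mantel–Cox) test is the standard two-group comparison —
observed-minus-expected deaths over pooled risk sets, one degree of
freedom, no continuity correction. The implementation delegates to
`lifelines.statistics.logrank_test`; the test suite checks it against a
hand-tabulated O−E/V computation on a small example.

## Locomotion metrics

Instantaneous speed is the Euclidean displacement between consecutive
centroid samples divided by the elapsed time. Speeds are unsmoothed by
default; an optional window-3 rolling median is available because
tracker jitter inflates the slow-frame fraction, and the choice is
recorded in outputs.

A directional shift is counted when the angle between successive
displacement vectors exceeds 90°. Displacements shorter than the noise
floor (`min_step`, default 0.005 mm) neither define a heading nor reset
the previous one, so a pause does not mask a reversal. This
reversal-dominant operator is a documented stand-in: the upstream
tracking tools expose a "Direction" output without publishing its exact
definition, and reversals are the locomotory feature that increases
with age and neurodegeneration, which is what the downstream index
measures. Thrashing frequency (body bends per second) cannot be derived
from centroid tracks at all; it enters the fitness panel as a
pre-computed per-worm scalar from a posture-aware tool.

The paralysis rule is: paralyzed iff strictly more than 80% of
instantaneous speeds are below 0.015 mm/s. The boundary is strict, so a
worm with exactly 80% slow frames is motile. The rule is monotone in
the speed threshold (raising it can only add slow frames), which the
suite asserts.

The direction rescue index for a treated group is the fraction of its
worms whose shift count is strictly below the untreated control group's
mean count. For treated counts drawn i.i.d. from the control
distribution the expected index is P(X < E X) ≈ 0.5 for symmetric
continuous distributions, a calibration the tests verify by simulation.

## Total fitness

The five panel metrics — body size, crawl speed, direction score, swim
speed, thrash frequency — are each normalized as treated/control ratios
and averaged; the control therefore scores exactly 1.0. The direction
metric is stored rescue-oriented (direction rescue index, or an
inverted shift ratio when indices are unavailable) so that higher means
fitter for all five; the mode is recorded in panel metadata. Extra
metrics can ride along in a panel but never enter the five-ratio mean.
The formula is deliberately the mean of ratios, matching the worked
control baseline of 1.0 — a literal left-to-right reading of the
composite with only the last term divided by 5 would give a baseline of
4.2 and is rejected.

## Regulatory scan

DEG filtering keeps a gene iff |log2FC| ≥ log2(2) = 1 and FDR ≤ 0.05,
both thresholds inclusive (a gene exactly at log2FC = 1, FDR = 0.05 is
kept). Rows with FDR outside [0, 1] are rejected with a message rather
than aborting the table.

Motif scanning expands the degenerate consensus (D = A/G/T, W = A/T,
R = A/G; TTDTCATC has 3 concrete words, WWTRTCAT has 8) and matches
case-insensitively with overlapping occurrences all counted; "presence"
means at least one site. Both strands are scanned by default —
minus-strand hits are found by matching the reverse-complemented motif
against the plus strand, so coordinates always refer to the provided
sequence — with a flag to restrict to the plus strand. N in the subject
never matches. A brute-force window-by-window oracle
(`nemaspan.oracles.brute_force_scan`) shares no code with the regex
scanner and is used for equivalence testing. On uniform-random
sequence, the expected hit rate is |expansion|/4^8 per position per
strand (11/65536 ≈ 1.68e-4 for the two motifs combined), which the
closure tests check within binomial error.

Promoter extraction takes the 1,500 bases upstream of the feature start
(transcript 5′ end when available, else gene start): for plus-strand
genes the bases ending immediately before the start, for minus-strand
genes the bases beginning immediately after the end,
reverse-complemented so the promoter reads 5′→3′ toward the gene.
Input coordinates are 1-based inclusive (the annotation convention);
all outputs are 0-based half-open, and flanks clipped at contig edges
are returned shorter and flagged. The upstream anchor and strand policy
are this package's documented defaults, not a claim about any
particular upstream tool.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

- **Cohorts**: exponential (constant hazard λ) or Gompertz mortality
  with hazard h(t) = a·exp(b·t) (the parameterization is stated because
  conventions vary), sampled by inverse CDF; deaths beyond an optional
  follow-up horizon are censored there. Stress is emulated as an
  accelerated hazard (e.g. hazard ratio 2 gives a population S/L of
  0.5, the recovery target used at n = 5,000 per group over 20 seeds).
- **Tracks**: 30-s recordings (matching the assay's video duration) at
  10 frames/s, a typical stereomicroscope capture rate. Motile worms
  follow a correlated random walk — heading evolves by wrapped-normal
  increments (SD 0.3 rad/step), speed ~ N(0.12, 0.03) mm/s — with
  Poisson reversal events (instantaneous 180° ± small noise heading
  flips) at 0.2 events/s. Paralyzed worms jitter isotropically at a
  mean speed of 0.002 mm/s, well below the 0.015 mm/s threshold. These
  are generator conventions, not claims about real worm biophysics:
  real tracks have posture-driven speed autocorrelation, omega turns,
  and segmentation noise that the generator does not emulate, so
  passing closure tests demonstrate internal consistency of the
  pipeline, not field performance on real video.
- **Promoters/DE tables**: 1,500-nt background sequence i.i.d. at 36%
  GC (a *C. elegans*-like genomic composition; the analytic-background
  closure test uses 50% GC because the analytic rate assumes uniform
  composition). Planted genes receive concrete motif words at
  non-overlapping uniform positions and strands. True-effect genes draw
  |log2FC| from N(2, 0.5) truncated at 1 with FDR ~ U(0, 0.01); nulls
  draw log2FC from N(0, 0.3) and FDR ~ U(0, 1), so essentially no null
  passes both thresholds jointly.

All generators are deterministic under a fixed seed (bitwise-identical
outputs, asserted).

## Problem sizes

Validation runs use cohorts of 5,000 per group over 20 seeds for the
hazard-ratio recovery, 1,000 random 1.5-kb sequences for scanner/oracle
equivalence, and 400 worms / 400 genes for the closure checks — sizes
at which the binomial error bands in the tests are meaningfully tight
while the whole suite runs in well under a minute per check.

## Known limitations

- The directional-shift operator and the promoter anchor/strand policy
  are documented package choices where upstream tools leave the
  definition open; results are comparable within the package, not
  necessarily across tools.
- Bootstrap CIs are percentile intervals; no BCa correction.
- Dose–resilience profiles summarize literature-level means and inherit
  whatever heterogeneity the source studies carry; no meta-analytic
  weighting is applied.
- Thrashing frequency is consumed, never computed, from centroid data.
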