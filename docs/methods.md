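# Methods

## Signal model

A Sanger electropherogram is modelled as four non-negative amplitude series
b_i(t), i ∈ {G, A, T, C}, on an integer sample grid, plus one peak time t_K
per called base. A mixed read of two templates P1 and P2 at fraction ω is,
pre-noise, the convex combination of the two pure signals recorded in a
single reaction — both templates share the run's time distortion and decay.
The pure reference reads come from *different* reactions and therefore carry
their own time and amplitude distortions; the central task of the pipeline
is to undo those run-to-run differences before fitting ω.

## Pipeline stages and their parameters

**Trimming** (defaults: keep base calls 20–1000). Early calls sit in
primer-proximal signal; quality degrades far into the run. Trimming is
index-based on base calls, not raw samples, and records the absolute offset
of the first kept call so that trimming is idempotent and window bounds stay
in original read coordinates.

**Peak calling** (secondary-peak relative threshold 0.014 of the column
sum, absolute floor 50 units; reference purity threshold 0.028). The
relative threshold decides when a second channel is a real minor-variant
peak rather than baseline; the absolute floor suppresses ghost calls in
low-signal columns. Purity is the stricter criterion applied to reference
reads when selecting anchors. All three are configuration values
(`RunConfig`), applied to analyzed (vendor-processed) amplitudes as read.
Ties in channel amplitude break by the fixed priority G, A, T, C for
determinism. An all-zero column counts as single-peak and pure, and is
excluded from anchors to avoid 0/0 gains.

**Alignment.** The mixed read is encoded over an extended alphabet — IUPAC
two-base ambiguity letters at two-peak positions, which are the lossless,
swap-invariant standard encoding of unordered base pairs — and aligned
globally against each reference's primary-base sequence with
`Bio.Align.PairwiseAligner`, linear gap penalty −2. The pairwise
substitution score is the single-reference projection of the column score
(plain match 1, extended letter containing the reference base 0.85, else
0); merged three-way columns are then re-scored with the full rule (1 / 2 /
0.85 / 0.75 / 0 / −1 / −2, see `sangermix.align`). Merging two pairwise
alignments on mixed-read coordinates avoids cubic three-way dynamic
programming; since both alignments share the mixed read's coordinate
system, the merge is exact. The −1 score is reserved for mixed positions
gapped in both references; single-gap columns keep their projection score
(diagnostic only — they can be neither anchors nor informative columns).

**Anchors** (minimum 5). Columns with identical, pure reference bases and a
single mixed peak register the three time frames. Monotonicity in all three
frames is enforced greedily (keep the earlier anchor), since the warp needs
strictly increasing segments; with a global alignment violations are rare.
Fewer than 5 anchors is a hard failure rather than a degraded estimate.

**Warping.** Between consecutive anchors the reference time axis is
stretched linearly; amplitudes at fractional positions are linearly
interpolated (the simplest monotone-preserving scheme; the warp is exact at
anchors by construction). Gains λ₁, λ₂ are the mixed/warped-reference
amplitude ratios at anchors, computed on the anchor base's channel only
(the channel carrying signal at a single-peak pure position), linearly
interpolated in between. Zero-denominator anchors are skipped and bridged;
if none is usable the run fails. Linear interpolation of an exponential
decay-ratio curve is accurate to well under 1% at typical anchor densities
(an anchor every few bases).

**Estimation.** ω minimizes the discretized least-squares objective over
the support of the informative columns: all samples within half a peak
spacing of each informative column's mixed peak time, on the two divergent
bases' channels. Restricting the integral to informative supports keeps
identical-sequence regions — which carry no contrast, only noise — out of
the objective; a `RunConfig.integration = "full"` mode integrates the whole
window instead. The closed form

ω* = Σ (b_M − g₂)(g₁ − g₂) / Σ (g₁ − g₂)², with g_j = λ_j · b̄_Pj,

follows from the normal equation of the quadratic objective and is clamped
to [0, 1] afterwards; the residual is reported at the clamped value. A
per-column ω diagnostic (same formula per support) is returned so
amplitude-weighting effects can be inspected: the global estimator weights
positions implicitly by contrast (g₁ − g₂)², which is the least-squares
optimum but differs from an unweighted average of per-position ratios.

**Informative columns** are gap-free columns in the quality window (base
calls 20–600, absolute coordinates) where the references diverge and every
called mixed peak belongs to {p1, p2}. Divergent columns where the mixed
read shows a *single* matching peak are deliberately included: they are
exactly what a strongly unbalanced mixture produces (at ω = 0 or 1 the
minor component's peak is below the calling threshold), and excluding them
would make boundary mixtures unquantifiable. Columns where neither peak
matches are mismatches — counted and reported, never used; two-peak columns
with exactly one matching peak are ignored entirely.

## Fluorescence estimator

For the two-reporter validation system (red mCherry on variant 1, green
EGFP on variant 2, same promoter), bulk readings give
ω = 1/(1 + λ(G/R − β)), with λ = R_P1/G_P2 (cross-reporter scale) and
β = G_P1/R_P1 (green bleed-through of pure red cells). Eight promoter
calibrations are bundled (`sangermix/data/promoters.tsv`). The formula can
leave [0, 1] under noise; values are clamped, and a non-positive
denominator (extreme red dominance) saturates at 1. Inputs are taken as
already-reduced fluorescence values; no background subtraction is applied.

## Synthetic data generator

`simulate_trace` emulates: per-base Gaussian peaks (sd 2 samples) at ~12
samples spacing with sd-0.5 jitter; initial amplitude 7000 with per-base
exponential decay 1.5e-3 (roughly 2.5-fold over 600 bases); 1% crosstalk
between spectrally adjacent dye channels; run-specific monotone
piecewise-linear time warps (segment slopes 1 ± 0.05 in the calibration
experiments); additive Gaussian noise sd 70 (1% of initial amplitude),
truncated at zero. These defaults are the package's standard simulated
operating point: a clean but not idealized capillary run. Mixtures are
exact convex combinations pre-noise; reference runs get independent seeds,
warps and ±20% decay jitter in `recovery_experiment`, modelling separate
sequencing reactions.

What the simulator does *not* model: dye-dependent peak shapes and mobility
shifts, base-call errors and quality scores, indels between the variants
(sequences are substitution-divergent and equal length), inhomogeneous
noise, saturation. Passing recovery tests therefore demonstrate the
correctness of the registration + least-squares machinery under controlled
distortions, not instrument-grade accuracy on real chromatograms.

## Numerical choices

- Exact arithmetic boundaries: the secondary-peak test uses ≥ (a peak at
  exactly the threshold counts); the purity test uses < (a second channel
  at exactly the threshold is impure).
- All interpolation is `np.interp` (linear); warp evaluation is exact at
  anchors by construction.
- The closed-form ω is used always; tests verify equivalence with a
  grid-plus-bounded-refinement numeric minimizer to 1e-6.
- Degenerate inputs fail loudly and specifically: identical references
  (`DivergenceError`), zero contrast on the support
  (`DegenerateContrastError`), no usable gain anchors, fewer than 5
  anchors, reads shorter than the trim start.
- Problem sizes: recovery experiments default to 650-base reads with 40
  divergent positions (mirroring a ~700-bp amplicon with two homologous
  reporter genes); unit tests use 120–300-base reads, which exercise every
  code path at a fraction of the cost.

## Known limitations

- Strictly two-component: three or more co-occurring variants are out of
  scope.
- Gap-free variant pairs: an indel between the variants desynchronizes all
  downstream peaks in the mixed read, which this model does not represent.
- No confidence interval on ω; the residual, anchor count and per-column
  spread are the available quality signals.
- Amplitude-threshold effects: because the absolute secondary-peak floor
  (50) does not rescale with trace intensity, global scale invariance of
  the estimate holds exactly only while secondary peaks stay above the
  floor.
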