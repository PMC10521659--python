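# sangermix

Quantification of two-variant DNA mixtures directly from Sanger
electropherograms.

## The problem

When two DNA variants co-occur in a sample — two co-transformed plasmids, a
rising de-novo mutation in a culture, an edited and an unedited allele — a
single Sanger read of the mixed template shows *two* peaks at every position
where the variants differ, with peak heights proportional to the variants'
abundances. `sangermix` turns that qualitative picture into a number: given
the mixed read and one pure read per variant, it estimates the fraction
ω ∈ [0, 1] of variant 1 in the mixture. This replaces qPCR or deep
sequencing for routine relative quantification at a fraction of the cost.

## The method

Traces from different runs are not comparable as-is: fragments migrate at
run-specific speeds (time distortion) and the signal decays at run-specific
rates (amplitude distortion). The pipeline therefore:

1. **Trims** each read to its reliable base calls (drop the first 20 and
   everything past 1,000).
2. **Calls peaks** per position: the top channel is the primary base; a
   secondary peak is accepted only if it reaches 1.4% of the column signal
   *and* an absolute amplitude of 50. Two-peak positions are written with
   IUPAC two-base letters (e.g. G+T → K).
3. **Aligns** the mixed read globally against each reference with a
   two-peak-aware substitution score (match 1; divergent-column single-peak
   match 2; both peaks matching the divergent pair 0.85; one of two peaks
   matching 0.75; gap −2), then merges the two alignments into three-way
   columns.
4. **Selects anchor points**: gap-free columns where both references carry
   the same base, both are pure (second channel < 2.8% of the column), and
   the mixed read is single-peak. At least 5 anchors are required.
5. **Warps** each reference into the mixed read's frame: piecewise-linear
   time stretching between anchors, and per-time gains λ₁(t), λ₂(t)
   interpolated between anchor amplitude ratios.
6. **Solves** the least-squares mixture model over the informative columns
   (reference-divergent positions in the quality window, base calls 20–600):

       min over ω in [0,1] of  Σ_t ( b_M(t) − ω λ₁(t) b̄_P1(t) − (1−ω) λ₂(t) b̄_P2(t) )²

   The optimum has a closed form from the normal equation and is clamped to
   [0, 1].

The package also includes a fluorescence-based estimator for the
two-reporter (mCherry/EGFP) validation system, ω = 1/(1 + λ(G/R − β)) with
bundled per-promoter (λ, β) calibration constants, and a synthetic
chromatogram simulator (Gaussian peaks, exponential decay, monotone time
warps, channel crosstalk, additive noise) so the whole pipeline can be
exercised with known ground truth and no sequencer.

## Worked example

```python
import numpy as np
from dataclasses import replace
from sangermix import SimSpec, divergent_pair, make_warp_knots, quantify, simulate_mixture

rng = np.random.default_rng(0)
seq1, seq2 = divergent_pair(650, 40, rng)          # two variants, 40 SNPs apart
specs = [
    replace(SimSpec(), seed=int(rng.integers(2**31 - 1)),
            warp_knots=make_warp_knots(rng, 660 * 12, strength=0.05))
    for _ in range(3)
]                                                   # three independent "runs"
mixed, ref1, ref2 = simulate_mixture(seq1, seq2, 0.3, *specs)
est = quantify(mixed, ref1, ref2)
print(f"omega       = {est.omega:.4f}")
print(f"informative = {est.n_informative}, mismatches = {est.n_mismatch}")
print(f"anchors     = {est.n_anchors}, window = {est.window}")
```

prints

```
omega       = 0.3141
informative = 38, mismatches = 0
anchors     = 132, window = (20, 600)
```

i.e. a 30% variant-1 mixture is recovered to within ~0.015 at 1% noise and
independent per-run time warps, using 38 divergent positions and 132 anchor
points. The same pipeline is available from the shell:

```sh
sangermix simulate --length 650 --n-diff 40 --omega 0.3 --seed 1 --outdir run/
sangermix quantify --mixed run/mixed.json --ref1 run/ref1.json --ref2 run/ref2.json
sangermix fluor --input readings.tsv          # TSV: sample, promoter, red, green
sangermix recover --ratios 0,0.1,0.3,0.5,0.7,0.9,1 --reps 3 --seed 1
```

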