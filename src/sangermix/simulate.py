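"""Synthetic chromatogram generation with known ground-truth mixing fraction.

Each base contributes a Gaussian peak on its channel; peak amplitude decays
exponentially along the read (polymerase termination kinetics), peak centers
drift by run-specific monotone piecewise-linear time warps (capillary
migration speed), channels leak into spectral neighbours through a crosstalk
matrix, and truncated Gaussian noise is added per sample per channel.

A mixture read is the convex combination ``omega * signal(seq1) + (1-omega)
* signal(seq2)`` of the two pure signals under one shared warp and decay
(both templates run in the same reaction), with noise added afterwards;
reference reads are generated as independent runs with their own warps,
decays and noise.

Default parameter values model a routine capillary run: ~12 samples between
peaks, peak sd 2 samples, initial peak amplitude 7000 with a 1.5e-3 per-base
decay, additive noise sd 70 (1% of the initial amplitude) and 1% leakage
between spectrally adjacent dye channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import DegenerateDesignError, SangermixError, ValidationError
from .ratio import RatioEstimate, quantify
from .traces import CHANNEL_ORDER, Chromatogram

_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}


def default_crosstalk(leak: float = 0.01) -> np.ndarray:
    """Crosstalk matrix with ``leak`` between spectrally adjacent channels.

    Row = source base, column = observed channel, in G, A, T, C order.
    """
    x = np.eye(4)
    for i in range(3):
        x[i, i + 1] = leak
        x[i + 1, i] = leak
    return x


@dataclass
class SimSpec:
    """Parameters of one simulated sequencing run.

    ``warp_knots`` is a monotone piecewise-linear map from nominal to actual
    sample time, given as (nominal, actual) pairs; ``None`` means no drift.
    Peaks must be resolvable: ``peak_spacing > 4 * peak_width``.
    """

    peak_spacing: float = 12.0
    spacing_jitter: float = 0.5
    peak_width: float = 2.0
    amp0: float = 7000.0
    decay: float = 0.0015
    noise_sd: float = 70.0
    crosstalk: np.ndarray | None = None
    warp_knots: Sequence[tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crosstalk is None:
            self.crosstalk = default_crosstalk()
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        if self.peak_spacing <= 4 * self.peak_width:
            raise ValidationError("peak_spacing must exceed 4 * peak_width")
        if self.decay < 0 or self.noise_sd < 0 or self.spacing_jitter < 0:
            raise ValidationError("decay, noise_sd, spacing_jitter must be >= 0")
        if self.crosstalk.shape != (4, 4) or np.any(self.crosstalk < 0):
            raise ValidationError("crosstalk must be a nonnegative 4x4 matrix")
        if np.any(self.crosstalk.sum(axis=1) > 1.1):
            raise ValidationError("crosstalk row sums must be <= 1.1")
        if self.warp_knots is not None:
            knots = np.asarray(self.warp_knots, dtype=float)
            if knots.ndim != 2 or knots.shape[1] != 2 or knots.shape[0] < 2:
                raise ValidationError("warp_knots must be >= 2 (nominal, actual) pairs")
            if np.any(np.diff(knots[:, 0]) <= 0) or np.any(np.diff(knots[:, 1]) <= 0):
                raise ValidationError("warp must be strictly increasing")


def make_warp_knots(
    rng: np.random.Generator,
    length: float,
    n_segments: int = 4,
    strength: float = 0.05,
) -> list[tuple[float, float]]:
    """Random monotone piecewise-linear warp over ``[0, length]``.

    Segment slopes are drawn uniformly from ``1 +/- strength``; ``strength``
    around 0.05 gives the mild run-to-run drift of a well-behaved capillary.
    """
    u = np.linspace(0.0, length, n_segments + 1)
    slopes = 1.0 + rng.uniform(-strength, strength, n_segments)
    v = np.concatenate([[0.0], np.cumsum(slopes * np.diff(u))])
    return list(zip(u.tolist(), v.tolist()))


def _apply_warp(times: np.ndarray, knots: Sequence[tuple[float, float]] | None) -> np.ndarray:
    if knots is None:
        return times
    k = np.asarray(knots, dtype=float)
    u, v = k[:, 0], k[:, 1]
    out = np.interp(times, u, v)
    # linear extrapolation beyond the knot range (np.interp clamps)
    lo_slope = (v[1] - v[0]) / (u[1] - u[0])
    hi_slope = (v[-1] - v[-2]) / (u[-1] - u[-2])
    below = times < u[0]
    above = times > u[-1]
    out[below] = v[0] + (times[below] - u[0]) * lo_slope
    out[above] = v[-1] + (times[above] - u[-1]) * hi_slope
    return out


def _validate_seq(seq: str) -> None:
    if not seq:
        raise ValidationError("sequence must be non-empty")
    if len(seq) > 1500:
        raise ValidationError("sequence longer than 1500 bases")
    bad = set(seq) - set(CHANNEL_ORDER)
    if bad:
        raise ValidationError(f"sequence contains non-GATC letters: {sorted(bad)}")


def _peak_centers(n: int, spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    gaps = rng.normal(spec.peak_spacing, spec.spacing_jitter, n)
    gaps = np.clip(gaps, 0.6 * spec.peak_spacing, 1.4 * spec.peak_spacing)
    centers = 3.0 * spec.peak_spacing + np.cumsum(gaps)
    return _apply_warp(centers, spec.warp_knots)


def _pure_signal(seq: str, centers: np.ndarray, spec: SimSpec, n_samples: int) -> np.ndarray:
    """Noise-free 4xT signal of one template, crosstalk applied."""
    sig = np.zeros((4, n_samples))
    reach = int(np.ceil(5 * spec.peak_width))
    t_axis = np.arange(n_samples)
    for k, base in enumerate(seq):
        c = centers[k]
        amp = spec.amp0 * np.exp(-spec.decay * k)
        lo = max(0, int(np.floor(c)) - reach)
        hi = min(n_samples, int(np.ceil(c)) + reach + 1)
        t = t_axis[lo:hi]
        sig[_CHANNEL_INDEX[base], lo:hi] += amp * np.exp(
            -((t - c) ** 2) / (2.0 * spec.peak_width**2)
        )
    return spec.crosstalk.T @ sig


def _finish(
    sig: np.ndarray,
    centers: np.ndarray,
    basecalls: str,
    spec: SimSpec,
    rng: np.random.Generator,
    sample_id: str,
) -> Chromatogram:
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd, sig.shape)
    sig = np.clip(sig, 0.0, None)
    peak_times = np.rint(centers).astype(np.int64)
    if np.any(np.diff(peak_times) <= 0):
        raise ValidationError("simulated peak times not strictly increasing")
    return Chromatogram(
        channels={b: sig[i] for b, i in _CHANNEL_INDEX.items()},
        peak_times=peak_times,
        basecalls=basecalls,
        sample_id=sample_id,
    )


def simulate_trace(seq: str, spec: SimSpec) -> Chromatogram:
    """Simulate a pure-template chromatogram; deterministic under ``spec.seed``."""
    _validate_seq(seq)
    rng = np.random.default_rng(spec.seed)
    centers = _peak_centers(len(seq), spec, rng)
    n_samples = int(np.ceil(centers[-1] + 3 * spec.peak_spacing))
    sig = _pure_signal(seq, centers, spec, n_samples)
    return _finish(sig, centers, seq, spec, rng, sample_id=f"sim-{spec.seed}")


def simulate_mixture(
    seq1: str,
    seq2: str,
    omega: float,
    spec_m: SimSpec,
    spec_1: SimSpec | None = None,
    spec_2: SimSpec | None = None,
) -> tuple[Chromatogram, Chromatogram, Chromatogram]:
    """Simulate a mixed read plus two independent reference runs.

    The mixed signal is the exact convex combination of the two pure signals
    under ``spec_m``'s shared peak positions, decay and crosstalk; noise is
    added after mixing.  References default to ``spec_m`` with shifted seeds
    when no spec of their own is given (pass explicit specs to model distinct
    warps and decays).
    """
    _validate_seq(seq1)
    _validate_seq(seq2)
    if len(seq1) != len(seq2):
        raise ValidationError("seq1 and seq2 must have equal length (gap-free model)")
    if not 0.0 <= omega <= 1.0:
        raise ValidationError("omega must be in [0, 1]")
    spec_1 = spec_1 if spec_1 is not None else replace(spec_m, seed=spec_m.seed + 1)
    spec_2 = spec_2 if spec_2 is not None else replace(spec_m, seed=spec_m.seed + 2)

    rng = np.random.default_rng(spec_m.seed)
    centers = _peak_centers(len(seq1), spec_m, rng)
    n_samples = int(np.ceil(centers[-1] + 3 * spec_m.peak_spacing))
    sig = omega * _pure_signal(seq1, centers, spec_m, n_samples) + (
        1.0 - omega
    ) * _pure_signal(seq2, centers, spec_m, n_samples)
    majority = seq1 if omega >= 0.5 else seq2
    mixed = _finish(
        sig, centers, majority, spec_m, rng, sample_id=f"mix-{omega}-{spec_m.seed}"
    )
    ref1 = simulate_trace(seq1, spec_1)
    ref2 = simulate_trace(seq2, spec_2)
    return mixed, ref1, ref2


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(CHANNEL_ORDER), size=n))


def mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    """Substitute each given position with a different random base."""
    out = list(seq)
    for p in positions:
        choices = [b for b in CHANNEL_ORDER if b != out[p]]
        out[p] = str(rng.choice(choices))
    return "".join(out)


def divergent_pair(
    n: int, n_diff: int, rng: np.random.Generator, lo: int = 25, hi: int | None = None
) -> tuple[str, str]:
    """A random sequence and a copy with ``n_diff`` substitutions in ``[lo, hi)``."""
    hi = hi if hi is not None else n - 5
    if not lo < hi or n_diff > hi - lo:
        raise ValidationError("divergent positions do not fit the requested range")
    seq1 = random_sequence(n, rng)
    positions = rng.choice(np.arange(lo, hi), size=n_diff, replace=False)
    return seq1, mutate(seq1, positions.tolist(), rng)


# ---------------------------------------------------------------------------
# recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    table: pd.DataFrame
    r_squared: float
    seq1: str = ""
    seq2: str = ""


def recovery_experiment(
    ratios: Sequence[float],
    reps: int,
    *,
    n_bases: int = 650,
    n_diff: int = 40,
    base_spec: SimSpec | None = None,
    warp_strength: float = 0.05,
    decay_jitter: float = 0.2,
    seed: int = 0,
    config: RunConfig | None = None,
) -> RecoveryResult:
    """Calibration experiment: simulate mixtures over a ratio grid and quantify.

    For every (ratio, replicate) a fresh triple of runs is simulated — the
    mixed read and both references get independent seeds, independent mild
    time warps (segment slopes within ``1 +/- warp_strength``) and decays
    jittered by ``+/- decay_jitter`` around the base value — then the full
    pipeline estimates the fraction.  Returns the per-run table and the
    squared Pearson correlation of estimated versus true fraction from an
    ordinary linear regression.  Failed runs are recorded, warned about and
    excluded from the regression.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if len(set(ratios)) < 2:
        raise DegenerateDesignError(
            "degenerate design: need at least two distinct true ratios"
        )
    base = base_spec if base_spec is not None else SimSpec()
    rng = np.random.default_rng(seed)
    seq1, seq2 = divergent_pair(n_bases, n_diff, rng)
    warp_length = (n_bases + 10) * base.peak_spacing

    rows = []
    for ratio in ratios:
        for rep in range(reps):
            specs = []
            for _ in range(3):
                run_seed = int(rng.integers(2**31 - 1))
                knots = (
                    make_warp_knots(rng, warp_length, strength=warp_strength)
                    if warp_strength > 0
                    else None
                )
                decay = base.decay * (1.0 + rng.uniform(-decay_jitter, decay_jitter))
                specs.append(
                    replace(base, seed=run_seed, warp_knots=knots, decay=decay)
                )
            mixed, ref1, ref2 = simulate_mixture(seq1, seq2, ratio, *specs)
            row = {"true": ratio, "rep": rep}
            try:
                est: RatioEstimate = quantify(mixed, ref1, ref2, config)
                row.update(
                    estimated=est.omega,
                    error=est.omega - ratio,
                    n_informative=est.n_informative,
                    n_anchors=est.n_anchors,
                    ok=True,
                    message="",
                )
            except SangermixError as e:
                warnings.warn(f"quantify failed at ratio={ratio} rep={rep}: {e}")
                row.update(
                    estimated=np.nan, error=np.nan, n_informative=0,
                    n_anchors=0, ok=False, message=str(e),
                )
            rows.append(row)

    table = pd.DataFrame(rows)
    good = table[table["ok"]]
    if good["true"].nunique() < 2:
        raise DegenerateDesignError(
            "degenerate design: fewer than two distinct ratios succeeded"
        )
    import statsmodels.api as sm

    fit = sm.OLS(good["estimated"], sm.add_constant(good["true"])).fit()
    return RecoveryResult(
        table=table, r_squared=float(fit.rsquared), seq1=seq1, seq2=seq2
    )
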