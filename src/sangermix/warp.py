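"""Piecewise-linear time warping of reference traces and amplitude gains.

Sanger runs of the same template drift in time (fragments migrate at
run-specific speeds) and in amplitude (signal decays at run-specific rates).
Anchor points give the correspondence between the mixed read's time frame
and each reference's frame.  Between consecutive anchors the reference time
axis is stretched linearly so its anchor peaks land exactly on the mixed
read's anchor peaks; amplitudes at fractional sample positions are linearly
interpolated.

The per-time gains lambda1(t), lambda2(t) rescale the warped references onto
the mixed trace's amplitude scale: at each anchor the gain is the ratio of
the mixed amplitude to the warped reference amplitude on the anchor base's
channel, and between anchors the gain is the linear interpolation of the two
anchor ratios.  Anchors with zero reference amplitude are skipped; the
interpolation bridges to the next usable anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AnchorPoint
from .errors import NoGainAnchorsError, ValidationError
from .traces import CHANNEL_ORDER, Chromatogram


@dataclass
class WarpedTrace:
    """A reference trace resampled onto the mixed read's grid.

    Defined exactly on the closed anchor span ``[t0, t0 + len - 1]`` of the
    mixed frame.
    """

    channels: dict[str, np.ndarray]
    t0: int
    source_id: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.channels[CHANNEL_ORDER[0]])

    @property
    def t_end(self) -> int:
        return self.t0 + self.n_samples - 1

    def amp(self, base: str, t: int | np.ndarray) -> float | np.ndarray:
        return self.channels[base][np.asarray(t) - self.t0]


@dataclass
class AmplitudeScale:
    """Per-time gains for the two warped references, on the same grid."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    t0: int

    def gain1(self, t: int | np.ndarray):
        return self.lambda1[np.asarray(t) - self.t0]

    def gain2(self, t: int | np.ndarray):
        return self.lambda2[np.asarray(t) - self.t0]


def _anchor_times(anchors: list[AnchorPoint], frame: str) -> tuple[np.ndarray, np.ndarray]:
    t_m = np.array([a.t_m for a in anchors], dtype=float)
    if frame == "p1":
        t_r = np.array([a.t_p1 for a in anchors], dtype=float)
    elif frame == "p2":
        t_r = np.array([a.t_p2 for a in anchors], dtype=float)
    else:
        raise ValidationError(f"frame must be 'p1' or 'p2', got {frame!r}")
    return t_m, t_r


def time_stretch(
    ref: Chromatogram, anchors: list[AnchorPoint], frame: str
) -> WarpedTrace:
    """Warp a reference trace into the mixed read's time frame.

    For mixed-frame times between consecutive anchors, the reference is
    evaluated at the linearly interpolated reference-frame time (exact at the
    anchors themselves); values at fractional reference positions are linear
    interpolations of adjacent samples.
    """
    if len(anchors) < 2:
        raise ValidationError("time_stretch needs at least 2 anchors")
    t_m, t_r = _anchor_times(anchors, frame)
    if np.any(np.diff(t_m) <= 0) or np.any(np.diff(t_r) <= 0):
        raise ValidationError("anchor times must strictly increase in both frames")

    grid = np.arange(int(t_m[0]), int(t_m[-1]) + 1)
    ref_positions = np.interp(grid, t_m, t_r)
    sample_axis = np.arange(ref.n_samples)
    channels = {
        b: np.interp(ref_positions, sample_axis, ref.channels[b])
        for b in CHANNEL_ORDER
    }
    return WarpedTrace(channels=channels, t0=int(t_m[0]), source_id=ref.sample_id)


def amplitude_scale(
    m: Chromatogram,
    w1: WarpedTrace,
    w2: WarpedTrace,
    anchors: list[AnchorPoint],
) -> AmplitudeScale:
    """Interpolated gain series for both warped references.

    Gains are computed from the anchor base's channel only — anchors are
    single-peak by construction, so that channel is the one carrying signal.
    """
    if len(anchors) < 2:
        raise ValidationError("amplitude_scale needs at least 2 anchors")
    t0 = min(w1.t0, w2.t0)
    t_end = max(w1.t_end, w2.t_end)
    grid = np.arange(t0, t_end + 1, dtype=float)

    def _gains(w: WarpedTrace) -> np.ndarray:
        ts: list[float] = []
        ratios: list[float] = []
        for a in anchors:
            if not (w.t0 <= a.t_m <= w.t_end):
                continue
            denom = float(w.amp(a.base, a.t_m))
            if denom <= 0:
                continue  # skipped; interpolation bridges over it
            ts.append(float(a.t_m))
            ratios.append(float(m.channels[a.base][a.t_m]) / denom)
        if not ts:
            raise NoGainAnchorsError("no usable gain anchors (all zero-denominator)")
        return np.interp(grid, np.asarray(ts), np.asarray(ratios))

    return AmplitudeScale(lambda1=_gains(w1), lambda2=_gains(w2), t0=t0)
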