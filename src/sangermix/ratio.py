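"""Mixture-fraction estimation and the end-to-end quantification pipeline.

The mixed trace is modelled, per channel and time, as the convex combination

    b_M(t) = omega * lambda1(t) * b_P1w(t) + (1 - omega) * lambda2(t) * b_P2w(t)

of the two warped, gain-corrected reference traces, where omega in [0, 1] is
the fraction of variant 1 in the template mixture.  omega is obtained by
least squares over the sample points supporting the *informative* columns —
aligned positions inside the quality window where the references diverge and
the mixed read's peaks are consistent with the reference pair.  The normal
equation of the quadratic objective gives the closed form

    omega* = sum (b_M - g2) (g1 - g2) / sum (g1 - g2)^2,
    g1 = lambda1 * b_P1w,   g2 = lambda2 * b_P2w,

clamped to [0, 1]; the reported residual is the objective at the clamped
optimum.  Columns where neither mixed peak matches a reference base are
mismatches: counted, never used.

Divergent columns where the mixed read shows a single peak matching one
reference are retained as informative — they are exactly what a strongly
unbalanced mixture (omega near 0 or 1) produces, and the least-squares model
handles them naturally (the missing component's amplitude is ~0).
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentColumn, ThreeWayAlignment, align_traces, select_anchors
from .config import RunConfig
from .errors import DegenerateContrastError, DivergenceError, SangermixError
from .peaks import call_peaks
from .traces import Chromatogram, trim
from .warp import AmplitudeScale, WarpedTrace, amplitude_scale, time_stretch


@dataclass
class RatioEstimate:
    """Result of a mixture quantification.

    ``omega`` is the estimated fraction of variant 1; ``residual`` the
    least-squares objective at the optimum; ``per_column`` a diagnostic list
    of (absolute column index, column-local omega) pairs.
    """

    omega: float
    residual: float
    n_informative: int
    n_mismatch: int
    window: tuple[int, int]
    n_anchors: int = 0
    alignment_scores: tuple[float, float] = (0.0, 0.0)
    clamped: bool = False
    per_column: list[tuple[int, float]] = field(default_factory=list)
    config: dict | None = None

    def to_dict(self) -> dict:
        return {
            "omega": self.omega,
            "residual": self.residual,
            "n_informative": self.n_informative,
            "n_mismatch": self.n_mismatch,
            "window": list(self.window),
            "n_anchors": self.n_anchors,
            "alignment_scores": list(self.alignment_scores),
            "clamped": self.clamped,
            "per_column": [[i, w] for i, w in self.per_column],
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# informative columns
# ---------------------------------------------------------------------------

def informative_columns(
    alignment: ThreeWayAlignment | list[AlignmentColumn],
    window: tuple[int, int] = (20, 600),
    call_offset: int = 0,
) -> tuple[list[AlignmentColumn], int]:
    """Split window columns into informative columns and a mismatch count.

    A column is informative when it has no gaps, its absolute mixed-read
    position lies in ``[window[0], window[1]]``, the references diverge
    (p1 != p2), and every mixed peak (one or two) belongs to {p1, p2}.
    Columns where *neither* peak matches are mismatches, counted separately.
    Divergent columns where only one of two peaks matches are ignored
    entirely (neither informative nor mismatch).

    Raises :class:`DivergenceError` when no informative column exists.
    """
    cols = alignment.columns if isinstance(alignment, ThreeWayAlignment) else alignment
    kept: list[AlignmentColumn] = []
    n_mismatch = 0
    for col in cols:
        if col.m_index is None or col.p1_index is None or col.p2_index is None:
            continue
        abs_index = col.m_index + call_offset
        if not window[0] <= abs_index <= window[1]:
            continue
        if col.p1_base == col.p2_base:
            continue
        refs = {col.p1_base, col.p2_base}
        peaks = {col.m_primary}
        if col.m_secondary is not None:
            peaks.add(col.m_secondary)
        if not peaks & refs:
            n_mismatch += 1
            continue
        if peaks <= refs:
            kept.append(col)
    if not kept:
        raise DivergenceError("sequences do not diverge in window")
    return kept, n_mismatch


# ---------------------------------------------------------------------------
# least-squares estimator
# ---------------------------------------------------------------------------

def _support_arrays(
    m: Chromatogram,
    w1: WarpedTrace,
    w2: WarpedTrace,
    scale: AmplitudeScale,
    informative: list[AlignmentColumn],
    half_width: int,
    mode: str = "informative",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, slice]]]:
    """Stack (b_M, g1, g2) sample vectors over the integration support."""
    t_lo = max(w1.t0, w2.t0, scale.t0)
    t_hi = min(w1.t_end, w2.t_end, scale.t0 + len(scale.lambda1) - 1)
    ys, g1s, g2s = [], [], []
    spans: list[tuple[int, slice]] = []
    pos = 0

    def _collect(ts: np.ndarray, bases: tuple[str, ...]):
        nonlocal pos
        start = pos
        for b in bases:
            ys.append(m.channels[b][ts])
            g1s.append(scale.gain1(ts) * np.asarray(w1.amp(b, ts)))
            g2s.append(scale.gain2(ts) * np.asarray(w2.amp(b, ts)))
            pos += len(ts)
        return slice(start, pos)

    if mode == "full":
        ts = np.arange(t_lo, t_hi + 1)
        spans.append((-1, _collect(ts, ("G", "A", "T", "C"))))
    else:
        for col in informative:
            t = int(m.peak_times[col.m_index])
            ts = np.arange(max(t - half_width, t_lo), min(t + half_width, t_hi) + 1)
            if ts.size == 0:
                continue
            spans.append((col.m_index, _collect(ts, (col.p1_base, col.p2_base))))
    if not ys:
        raise DegenerateContrastError(
            "no informative support inside the warped anchor span"
        )
    return np.concatenate(ys), np.concatenate(g1s), np.concatenate(g2s), spans


def _solve(y: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, bool]:
    d = g1 - g2
    denom = float(np.dot(d, d))
    if denom <= 0.0:
        raise DegenerateContrastError(
            "degenerate contrast: references indistinguishable on support"
        )
    raw = float(np.dot(y - g2, d)) / denom
    omega = min(1.0, max(0.0, raw))
    resid = y - omega * g1 - (1.0 - omega) * g2
    return omega, float(np.dot(resid, resid)), omega != raw


def estimate_omega(
    m: Chromatogram,
    w1: WarpedTrace,
    w2: WarpedTrace,
    scale: AmplitudeScale,
    informative: list[AlignmentColumn],
    half_width: int | None = None,
    mode: str = "informative",
    window: tuple[int, int] = (20, 600),
) -> RatioEstimate:
    """Closed-form least-squares estimate of the mixture fraction.

    The objective is summed over sample points within ``half_width`` samples
    of each informative column's mixed peak time (default: half the median
    peak spacing), on the two divergent bases' channels; ``mode="full"``
    integrates all four channels over the whole warped span instead.
    """
    if not informative and mode != "full":
        raise DivergenceError("no informative columns given")
    if half_width is None:
        spacing = float(np.median(np.diff(m.peak_times))) if m.n_calls > 1 else 12.0
        half_width = max(1, int(spacing // 2))
    y, g1, g2, spans = _support_arrays(m, w1, w2, scale, informative, half_width, mode)
    omega, residual, clamped = _solve(y, g1, g2)

    per_column: list[tuple[int, float]] = []
    for m_index, span in spans:
        if m_index < 0:
            continue
        try:
            w, _, _ = _solve(y[span], g1[span], g2[span])
        except DegenerateContrastError:
            w = float("nan")
        per_column.append((m_index, w))

    return RatioEstimate(
        omega=omega,
        residual=residual,
        n_informative=len(informative),
        n_mismatch=0,
        window=window,
        clamped=clamped,
        per_column=per_column,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@contextmanager
def _stage(name: str):
    try:
        yield
    except SangermixError as e:
        if e.stage is None:
            e.stage = name
            e.args = (f"{name}: {e.args[0] if e.args else ''}",) + e.args[1:]
        raise


def quantify(
    mixed: Chromatogram,
    ref1: Chromatogram,
    ref2: Chromatogram,
    config: RunConfig | None = None,
) -> RatioEstimate:
    """Run the full pipeline: trim, peak-call, align, anchor, warp, estimate.

    Any stage failure propagates as a :class:`SangermixError` whose message
    and ``stage`` attribute name the failing stage.
    """
    cfg = config or RunConfig()

    with _stage("trim"):
        m = trim(mixed, *cfg.trim)
        r1 = trim(ref1, *cfg.trim)
        r2 = trim(ref2, *cfg.trim)

    with _stage("peak_calling"):
        m_calls = call_peaks(m, cfg.rel_threshold, cfg.abs_threshold)
        r1_calls = call_peaks(r1, cfg.rel_threshold, cfg.abs_threshold)
        r2_calls = call_peaks(r2, cfg.rel_threshold, cfg.abs_threshold)

    with _stage("alignment"):
        alignment = align_traces(
            m_calls, r1_calls, r2_calls,
            gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
            gap_vs_mixed=cfg.gap_vs_mixed,
        )

    with _stage("anchors"):
        anchors = select_anchors(
            alignment, m, r1, r2,
            purity=cfg.purity_threshold, min_anchors=cfg.min_anchors,
        )

    with _stage("warping"):
        w1 = time_stretch(r1, anchors, "p1")
        w2 = time_stretch(r2, anchors, "p2")
        scale = amplitude_scale(m, w1, w2, anchors)

    with _stage("informative_columns"):
        informative, n_mismatch = informative_columns(
            alignment, cfg.window, call_offset=m.call_offset
        )

    with _stage("estimation"):
        est = estimate_omega(
            m, w1, w2, scale, informative,
            mode=cfg.integration, window=cfg.window,
        )

    est.n_mismatch = n_mismatch
    est.n_anchors = len(anchors)
    est.alignment_scores = (alignment.score_p1, alignment.score_p2)
    est.per_column = [(i + m.call_offset, w) for i, w in est.per_column]
    est.config = cfg.to_dict()
    return est
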