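"""Global alignment of the mixed read against each reference and anchor selection.

The mixed read is base-called in the extended alphabet (two-peak positions
get a two-base IUPAC letter) and aligned globally against each single-variant
reference read.  The two pairwise alignments are merged on mixed-read
positions into three-way columns.

Column scoring follows a two-peak-aware scheme.  For a merged three-way
column with mixed primary/secondary peaks and reference bases p1, p2:

* ``1``    — mixed single peak matching both references (p1 == p2),
* ``2``    — mixed single peak at a divergent column (p1 != p2) matching
  exactly one reference,
* ``0.85`` — mixed two peaks exactly matching the divergent pair {p1, p2},
* ``0.75`` — mixed two peaks of which exactly one matches a reference,
* ``0``    — mismatch,
* ``-1``   — mixed position aligned to a gap in *both* references,
* ``-2``   — gap opened or extended in a pairwise alignment.

The pairwise aligner cannot see both references at once, so it uses the
single-reference projection of the scheme (plain match 1, extended letter
containing the reference base 0.85, else 0; linear gap penalty -2).  The
merged columns are then re-scored with the full two-reference rule above.

Anchor points — columns where both references carry the same base, both
reference positions are pure, and the mixed read shows a single peak — tie
the three time frames together for the downstream warping.  At least five
anchors are required; fewer is a hard failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InsufficientAnchorsError, ValidationError
from .peaks import EXTENDED_ALPHABET, PeakCall, decode_extended, encode_extended, primary_sequence, purity_ok
from .traces import Chromatogram

MIN_READ_BASES = 5


@dataclass(frozen=True)
class AlignmentColumn:
    """One merged three-way column, keyed by mixed-read position."""

    m_index: int | None
    p1_index: int | None
    p2_index: int | None
    m_primary: str | None
    m_secondary: str | None
    p1_base: str | None
    p2_base: str | None
    score: float


@dataclass(frozen=True)
class AnchorPoint:
    """A column registering the three time frames.

    Carries the shared reference base and the peak time of the column in the
    mixed (``t_m``), reference-1 (``t_p1``) and reference-2 (``t_p2``) frames.
    """

    m_index: int
    p1_index: int
    p2_index: int
    base: str
    t_m: int
    t_p1: int
    t_p2: int


@dataclass
class ThreeWayAlignment:
    columns: list[AlignmentColumn]
    score_p1: float
    score_p2: float

    def __iter__(self):
        return iter(self.columns)

    def __len__(self):
        return len(self.columns)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_column(
    m_primary: str, m_secondary: str | None, p1: str, p2: str
) -> float:
    """Match score of a gap-free three-way column (see module docstring)."""
    refs = {p1, p2}
    if m_secondary is None:
        if p1 == p2:
            return 1.0 if m_primary == p1 else 0.0
        return 2.0 if m_primary in refs else 0.0
    peaks = {m_primary, m_secondary}
    if p1 != p2 and peaks == refs:
        return 0.85
    if peaks & refs:
        return 0.75
    return 0.0


def projection_score(m_letter: str, ref_letter: str) -> float:
    """Pairwise (single-reference) projection of the column score."""
    sm = decode_extended(m_letter)
    sr = decode_extended(ref_letter)
    if len(sm) == 1 and len(sr) == 1:
        return 1.0 if m_letter == ref_letter else 0.0
    return 0.85 if sm & sr else 0.0


@lru_cache(maxsize=1)
def _projection_matrix() -> substitution_matrices.Array:
    mat = substitution_matrices.Array(alphabet=EXTENDED_ALPHABET, dims=2)
    for x in EXTENDED_ALPHABET:
        for y in EXTENDED_ALPHABET:
            mat[x, y] = projection_score(x, y)
    return mat


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _projection_matrix()
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    m_seq: str,
    ref_seq: str,
    gap_open: float = -2.0,
    gap_extend: float = -2.0,
) -> tuple[dict[int, int], float]:
    """Globally align an extended-alphabet read against a plain reference.

    Returns the mapping ``mixed position -> reference position`` over aligned
    (non-gap) pairs, and the optimal alignment score.
    """
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(m_seq, ref_seq)[0]
    mapping: dict[int, int] = {}
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        for offset in range(te - ts):
            mapping[ts + offset] = qs + offset
    return mapping, float(alignment.score)


# ---------------------------------------------------------------------------
# three-way merge
# ---------------------------------------------------------------------------

def align_traces(
    m_calls: list[PeakCall],
    p1_calls: list[PeakCall],
    p2_calls: list[PeakCall],
    gap_open: float = -2.0,
    gap_extend: float = -2.0,
    gap_vs_mixed: float = -1.0,
) -> ThreeWayAlignment:
    """Align the mixed read to both references and merge on mixed positions.

    References are taken as their primary base calls (single-peak reads by
    assumption); the mixed read as its extended-alphabet encoding.
    """
    for name, calls in (("mixed", m_calls), ("ref1", p1_calls), ("ref2", p2_calls)):
        if len(calls) < MIN_READ_BASES:
            raise ValidationError(
                f"{name} read has {len(calls)} bases; need >= {MIN_READ_BASES}"
            )
    m_seq = encode_extended(m_calls)
    p1_seq = primary_sequence(p1_calls)
    p2_seq = primary_sequence(p2_calls)

    map1, score1 = align_pair(m_seq, p1_seq, gap_open, gap_extend)
    map2, score2 = align_pair(m_seq, p2_seq, gap_open, gap_extend)

    columns: list[AlignmentColumn] = []
    for k, call in enumerate(m_calls):
        i1 = map1.get(k)
        i2 = map2.get(k)
        p1_base = p1_calls[i1].primary_base if i1 is not None else None
        p2_base = p2_calls[i2].primary_base if i2 is not None else None
        if i1 is None and i2 is None:
            score = gap_vs_mixed
        elif i1 is None or i2 is None:
            ref = p1_base if p1_base is not None else p2_base
            score = projection_score(encode_extended([call]), ref)  # type: ignore[arg-type]
        else:
            score = score_column(call.primary_base, call.secondary_base, p1_base, p2_base)
        columns.append(
            AlignmentColumn(
                m_index=k,
                p1_index=i1,
                p2_index=i2,
                m_primary=call.primary_base,
                m_secondary=call.secondary_base,
                p1_base=p1_base,
                p2_base=p2_base,
                score=score,
            )
        )
    return ThreeWayAlignment(columns=columns, score_p1=score1, score_p2=score2)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def select_anchors(
    alignment: ThreeWayAlignment | list[AlignmentColumn],
    c_m: Chromatogram,
    c_p1: Chromatogram,
    c_p2: Chromatogram,
    purity: float = 0.028,
    min_anchors: int = 5,
) -> list[AnchorPoint]:
    """Select anchor points from the merged columns.

    A column qualifies when it has no gaps, both references carry the same
    base, both reference positions pass the purity test, the mixed read is
    single-peak there, and the anchor base carries nonzero signal in all
    three traces.  Columns breaking strict time increase in any frame are
    dropped greedily (keeping the earlier anchor), since the piecewise-linear
    warp needs monotone segments.
    """
    cols = alignment.columns if isinstance(alignment, ThreeWayAlignment) else alignment
    m_calls_by_index = {int(k): int(t) for k, t in enumerate(c_m.peak_times)}

    anchors: list[AnchorPoint] = []
    for col in cols:
        if col.m_index is None or col.p1_index is None or col.p2_index is None:
            continue
        if col.p1_base != col.p2_base or col.p1_base is None:
            continue
        if col.m_secondary is not None:
            continue
        if not purity_ok(c_p1, col.p1_index, purity):
            continue
        if not purity_ok(c_p2, col.p2_index, purity):
            continue
        base = col.p1_base
        t_m = m_calls_by_index[col.m_index]
        t_p1 = int(c_p1.peak_times[col.p1_index])
        t_p2 = int(c_p2.peak_times[col.p2_index])
        # zero-signal columns carry no registration information
        if c_p1.amp(base, t_p1) <= 0 or c_p2.amp(base, t_p2) <= 0:
            continue
        if np.all(c_m.column(t_m) == 0):
            continue
        anchors.append(
            AnchorPoint(
                m_index=col.m_index,
                p1_index=col.p1_index,
                p2_index=col.p2_index,
                base=base,
                t_m=t_m,
                t_p1=t_p1,
                t_p2=t_p2,
            )
        )

    # greedy monotonicity repair across all three frames
    kept: list[AnchorPoint] = []
    for a in anchors:
        if kept:
            prev = kept[-1]
            if a.t_m <= prev.t_m or a.t_p1 <= prev.t_p1 or a.t_p2 <= prev.t_p2:
                continue
        kept.append(a)

    if len(kept) < min_anchors:
        raise InsufficientAnchorsError(
            f"insufficient anchor points: {len(kept)} < {min_anchors}"
        )
    return kept
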