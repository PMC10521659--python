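"""Column scoring, global alignment versus an exhaustive DP oracle, anchors."""

from functools import lru_cache

import numpy as np
import pytest

from sangermix import (
    InsufficientAnchorsError,
    SimSpec,
    ValidationError,
    align_pair,
    align_traces,
    score_column,
    select_anchors,
    simulate_mixture,
)
from sangermix.align import projection_score
from sangermix.peaks import call_peaks

from helpers import make_chromatogram, threshold_fixed_point


def oracle_score(m_seq: str, ref_seq: str, gap: float = -2.0) -> float:
    """Independent exhaustive-DP optimal global alignment score.

    Plain memoized recursion over (i, j): substitute, or gap either sequence
    at linear cost.  Kept free of any package alignment machinery except the
    published per-pair substitution score.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(m_seq) and j == len(ref_seq):
            return 0.0
        options = []
        if i < len(m_seq) and j < len(ref_seq):
            options.append(projection_score(m_seq[i], ref_seq[j]) + best(i + 1, j + 1))
        if i < len(m_seq):
            options.append(gap + best(i + 1, j))
        if j < len(ref_seq):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestScoreColumn:
    @pytest.mark.parametrize(
        "m1,m2,p1,p2,expected",
        [
            ("G", None, "G", "G", 1.0),   # single peak matching both refs
            ("G", None, "G", "T", 2.0),   # single peak at a divergent column
            ("G", None, "T", "G", 2.0),   # ... either assignment
            ("G", "T", "G", "T", 0.85),   # two peaks matching the pair
            ("T", "G", "G", "T", 0.85),   # ... swap-invariant
            ("G", "T", "G", "C", 0.75),   # one of two peaks matches
            ("G", "T", "G", "G", 0.75),   # identical refs, one peak matches
            ("A", None, "G", "T", 0.0),   # mismatch, single peak
            ("A", "C", "G", "T", 0.0),    # mismatch, two peaks
            ("A", None, "G", "G", 0.0),   # mismatch against identical refs
        ],
    )
    def test_published_scoring_table(self, m1, m2, p1, p2, expected):
        assert score_column(m1, m2, p1, p2) == expected


class TestAlignPair:
    def test_identical_sequences_score_length(self):
        seq = "GATTACAGATTACAGATTACAGATTACAGA"
        mapping, score = align_pair(seq, seq)
        assert score == len(seq)
        assert mapping == {i: i for i in range(len(seq))}

    def test_single_deletion_costs_one_gap(self):
        seq = "GATTACAGATTACAGATTACAGATTACAGA"
        deleted = seq[:10] + seq[11:]
        _, score = align_pair(deleted, seq)
        assert score == (len(seq) - 1) * 1.0 - 2.0

    def test_extended_letter_scores_085(self):
        _, score = align_pair("GATKC", "GATGC")
        assert score == 4 + 0.85

    def test_matches_exhaustive_oracle_on_random_pairs(self, rng):
        """Optimal scores agree with an independent DP on >= 200 short pairs."""
        alphabet = list("GATCRYSWKM")
        n_checked = 0
        for _ in range(220):
            lm = int(rng.integers(1, 9))
            lr = int(rng.integers(1, 9))
            m_seq = "".join(rng.choice(alphabet, lm))
            ref_seq = "".join(rng.choice(list("GATC"), lr))
            _, score = align_pair(m_seq, ref_seq)
            assert score == pytest.approx(oracle_score(m_seq, ref_seq), abs=1e-9)
            n_checked += 1
        assert n_checked >= 200


class TestAlignTraces:
    def _triple(self, columns_m, columns_1, columns_2):
        return (
            call_peaks(make_chromatogram(columns_m)),
            call_peaks(make_chromatogram(columns_1)),
            call_peaks(make_chromatogram(columns_2)),
        )

    def test_identical_single_peak_reads(self):
        cols = [(1000, 0, 0, 0)] * 30
        m, p1, p2 = self._triple(cols, cols, cols)
        aln = align_traces(m, p1, p2)
        assert len(aln) == 30
        assert all(c.score == 1.0 for c in aln.columns)
        assert aln.score_p1 == 30 and aln.score_p2 == 30

    def test_two_peak_divergent_column_scores_085(self):
        base = [(1000, 0, 0, 0)] * 10
        mixed = base[:5] + [(600, 0, 400, 0)] + base[5:]
        ref1 = base[:5] + [(1000, 0, 0, 0)] + base[5:]
        ref2 = base[:5] + [(0, 0, 1000, 0)] + base[5:]
        m, p1, p2 = self._triple(mixed, ref1, ref2)
        aln = align_traces(m, p1, p2)
        assert aln.columns[5].score == 0.85

    def test_short_read_rejected(self):
        cols = [(1000, 0, 0, 0)] * 4
        m, p1, p2 = self._triple(cols, cols, cols)
        with pytest.raises(ValidationError):
            align_traces(m, p1, p2)


class TestSelectAnchors:
    def _anchor_setup(self, n_identical):
        cols = [(1000, 0, 0, 0)] * n_identical
        c_m = make_chromatogram(cols)
        c_p1 = make_chromatogram(cols)
        c_p2 = make_chromatogram(cols)
        aln = align_traces(call_peaks(c_m), call_peaks(c_p1), call_peaks(c_p2))
        return aln, c_m, c_p1, c_p2

    def test_six_pure_columns_give_six_anchors(self):
        aln, c_m, c_p1, c_p2 = self._anchor_setup(6)
        anchors = select_anchors(aln, c_m, c_p1, c_p2)
        assert len(anchors) == 6
        for frame in ("t_m", "t_p1", "t_p2"):
            times = [getattr(a, frame) for a in anchors]
            assert all(b > a for a, b in zip(times, times[1:]))

    def test_four_columns_insufficient(self):
        aln, c_m, c_p1, c_p2 = self._anchor_setup(5)
        # drop one candidate by making ref1 impure there
        c_p1.channels["A"][c_p1.peak_times[2]] = 100.0
        with pytest.raises(InsufficientAnchorsError):
            select_anchors(aln, c_m, c_p1, c_p2)

    def test_purity_boundary_excludes_anchor(self):
        """A reference secondary channel at exactly 2.8% of the column sum
        disqualifies the anchor; just below keeps it."""
        aln, c_m, c_p1, c_p2 = self._anchor_setup(6)
        t = int(c_p1.peak_times[3])
        a = threshold_fixed_point(1000.0, 0.028)  # a == 0.028 * (1000 + a)
        c_p1.channels["A"][t] = a
        assert len(select_anchors(aln, c_m, c_p1, c_p2)) == 5
        c_p1.channels["A"][t] = np.nextafter(a, 0)
        assert len(select_anchors(aln, c_m, c_p1, c_p2)) == 6

    def test_mixed_two_peak_column_not_an_anchor(self):
        aln, c_m, c_p1, c_p2 = self._anchor_setup(6)
        c_m.channels["A"][int(c_m.peak_times[2])] = 400.0
        aln = align_traces(call_peaks(c_m), call_peaks(c_p1), call_peaks(c_p2))
        assert len(select_anchors(aln, c_m, c_p1, c_p2)) == 5

    def test_deterministic(self):
        aln, c_m, c_p1, c_p2 = self._anchor_setup(8)
        a1 = select_anchors(aln, c_m, c_p1, c_p2)
        a2 = select_anchors(aln, c_m, c_p1, c_p2)
        assert a1 == a2


def test_anchor_times_increase_on_simulated_mixture(rng):
    """On realistic simulated data, anchors strictly increase in all frames."""
    from sangermix import divergent_pair, make_warp_knots, trim
    from dataclasses import replace

    seq1, seq2 = divergent_pair(120, 8, rng)
    spec = SimSpec(seed=9)
    specs = [
        replace(spec, seed=i, warp_knots=make_warp_knots(rng, 130 * 12, strength=0.05))
        for i in (1, 2, 3)
    ]
    mixed, ref1, ref2 = simulate_mixture(seq1, seq2, 0.4, *specs)
    m, r1, r2 = (trim(c, 20, 1000) for c in (mixed, ref1, ref2))
    aln = align_traces(call_peaks(m), call_peaks(r1), call_peaks(r2))
    anchors = select_anchors(aln, m, r1, r2)
    assert len(anchors) >= 5
    for frame in ("t_m", "t_p1", "t_p2"):
        times = [getattr(a, frame) for a in anchors]
        assert all(b > a for a, b in zip(times, times[1:]))
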