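"""Peak calling at base positions and the extended (two-peak) alphabet.

At each called position the primary base is the channel with the highest
amplitude.  A secondary peak is accepted only when the second-largest channel
clears both a relative threshold (a fraction of the total column signal) and
an absolute amplitude floor; the defaults (0.014 of the column sum, floor 50)
are the method's standard operating point.  A separate, stricter relative
threshold (0.028) defines "purity" of reference reads: a position is pure
when the second-largest channel stays below it.

Two-peak positions are encoded with IUPAC two-base ambiguity letters
(R, Y, S, W, K, M), which are lossless for unordered base pairs and
swap-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .traces import CHANNEL_ORDER, Chromatogram

#: unordered base pair -> IUPAC two-base ambiguity letter
PAIR_TO_CODE: dict[frozenset, str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
CODE_TO_PAIR: dict[str, frozenset] = {v: k for k, v in PAIR_TO_CODE.items()}

EXTENDED_ALPHABET = "GATCRYSWKM"


@dataclass(frozen=True)
class PeakCall:
    """Primary/secondary call at one base position.

    ``index`` is the local position in the (possibly trimmed) read;
    ``time`` the sample index of the peak.  ``secondary_base`` is ``None``
    and ``secondary_amp`` 0 for single-peak positions.
    """

    index: int
    time: int
    primary_base: str
    primary_amp: float
    secondary_base: str | None = None
    secondary_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.secondary_base is not None:
            if self.secondary_base == self.primary_base:
                raise ValidationError("secondary base equals primary base")
            if self.secondary_amp > self.primary_amp:
                raise ValidationError("secondary amplitude exceeds primary")

    @property
    def bases(self) -> frozenset:
        """The unordered set of called bases at this position."""
        if self.secondary_base is None:
            return frozenset((self.primary_base,))
        return frozenset((self.primary_base, self.secondary_base))


def _ranked_channels(amps: np.ndarray) -> list[int]:
    # descending amplitude; ties broken by fixed channel priority G, A, T, C
    return sorted(range(4), key=lambda i: (-amps[i], i))


def call_peaks(
    c: Chromatogram,
    rel_threshold: float = 0.014,
    abs_threshold: float = 50.0,
) -> list[PeakCall]:
    """Call primary and (thresholded) secondary peaks at every base position.

    A secondary peak exists iff the second-largest channel amplitude is at
    least ``rel_threshold`` times the sum of the four channel amplitudes at
    that position *and* at least ``abs_threshold``.  An all-zero column yields
    a zero-amplitude single-peak call (channel priority G).
    """
    calls: list[PeakCall] = []
    for k, t in enumerate(c.peak_times):
        amps = c.column(int(t))
        order = _ranked_channels(amps)
        primary_i, second_i = order[0], order[1]
        total = float(amps.sum())
        sec_amp = float(amps[second_i])
        has_secondary = sec_amp >= rel_threshold * total and sec_amp >= abs_threshold
        calls.append(
            PeakCall(
                index=k,
                time=int(t),
                primary_base=CHANNEL_ORDER[primary_i],
                primary_amp=float(amps[primary_i]),
                secondary_base=CHANNEL_ORDER[second_i] if has_secondary else None,
                secondary_amp=sec_amp if has_secondary else 0.0,
            )
        )
    return calls


def purity_ok(c: Chromatogram, k: int, threshold: float = 0.028) -> bool:
    """Is position ``k`` free of a secondary peak at the purity threshold?

    True iff the second-largest channel amplitude at the position's peak time
    is below ``threshold`` times the column sum.  An all-zero column counts
    as pure (no secondary signal to speak of).
    """
    if not 0 <= k < c.n_calls:
        raise ValidationError(f"position {k} outside [0, {c.n_calls})")
    amps = c.column(int(c.peak_times[k]))
    total = float(amps.sum())
    if total == 0.0:
        return True
    second = float(amps[_ranked_channels(amps)[1]])
    return second < threshold * total


def encode_base_set(bases: frozenset) -> str:
    if len(bases) == 1:
        (b,) = bases
        return b
    if len(bases) == 2:
        return PAIR_TO_CODE[bases]
    raise ValidationError(f"cannot encode base set {set(bases)}")


def decode_extended(letter: str) -> frozenset:
    """Decode an extended-alphabet letter to its unordered set of plain bases."""
    if letter in CHANNEL_ORDER:
        return frozenset((letter,))
    try:
        return CODE_TO_PAIR[letter]
    except KeyError:
        raise ValidationError(f"unknown extended letter {letter!r}") from None


def encode_extended(calls: list[PeakCall]) -> str:
    """Encode peak calls as an extended-alphabet string, one letter per position.

    Single-peak positions keep their plain base; two-peak positions get the
    IUPAC code of the unordered pair, so the encoding is invariant under
    swapping primary and secondary.
    """
    return "".join(encode_base_set(call.bases) for call in calls)


def primary_sequence(calls: list[PeakCall]) -> str:
    """Plain sequence of primary bases."""
    return "".join(call.primary_base for call in calls)
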