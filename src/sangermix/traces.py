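"""In-memory chromatogram model, JSON serialization, trimming, FASTA export.

A capillary Sanger run yields four fluorescence-versus-time series (one per
dye-labelled terminator base) plus, after vendor base calling, a list of peak
sample indices and called letters.  :class:`Chromatogram` holds exactly that.
Amplitudes are kept as floats in arbitrary fluorescence units; peak times are
integer sample indices into the channel arrays.

The native on-disk form is a small versioned JSON dialect (lossless for
floats), so the whole test battery can run on text fixtures.  AB1/ABIF input
and output live in :mod:`sangermix.abif`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ReadTooShortError, TraceParseError, ValidationError

#: channel key order; also the deterministic tie-break priority for peak calls
CHANNEL_ORDER = ("G", "A", "T", "C")

JSON_FORMAT_NAME = "sangermix-trace"
JSON_FORMAT_VERSION = 1


@dataclass
class Chromatogram:
    """Four-channel electropherogram with called peak positions.

    Parameters
    ----------
    channels
        Mapping from base letter (``G``, ``A``, ``T``, ``C``) to a 1-D
        non-negative float array; all four arrays share the length ``T``.
    peak_times
        Strictly increasing integer sample indices, one per called base.
    basecalls
        Called letters, same length as ``peak_times`` (may be empty before
        base calling).
    sample_id
        Free-text identifier.
    call_offset
        Absolute index (in the original, untrimmed read) of the first retained
        base call.  ``0`` for a fresh read; set by :func:`trim` so that
        trimming is idempotent and window bounds keep referring to positions
        of the original read.
    """

    channels: dict[str, np.ndarray]
    peak_times: np.ndarray
    basecalls: str = ""
    sample_id: str = ""
    call_offset: int = 0

    def __post_init__(self) -> None:
        self.channels = {
            b: np.asarray(self.channels[b], dtype=float) for b in CHANNEL_ORDER
        }
        self.peak_times = np.asarray(self.peak_times, dtype=np.int64)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        lengths = {b: len(a) for b, a in self.channels.items()}
        if set(self.channels) != set(CHANNEL_ORDER):
            raise ValidationError(f"channels must be keyed {CHANNEL_ORDER}")
        if len(set(lengths.values())) != 1:
            raise ValidationError(f"unequal channel lengths: {lengths}")
        T = self.n_samples
        if T == 0:
            raise ValidationError("empty trace (T=0)")
        for b, a in self.channels.items():
            if a.ndim != 1:
                raise ValidationError(f"channel {b} is not 1-D")
            if np.any(a < 0):
                raise ValidationError(f"negative amplitude in channel {b}")
        t = self.peak_times
        if t.size:
            if t.min() < 0 or t.max() >= T:
                raise ValidationError("peak_times outside [0, T)")
            if np.any(np.diff(t) <= 0):
                raise ValidationError("peak_times not strictly increasing")
        if self.basecalls and len(self.basecalls) != t.size:
            raise ValidationError("basecalls and peak_times length mismatch")

    # -- conveniences -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.channels["G"])

    @property
    def n_calls(self) -> int:
        return int(self.peak_times.size)

    def column(self, t: int) -> np.ndarray:
        """Amplitudes of the four channels at sample ``t`` (G, A, T, C order)."""
        return np.array([self.channels[b][t] for b in CHANNEL_ORDER])

    def amp(self, base: str, t: int) -> float:
        return float(self.channels[base][t])


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def trim(c: Chromatogram, first_base: int = 20, last_base: int = 1000) -> Chromatogram:
    """Restrict a read to base calls with absolute index in ``[first_base, last_base)``.

    The leading calls of a read sit in low-quality signal (and, for the
    intended two-variant assay, in sequence shared by both variants), and
    call quality degrades far into the run, so both ends are discarded by
    default.  Channel samples outside the retained span are dropped and peak
    times re-offset; ``call_offset`` records the absolute index of the first
    retained call so a second ``trim`` with the same bounds is the identity.
    """
    if first_base >= last_base:
        raise ValidationError("first_base must be < last_base")
    end_abs = c.call_offset + c.n_calls
    if end_abs <= first_base:
        raise ReadTooShortError(
            f"read too short: {c.n_calls} calls starting at {c.call_offset}, "
            f"need calls beyond index {first_base}"
        )
    lo_abs = max(first_base, c.call_offset)
    hi_abs = min(last_base, end_abs)
    if lo_abs >= hi_abs:
        raise ReadTooShortError("no calls inside the trim window")
    lo = lo_abs - c.call_offset
    hi = hi_abs - c.call_offset

    t = c.peak_times
    # cut channel samples at midpoints between the last dropped and first kept
    # peak, so the kept peaks retain their local context
    t0 = 0 if lo == 0 else int((t[lo - 1] + t[lo]) // 2 + 1)
    t1 = c.n_samples if hi == c.n_calls else int((t[hi - 1] + t[hi]) // 2 + 1)

    return Chromatogram(
        channels={b: a[t0:t1].copy() for b, a in c.channels.items()},
        peak_times=t[lo:hi] - t0,
        basecalls=c.basecalls[lo:hi] if c.basecalls else "",
        sample_id=c.sample_id,
        call_offset=lo_abs,
    )


# ---------------------------------------------------------------------------
# JSON trace dialect
# ---------------------------------------------------------------------------

def to_json_dict(c: Chromatogram) -> dict:
    return {
        "format": JSON_FORMAT_NAME,
        "version": JSON_FORMAT_VERSION,
        "sample_id": c.sample_id,
        "call_offset": c.call_offset,
        "channels": {b: c.channels[b].tolist() for b in CHANNEL_ORDER},
        "peak_times": c.peak_times.tolist(),
        "basecalls": c.basecalls,
    }


def from_json_dict(d: dict) -> Chromatogram:
    if d.get("format") != JSON_FORMAT_NAME:
        raise TraceParseError("not a sangermix trace JSON document")
    if d.get("version") != JSON_FORMAT_VERSION:
        raise TraceParseError(f"unsupported trace version {d.get('version')!r}")
    try:
        return Chromatogram(
            channels={b: d["channels"][b] for b in CHANNEL_ORDER},
            peak_times=d["peak_times"],
            basecalls=d.get("basecalls", ""),
            sample_id=d.get("sample_id", ""),
            call_offset=int(d.get("call_offset", 0)),
        )
    except KeyError as e:  # pragma: no cover - defensive
        raise TraceParseError(f"trace JSON missing key {e}") from e


def write_trace(c: Chromatogram, path: str | Path, format: str = "json") -> None:
    """Serialize a chromatogram.

    ``json`` round-trips bit-exactly; ``abif`` writes a minimal ABIF subset
    (integer-quantized amplitudes) readable by any AB1-aware tool.
    """
    c.validate()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(to_json_dict(c), fh)
    elif format == "abif":
        from .abif import write_abif  # local import: keep the modules decoupled

        write_abif(c, path)
    else:
        raise ValueError(f"unknown trace format {format!r}")


def read_trace(path: str | Path) -> Chromatogram:
    """Read a chromatogram from JSON or AB1/ABIF, sniffing the magic bytes."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"ABIF":
        from .abif import read_abif

        return read_abif(path)
    try:
        with open(path) as fh:
            return from_json_dict(json.load(fh))
    except (json.JSONDecodeError, UnicodeDecodeError) as e:
        raise TraceParseError(f"{path}: neither ABIF nor trace JSON") from e


# ---------------------------------------------------------------------------
# FASTA export
# ---------------------------------------------------------------------------

def export_fasta(
    entries: Iterable[tuple[str, str]], path: str | Path, alphabet: str = "plain"
) -> None:
    """Write (id, sequence) pairs as FASTA.

    ``alphabet="extended"`` flags in the header that two-peak positions are
    encoded with IUPAC two-base ambiguity letters.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    if alphabet not in ("plain", "extended"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = [
        SeqRecord(Seq(seq), id=name, description=f"alphabet={alphabet}")
        for name, seq in entries
    ]
    seqio_write(records, str(path), "fasta")


def with_basecalls(c: Chromatogram, basecalls: str) -> Chromatogram:
    """Return a copy of ``c`` carrying the given base calls."""
    return replace(c, basecalls=basecalls)
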