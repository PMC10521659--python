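"""AB1/ABIF chromatogram input and a minimal ABIF-subset writer.

Reading goes through ``Bio.SeqIO`` ("abi" format), which exposes every ABIF
directory entry under ``annotations["abif_raw"]``.  The tags used are the
standard analyzed-data set:

========  =======================================================
tag       content
========  =======================================================
DATA9-12  analyzed trace arrays, one per dye
FWO_1     filter-wheel order: the base letter of each DATA channel
PLOC2/1   peak sample index per called base
PBAS2/1   called bases
========  =======================================================

The channel-to-base mapping is always resolved through ``FWO_1`` — dye order
varies between instruments and is never assumed positional.  Peak-time
indices in ABIF refer to the analyzed arrays, which is why the analyzed
(DATA9-12), not raw (DATA1-4), arrays are loaded.

The writer emits only the tags above (big-endian, amplitudes quantized to
int16), which is sufficient for round-tripping synthetic traces through any
AB1-aware tool.  Re-basecalling from raw traces is out of scope: a file
without peak locations is rejected.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import TraceParseError, ValidationError
from .traces import CHANNEL_ORDER, Chromatogram

_HEADER_SIZE = 128
_DIR_ENTRY_SIZE = 28

# ABIF element types used by the writer
_ETYPE_CHAR = 2
_ETYPE_SHORT = 4


def read_abif(path: str | Path) -> Chromatogram:
    """Parse an AB1/ABIF file into a :class:`Chromatogram`.

    Raises
    ------
    TraceParseError
        On a malformed file or when a required tag is absent.  A missing
        peak-location tag means the file was never base-called; peak calling
        from raw traces is not supported.
    """
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as e:
        raise TraceParseError(f"{path}: not a readable ABIF file ({e})") from e
    raw = record.annotations.get("abif_raw", {})

    fwo = raw.get("FWO_1")
    if fwo is None:
        raise TraceParseError(f"{path}: missing channel-order tag FWO_1")
    order = fwo.decode() if isinstance(fwo, bytes) else str(fwo)
    if sorted(order) != sorted(CHANNEL_ORDER):
        raise TraceParseError(f"{path}: FWO_1 is {order!r}, expected a GATC permutation")

    channels: dict[str, np.ndarray] = {}
    for i, base in enumerate(order):
        tag = f"DATA{9 + i}"
        data = raw.get(tag)
        if data is None:
            raise TraceParseError(f"{path}: missing analyzed trace tag {tag}")
        channels[base] = np.asarray(data, dtype=float)

    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        raise TraceParseError(
            f"{path}: missing peak-location tag PLOC2/PLOC1; "
            "peak calling from raw traces is not supported"
        )
    pbas = raw.get("PBAS2", raw.get("PBAS1"))
    basecalls = ""
    if pbas is not None:
        basecalls = pbas.decode() if isinstance(pbas, bytes) else str(pbas)

    return Chromatogram(
        channels=channels,
        peak_times=np.asarray(ploc, dtype=np.int64),
        basecalls=basecalls,
        sample_id=Path(path).stem,
    )


def write_abif(c: Chromatogram, path: str | Path, fwo: str = "GATC") -> None:
    """Write a chromatogram as a minimal ABIF file.

    Amplitudes are rounded to int16 (the format's analyzed-trace element
    type), so the round trip is exact only for integer-valued traces below
    32767.  ``fwo`` selects the on-disk channel order; readers must resolve
    it through the FWO_1 tag.
    """
    c.validate()
    if sorted(fwo) != sorted(CHANNEL_ORDER):
        raise ValidationError(f"fwo must be a GATC permutation, got {fwo!r}")
    if any(np.any(c.channels[b] > 32767) for b in CHANNEL_ORDER):
        raise ValidationError("amplitude exceeds int16 range of the ABIF subset")
    if c.n_samples > 32767:
        raise ValidationError("trace longer than the int16 peak-index range")

    entries: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: bytes, number: int, etype: int, esize: int, nelem: int, payload: bytes):
        entries.append((name, number, etype, esize, nelem, payload))

    for i, base in enumerate(fwo):
        arr = np.rint(c.channels[base]).astype(">i2")
        add(b"DATA", 9 + i, _ETYPE_SHORT, 2, len(arr), arr.tobytes())
    add(b"FWO_", 1, _ETYPE_CHAR, 1, 4, fwo.encode())
    ploc = c.peak_times.astype(">i2")
    add(b"PLOC", 2, _ETYPE_SHORT, 2, len(ploc), ploc.tobytes())
    if c.basecalls:
        add(b"PBAS", 2, _ETYPE_CHAR, 1, len(c.basecalls), c.basecalls.encode())

    offset = _HEADER_SIZE
    payload_blob = b""
    dir_blob = b""
    for name, number, etype, esize, nelem, payload in entries:
        size = len(payload)
        if size <= 4:
            dir_blob += (
                struct.pack(">4sihhii", name, number, etype, esize, nelem, size)
                + payload.ljust(4, b"\0")
                + b"\0" * 4
            )
        else:
            dir_blob += (
                struct.pack(">4sihhiii", name, number, etype, esize, nelem, size, offset)
                + b"\0" * 4
            )
            payload_blob += payload
            offset += size

    tdir = (
        struct.pack(
            ">4sihhiii", b"tdir", 1, 1023, _DIR_ENTRY_SIZE,
            len(entries), _DIR_ENTRY_SIZE * len(entries), offset,
        )
        + b"\0" * 4
    )
    header = (b"ABIF" + struct.pack(">h", 101) + tdir).ljust(_HEADER_SIZE, b"\0")
    with open(path, "wb") as fh:
        fh.write(header + payload_blob + dir_blob)
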