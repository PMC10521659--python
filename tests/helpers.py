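"""Shared test helpers."""

import numpy as np

from sangermix import Chromatogram


def make_chromatogram(columns, spacing=10, sample_id="toy"):
    """Build a trace whose peak columns are exactly the given (G, A, T, C) tuples.

    Each column occupies one sample at t = spacing*(k+1); everything else is 0.
    """
    n = len(columns)
    T = spacing * (n + 1)
    channels = {b: np.zeros(T) for b in "GATC"}
    peak_times = []
    for k, col in enumerate(columns):
        t = spacing * (k + 1)
        peak_times.append(t)
        for b, amp in zip("GATC", col):
            channels[b][t] = amp
    return Chromatogram(channels=channels, peak_times=np.array(peak_times),
                        sample_id=sample_id)


def threshold_fixed_point(major: float, frac: float, iterations: int = 80) -> float:
    """Minor amplitude a solving a == frac * (major + a) in float arithmetic.

    Used to place a second channel exactly on a relative-threshold boundary.
    """
    a = frac * major
    for _ in range(iterations):
        a = frac * (major + a)
    return a
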