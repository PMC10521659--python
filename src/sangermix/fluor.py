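"""Fluorescence-based mixture fraction for the two-reporter validation system.

In the two-plasmid assay, variant 1 carries a red reporter (mCherry) and
variant 2 a green one (EGFP), both driven by the same promoter.  With bulk
red/green readings R and G of a co-transformed culture, the fraction of
variant 1 is

    omega = 1 / (1 + lambda * (G/R - beta)),

where ``lambda = R_P1 / G_P2`` calibrates the red signal of pure variant-1
cells against the green signal of pure variant-2 cells, and
``beta = G_P1 / R_P1`` is the green bleed-through of pure variant-1 cells.
Per-promoter (lambda, beta) pairs are bundled as a packaged data file.

Noisy readings can push the formula outside [0, 1]; the result is clamped
(omega is a fraction by definition).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import UnknownPromoterError, ValidationError


@dataclass(frozen=True)
class FluorescenceParams:
    """Promoter-specific calibration constants (both dimensionless)."""

    promoter: str
    lambda_: float
    beta: float

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValidationError("lambda must be > 0")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")


def _load_table() -> dict[str, FluorescenceParams]:
    text = resources.files("sangermix").joinpath("data/promoters.tsv").read_text()
    table: dict[str, FluorescenceParams] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        table[row["promoter"]] = FluorescenceParams(
            promoter=row["promoter"],
            lambda_=float(row["lambda"]),
            beta=float(row["beta"]),
        )
    return table


_TABLE: dict[str, FluorescenceParams] | None = None


def params_for_promoter(name: str) -> FluorescenceParams:
    """Bundled (lambda, beta) pair for a promoter; error lists known names."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    try:
        return _TABLE[name]
    except KeyError:
        known = ", ".join(sorted(_TABLE))
        raise UnknownPromoterError(
            f"unknown promoter {name!r}; known promoters: {known}"
        ) from None


def known_promoters() -> list[str]:
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return sorted(_TABLE)


def omega_from_fluorescence(
    red: float, green: float, params: FluorescenceParams
) -> float:
    """Mixture fraction of variant 1 from red/green readings, clamped to [0, 1].

    ``red`` must be positive; ``green`` non-negative.  When the denominator
    ``1 + lambda*(G/R - beta)`` is non-positive (extreme red dominance under
    noise) the estimate saturates at 1.
    """
    if red <= 0:
        raise ValidationError("nonpositive red signal")
    if green < 0:
        raise ValidationError("negative green signal")
    x = params.lambda_ * (green / red - params.beta)
    if 1.0 + x <= 0.0:
        return 1.0
    return min(1.0, max(0.0, 1.0 / (1.0 + x)))
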