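"""Run configuration: every tunable constant of the pipeline in one place.

Defaults are the method's standard operating point: secondary-peak relative
threshold 0.014 with absolute floor 50, reference purity threshold 0.028,
quality window at base positions 20-600, read trim to calls 20-1000, a
minimum of 5 anchor points, and linear gap penalty -2 (-1 for a mixed
position gapped in both references).
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    rel_threshold: float = 0.014
    abs_threshold: float = 50.0
    purity_threshold: float = 0.028
    window: tuple[int, int] = (20, 600)
    trim: tuple[int, int] = (20, 1000)
    min_anchors: int = 5
    gap_open: float = -2.0
    gap_extend: float = -2.0
    gap_vs_mixed: float = -1.0
    #: "informative" sums the objective over supports around informative
    #: columns only; "full" integrates over the whole quality window
    integration: str = "informative"

    def __post_init__(self) -> None:
        self.window = tuple(self.window)  # type: ignore[assignment]
        self.trim = tuple(self.trim)  # type: ignore[assignment]
        if min(self.rel_threshold, self.abs_threshold, self.purity_threshold) <= 0:
            raise ValidationError("thresholds must be positive")
        if self.min_anchors < 2:
            raise ValidationError("min_anchors must be >= 2")
        if not (self.trim[0] <= self.window[0] < self.window[1] <= self.trim[1]):
            raise ValidationError("quality window must sit inside the trim bounds")
        if self.integration not in ("informative", "full"):
            raise ValidationError(f"unknown integration mode {self.integration!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        d["trim"] = list(self.trim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a JSON or TOML key-value file."""
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
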