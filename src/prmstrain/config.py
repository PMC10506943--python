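"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import SpecificationError
from .tracking import TrackingParams

PROJECTION_MODES = ("incremental", "terminal")
ORIENTATIONS = ("right_at_s0", "left_at_s0")


@dataclass
class RunConfig:
    """All tunables of a per-subject analysis run.

    ``projection_mode`` selects how the fiber direction is tracked over
    time: ``incremental`` (default) recomputes the centerline on the
    propagated mask each frame and accumulates projected scalar
    increments (angle correction); ``terminal`` projects the fully
    accumulated 3-vector field on the rest-frame centerline once.
    """

    tracking: TrackingParams = field(default_factory=TrackingParams)
    centerline_degree: int = 5
    projection_mode: str = "incremental"
    increment_smoothing_mm: float = 2.0
    projection_smoothing_mm: float = 1.0
    end_fraction: float = 1.0 / 3.0
    orientation: str = "right_at_s0"
    max_contraction_frame: int | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.projection_mode not in PROJECTION_MODES:
            raise SpecificationError(
                f"projection_mode must be one of {PROJECTION_MODES}"
            )
        if self.orientation not in ORIENTATIONS:
            raise SpecificationError(f"orientation must be one of {ORIENTATIONS}")
        if not (0.0 < self.end_fraction < 1.0):
            raise SpecificationError("end_fraction must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise SpecificationError("alpha must lie in (0, 1)")
        if self.centerline_degree < 1:
            raise SpecificationError("centerline_degree must be >= 1")
        if self.increment_smoothing_mm < 0 or self.projection_smoothing_mm < 0:
            raise SpecificationError("smoothing scales must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tracking"]["block_size"] = list(self.tracking.block_size)
        d["tracking"]["search_radius"] = list(self.tracking.search_radius)
        return d

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        tp = d.pop("tracking", {}) or {}
        return cls(tracking=TrackingParams(**tp), **d)

    @classmethod
    def loads(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.loads(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())
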