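"""Three-region partition of the muscle and the normalized strain ratio.

The muscle is split along its arc coordinate into a right end, a mid
("sling") region and a left end; the combined ends hold a target
fraction (default one third) of the voxels, half per end.  Regional
strain medians feed the normalized strain ratio

    ratio = |eps_right - eps_left| / |eps_mid - (eps_right + eps_left) / 2|

which contrasts the between-end strain asymmetry with the mid-vs-end
contrast: symmetric (intact) ends give ratios below 1, a unilaterally
avulsed end drives the ratio above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import ArcCoordinateMap
from .errors import DegenerateDenominatorError, EmptyRegionError, SpecificationError

LABELS = {"right_end": 1, "mid": 2, "left_end": 3}


@dataclass
class RegionPartition:
    """Per-voxel region labels plus the arc-coordinate cuts."""

    voxels: np.ndarray  # (n, 3)
    labels: np.ndarray  # (n,) values in {1: right_end, 2: mid, 3: left_end}
    s_lo: float
    s_hi: float
    end_fraction: float
    orientation: str

    def label_grid(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=np.uint8)
        out[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = self.labels
        return out

    def region_voxels(self, name: str) -> np.ndarray:
        return self.voxels[self.labels == LABELS[name]]


@dataclass
class SubjectStrainSummary:
    """Regional strain medians and the normalized strain ratio for one
    subject (woman or phantom)."""

    eps_right: float
    eps_left: float
    eps_mid: float
    ratio: float | None
    frame: int
    condition_label: str | None = None
    subject_id: str | None = None
    ratio_error: str | None = None

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "eps_right": self.eps_right,
            "eps_left": self.eps_left,
            "eps_mid": self.eps_mid,
            "ratio": self.ratio,
            "frame": self.frame,
            "condition_label": self.condition_label,
        }


def partition_regions(
    mask: np.ndarray,
    amap: ArcCoordinateMap,
    end_fraction: float = 1.0 / 3.0,
    orientation: str = "right_at_s0",
) -> RegionPartition:
    """Split the mask into right end / mid / left end by arc coordinate.

    The cut ``s_lo`` is placed so that exactly ``ceil(end_fraction/2 *
    n)`` voxels fall below it (by sorted s); ``s_hi`` symmetrically from
    the top.  ``orientation`` maps the s = 0 end to the "right" (default)
    or "left" label.
    """
    if not (0.0 < end_fraction < 1.0):
        raise SpecificationError("end_fraction must lie in (0, 1)")
    if orientation not in ("right_at_s0", "left_at_s0"):
        raise SpecificationError(f"unknown orientation {orientation!r}")
    s = amap.s
    n = s.size
    if n == 0:
        raise EmptyRegionError("arc map covers no voxels")
    k = int(np.ceil(end_fraction / 2.0 * n))
    if k < 1 or 2 * k >= n:
        raise EmptyRegionError("end_fraction leaves an empty region")
    order = np.sort(s)
    s_lo = 0.5 * (order[k - 1] + order[k])
    s_hi = 0.5 * (order[n - k - 1] + order[n - k])

    lab_s0 = LABELS["right_end"] if orientation == "right_at_s0" else LABELS["left_end"]
    lab_s1 = LABELS["left_end"] if orientation == "right_at_s0" else LABELS["right_end"]
    labels = np.full(n, LABELS["mid"], dtype=np.uint8)
    labels[s < s_lo] = lab_s0
    labels[s > s_hi] = lab_s1
    for name, lab in LABELS.items():
        if not np.any(labels == lab):
            raise EmptyRegionError(f"region '{name}' is empty after cuts")
    return RegionPartition(
        voxels=amap.voxels,
        labels=labels,
        s_lo=float(s_lo),
        s_hi=float(s_hi),
        end_fraction=float(end_fraction),
        orientation=orientation,
    )


def region_medians(
    strain_grid: np.ndarray, partition: RegionPartition
) -> tuple[float, float, float]:
    """Median percent strain per region (right, left, mid).

    Medians are taken over defined (finite) strain voxels; even counts
    give the mean of the central pair (numpy convention).
    """
    v = partition.voxels
    vals = np.asarray(strain_grid, dtype=float)[v[:, 0], v[:, 1], v[:, 2]]
    out = {}
    for name, lab in LABELS.items():
        x = vals[partition.labels == lab]
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise EmptyRegionError(f"region '{name}' has no defined strain voxels")
        out[name] = float(np.median(x))
    return out["right_end"], out["left_end"], out["mid"]


def normalized_strain_ratio(
    eps_right: float, eps_left: float, eps_mid: float
) -> float:
    """The normalized strain ratio of the regional medians.

    Raises :class:`DegenerateDenominatorError` when the mid strain
    equals the end average to within 1e-9 (the ratio is undefined and is
    never silently returned as infinity).
    """
    num = abs(eps_right - eps_left)
    den = abs(eps_mid - (eps_right + eps_left) / 2.0)
    if den < 1e-9:
        raise DegenerateDenominatorError(
            "mid strain equals the average of the end strains; ratio undefined"
        )
    return num / den
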