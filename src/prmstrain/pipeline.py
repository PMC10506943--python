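"""Per-subject orchestration and cohort comparison.

``analyze_subject`` is the in-memory pipeline (tracking -> propagation
-> centerline projection -> LSQSE strain -> regional summary);
``run_subject`` wraps it with file I/O, stage-level logging, checksums
and reproducibility metadata.  ``run_cohort`` compares two groups of
subject summaries and renders the ratio boxplot.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .core import VolumeSequence
from .errors import DegenerateDenominatorError, InputError, StageError
from .regions import (
    RegionPartition,
    SubjectStrainSummary,
    normalized_strain_ratio,
    partition_regions,
    region_medians,
)
from .stats import GroupComparison, compare_cohorts
from .strain import StrainSeries, compute_strain_series, select_max_contraction

log = logging.getLogger("prmstrain")


@dataclass
class SubjectResult:
    """In-memory result of one subject analysis."""

    summary: SubjectStrainSummary
    series: StrainSeries
    partition: RegionPartition


@dataclass
class SubjectRunRecord:
    """Provenance of one on-disk subject run."""

    inputs: dict
    config: dict
    timings: dict
    summary: SubjectStrainSummary
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "config": self.config,
            "timings_s": self.timings,
            "summary": self.summary.to_row() | {"ratio_error": self.summary.ratio_error},
            "version": self.version,
        }


def analyze_subject(
    volumes: VolumeSequence,
    rest_mask: np.ndarray,
    config: RunConfig | None = None,
    subject_id: str | None = None,
    condition_label: str | None = None,
) -> SubjectResult:
    """Run the full strain analysis on an in-memory sequence.

    The regional medians are taken at the maximum-contraction frame
    (most negative mid-region median), or at
    ``config.max_contraction_frame`` when overridden.  A degenerate
    normalized-ratio denominator (e.g. a motionless subject) is recorded
    on the summary instead of aborting the run.
    """
    config = config or RunConfig()
    try:
        series = compute_strain_series(volumes, rest_mask, config)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("strain_series", e) from e
    try:
        partition = partition_regions(
            rest_mask, series.rest_arc_map, config.end_fraction, config.orientation
        )
    except Exception as e:
        raise StageError("partition_regions", e) from e
    if config.max_contraction_frame is not None:
        frame = int(config.max_contraction_frame)
        if not (0 <= frame < series.n_frames):
            raise InputError(f"max_contraction_frame {frame} out of range")
    else:
        frame = select_max_contraction(series, partition)
    eps_r, eps_l, eps_m = region_medians(series.strain[frame], partition)
    ratio = None
    ratio_error = None
    try:
        ratio = normalized_strain_ratio(eps_r, eps_l, eps_m)
    except DegenerateDenominatorError as e:
        ratio_error = str(e)
        log.warning("subject %s: %s", subject_id, e)
    summary = SubjectStrainSummary(
        eps_right=eps_r,
        eps_left=eps_l,
        eps_mid=eps_m,
        ratio=ratio,
        frame=frame,
        condition_label=condition_label,
        subject_id=subject_id,
        ratio_error=ratio_error,
    )
    return SubjectResult(summary=summary, series=series, partition=partition)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_subject(
    volumes_path,
    mask_path,
    config: RunConfig | None = None,
    out_dir=None,
    subject_id: str | None = None,
    condition_label: str | None = None,
) -> SubjectRunRecord:
    """File-based subject run: read NIfTI inputs, analyze, write outputs.

    Writes the propagated masks, the full strain series, the region
    label map, the centerline CSV, a summary CSV row and a JSON run
    record with input checksums and per-stage timings.
    """
    from . import io as pio

    config = config or RunConfig()
    volumes_path, mask_path = Path(volumes_path), Path(mask_path)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    volumes = pio.read_volume_sequence(volumes_path)
    rest_mask, mask_spacing = pio.read_mask(mask_path)
    if rest_mask.shape != volumes.grid_shape:
        raise InputError(
            f"mask grid {rest_mask.shape} does not match volumes {volumes.grid_shape}"
        )
    if not np.allclose(mask_spacing, volumes.spacing, rtol=1e-4):
        raise InputError(
            f"mask spacing {mask_spacing} does not match volumes {volumes.spacing}"
        )
    timings["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = analyze_subject(
        volumes, rest_mask, config, subject_id=subject_id, condition_label=condition_label
    )
    timings["analysis"] = time.perf_counter() - t0

    if out_dir is not None:
        t0 = time.perf_counter()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_frames_scalar(out_dir / "strain.nii.gz", result.series.strain, volumes.spacing)
        pio.write_frames_scalar(
            out_dir / "masks.nii.gz", result.series.masks.astype(np.uint8), volumes.spacing
        )
        pio.write_label_map(
            out_dir / "regions.nii.gz",
            result.partition.label_grid(rest_mask.shape),
            volumes.spacing,
        )
        pio.write_centerline_csv(out_dir / "centerline.csv", result.series.rest_centerline)
        import pandas as pd

        pd.DataFrame([result.summary.to_row()]).to_csv(out_dir / "summary.csv", index=False)
        timings["write"] = time.perf_counter() - t0

    record = SubjectRunRecord(
        inputs={
            "volumes": {"path": str(volumes_path), "sha256": _sha256(volumes_path)},
            "mask": {"path": str(mask_path), "sha256": _sha256(mask_path)},
        },
        config=config.to_dict(),
        timings={k: round(v, 3) for k, v in timings.items()},
        summary=result.summary,
    )
    if out_dir is not None:
        (Path(out_dir) / "run_record.json").write_text(
            json.dumps(record.to_dict(), indent=2, sort_keys=True)
        )
    return record


def run_cohort(
    summaries_a,
    summaries_b,
    alpha: float = 0.05,
    out_dir=None,
    labels: tuple[str, str] = ("intact", "avulsed"),
) -> GroupComparison:
    """Compare two groups of subject summaries (or raw ratios).

    Writes ``comparison.json`` and a ratio boxplot when ``out_dir`` is
    given.  Requires at least 2 subjects per group.
    """
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise InputError("each group needs at least 2 subjects")
    comp = compare_cohorts(summaries_a, summaries_b, alpha=alpha)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "comparison.json").write_text(
            json.dumps(comp.to_dict(), indent=2, sort_keys=True)
        )
        _boxplot(comp, out_dir / "ratio_boxplot.png", labels)
    return comp


def _boxplot(comp: GroupComparison, path, labels) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([comp.ratios_a, comp.ratios_b], tick_labels=list(labels))
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("normalized strain ratio")
    ax.set_title(f"U = {comp.u_statistic:.1f}, p = {comp.p_value:.3f} ({comp.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
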