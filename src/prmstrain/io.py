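"""File I/O: NIfTI interchange plus best-effort multi-frame DICOM reading.

NIfTI is the canonical interchange format of the pipeline: 4D images for
volume sequences and per-frame scalar stacks, 3D images for masks and
label maps, CSV for centerlines and cohort summaries, JSON for
provenance.  A generic DICOM series reader is provided for
convenience — it reassembles single-frame files into a temporally
ordered sequence by temporal index, then instance number — but makes no
attempt at any vendor's private 3D format.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import VolumeSequence
from .errors import InputError


def _affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def _check_spacing(img) -> tuple[float, float, float]:
    """Spacing from the header; refuse files without spatial metadata.

    A NIfTI with neither an sform nor a qform carries no trustworthy
    voxel size (nibabel substitutes 1 mm), so it is rejected rather than
    silently analyzed at the wrong scale.
    """
    hdr = img.header
    if int(hdr["sform_code"]) == 0 and int(hdr["qform_code"]) == 0:
        raise InputError(
            "volume has no spatial metadata (sform and qform both absent): "
            "voxel spacing is missing; refusing to assume 1 mm"
        )
    spacing = tuple(float(z) for z in hdr.get_zooms()[:3])
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise InputError(
            f"volume has missing or invalid voxel spacing {spacing}; refusing to "
            "assume 1 mm"
        )
    return spacing


def write_volume_sequence(path, seq: VolumeSequence) -> None:
    """4D NIfTI with spatial zooms = spacing and temporal zoom = frame dt."""
    data = np.moveaxis(seq.data, 0, -1)  # (x, y, z, t)
    img = nib.Nifti1Image(np.asarray(data, np.float32), _affine(seq.spacing))
    img.header.set_zooms((*seq.spacing, seq.frame_interval))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume_sequence(path) -> VolumeSequence:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise InputError(f"expected a 4D NIfTI; got {data.ndim}D")
    spacing = _check_spacing(img)
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0 / 1.5
    return VolumeSequence(np.moveaxis(data, -1, 0), spacing, dt)


def write_mask(path, mask: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(mask, np.uint8), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"expected a 3D mask NIfTI; got {data.ndim}D")
    return data > 0, _check_spacing(img)


def write_frames_scalar(path, frames: np.ndarray, spacing) -> None:
    """(t, x, y, z) scalar stack as 4D NIfTI (strain, truth components...)."""
    data = np.moveaxis(np.asarray(frames, np.float32), 0, -1)
    img = nib.Nifti1Image(data, _affine(spacing))
    nib.save(img, str(path))


def read_frames_scalar(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.moveaxis(np.asanyarray(img.dataobj), -1, 0)


def write_label_map(path, labels: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(labels, np.uint8), _affine(spacing))
    nib.save(img, str(path))


def write_displacement_field(path_prefix, field, extra_meta: dict | None = None):
    """Displacement subgrid as one NIfTI per component + JSON metadata."""
    path_prefix = Path(path_prefix)
    paths = {}
    for c, name in enumerate("xyz"):
        p = path_prefix.with_name(path_prefix.name + f"_{name}.nii.gz")
        img = nib.Nifti1Image(
            np.asarray(field.vectors[..., c], np.float32), np.eye(4)
        )
        nib.save(img, str(p))
        paths[name] = str(p)
    qp = path_prefix.with_name(path_prefix.name + "_quality.nii.gz")
    nib.save(nib.Nifti1Image(np.asarray(field.quality, np.float32), np.eye(4)), str(qp))
    meta = {
        "frame_pair": list(field.frame_pair),
        "stride": int(field.stride),
        "spacing": list(field.spacing),
        "volume_shape": list(field.volume_shape),
        "grid_x": field.grid_x.tolist(),
        "grid_y": field.grid_y.tolist(),
        "grid_z": field.grid_z.tolist(),
        "components": paths,
        "quality": str(qp),
    }
    meta.update(extra_meta or {})
    mp = path_prefix.with_name(path_prefix.name + ".json")
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return mp


def write_centerline_csv(path, cl) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "s": cl.arc_length,
            "x": cl.points[:, 0],
            "y": cl.points[:, 1],
            "z": cl.points[:, 2],
            "tx": cl.tangents[:, 0],
            "ty": cl.tangents[:, 1],
            "tz": cl.tangents[:, 2],
        }
    ).to_csv(path, index=False)


def read_dicom_series(directory) -> VolumeSequence:
    """Best-effort multi-frame read of a directory of single-frame DICOMs.

    Frames are grouped by TemporalPositionIndex (falling back to
    InstanceNumber order) and slices within a frame by InstanceNumber,
    so a shuffled file listing still reassembles in temporal order.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise InputError(f"no files in {directory}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise InputError(f"no readable DICOM files in {directory}")

    def temporal_key(ds):
        t = getattr(ds, "TemporalPositionIndex", None)
        if t is None:
            t = getattr(ds, "TemporalPositionIdentifier", None)
        return int(t) if t is not None else None

    frames: dict[int, list] = {}
    for ds in datasets:
        t = temporal_key(ds)
        if t is None:
            # single 4D-ish fallback: every file its own frame by instance
            t = int(getattr(ds, "InstanceNumber", len(frames)))
        frames.setdefault(t, []).append(ds)

    vols = []
    spacing = None
    for t in sorted(frames):
        group = sorted(frames[t], key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        slices = [d.pixel_array.astype(np.float32) for d in group]
        vols.append(np.stack(slices, axis=-1))
        ps = getattr(group[0], "PixelSpacing", None)
        st = getattr(group[0], "SliceThickness", None) or getattr(
            group[0], "SpacingBetweenSlices", None
        )
        if ps is not None and st is not None:
            spacing = (float(ps[0]), float(ps[1]), float(st))
    if spacing is None:
        raise InputError("DICOM series lacks PixelSpacing/SliceThickness metadata")
    data = np.stack(vols, axis=0)
    if data.shape[0] < 2:
        raise InputError("DICOM series holds fewer than 2 temporal frames")
    return VolumeSequence(data, spacing)
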