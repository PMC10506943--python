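"""Segmentation propagation and Lagrangian displacement accumulation.

The rest-frame segmentation is carried through time by warping it with
each inter-volume displacement field, and the inter-volume fields are
composed into the cumulative motion of each rest-frame material voxel.
Accumulation is Lagrangian: the increment is sampled (trilinearly) at
the material point's current position, not at its rest position, which
reduces to plain summation in the small-motion limit but stays correct
once motion exceeds a voxel.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_closing, map_coordinates

from .errors import InputError
from .tracking import DisplacementField


def _dense_mm(field, volume_shape) -> np.ndarray:
    if isinstance(field, DisplacementField):
        if field.volume_shape != tuple(volume_shape):
            raise InputError("displacement field grid does not match the mask grid")
        return field.dense()
    arr = np.asarray(field, dtype=float)
    if arr.shape != (*volume_shape, 3):
        raise InputError(
            f"dense field must have shape {(*volume_shape, 3)}; got {arr.shape}"
        )
    return arr


def warp_mask(
    mask: np.ndarray,
    field,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Move a binary mask with a displacement field.

    Each set voxel is splatted to the nearest voxel of its displaced
    position; the result is closed with a one-voxel morphological
    closing so that expansion cannot punch dropout holes.  NaN vectors
    at set voxels are substituted by the nearest defined vector (the
    dense interpolation does this); an all-undefined field is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    dense = _dense_mm(field, mask.shape)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise InputError("mask is empty")
    u_vox = dense[idx[:, 0], idx[:, 1], idx[:, 2]] / np.asarray(spacing, float)
    if not np.isfinite(u_vox).all():
        raise InputError("displacement undefined at mask voxels with no fallback")
    new = np.rint(idx + u_vox).astype(np.int64)
    ok = np.all((new >= 0) & (new < np.asarray(mask.shape)), axis=1)
    out = np.zeros_like(mask)
    out[new[ok, 0], new[ok, 1], new[ok, 2]] = True
    return binary_closing(out, structure=np.ones((3, 3, 3), bool))


def accumulate(
    accum_prev: np.ndarray,
    rest_voxels: np.ndarray,
    incr,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    volume_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Compose an incremental field onto the accumulated motion.

    Parameters
    ----------
    accum_prev:
        ``(n, 3)`` cumulative displacement (mm) of the rest-frame
        material voxels at frame ``t`` (all zeros at frame 0).
    rest_voxels:
        ``(n, 3)`` integer voxel indices of the material points on the
        rest grid.
    incr:
        Inter-volume displacement for ``(t, t+1)`` — a
        :class:`DisplacementField` or a dense ``(x, y, z, 3)`` mm array.

    Returns
    -------
    ``(n, 3)`` cumulative displacement at frame ``t+1``;  NaN rows mark
    material points whose current position left the grid.
    """
    accum_prev = np.asarray(accum_prev, dtype=float)
    rest_voxels = np.asarray(rest_voxels)
    if accum_prev.shape != (rest_voxels.shape[0], 3):
        raise InputError("accum_prev must be (n, 3) matching rest_voxels")
    if volume_shape is None:
        if isinstance(incr, DisplacementField):
            volume_shape = incr.volume_shape
        else:
            volume_shape = np.asarray(incr).shape[:-1]
    dense = _dense_mm(incr, volume_shape)
    sp = np.asarray(spacing, float)
    pos_vox = rest_voxels + accum_prev / sp
    inc = sample_dense(dense, pos_vox)
    return accum_prev + inc


def sample_dense(dense: np.ndarray, pos_vox: np.ndarray) -> np.ndarray:
    """Trilinear sample of a dense (x, y, z, 3) field at fractional voxel
    positions; out-of-grid positions give NaN."""
    pos = np.asarray(pos_vox, float)
    ok = np.isfinite(pos).all(axis=1)
    out = np.full((pos.shape[0], 3), np.nan)
    if ok.any():
        coords = pos[ok].T
        for c in range(3):
            out[ok, c] = map_coordinates(
                dense[..., c], coords, order=1, mode="constant", cval=np.nan
            )
    return out
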