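"""Dense inter-volume 3D displacement estimation (3D speckle tracking).

The base estimator is block matching: for each block center, the integer
displacement maximizing normalized cross-correlation (NCC) within a
search window, refined per axis by a Gaussian fit through the
correlation peak.  Because any correlation-peak readout on speckle
carries a pattern-dependent subvoxel bias, the field is then polished by
warp-and-refine passes whose residual step is a per-block Lucas-Kanade
solve — exactly zero once the volumes align.  The NCC peak value is kept
as a per-estimate quality score; low-quality vectors can be repaired
from their neighborhood median (:func:`quality_filter`), and
:func:`refine_displacement` re-registers accumulated fields directly to
the rest frame to remove composition drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from ._blockmatch import lk_blocks, match_blocks
from .errors import InputError, SpecificationError


@dataclass
class TrackingParams:
    """Block-matching configuration.

    Defaults (7^3 block, +/-5 voxel search) resolve the sub-2-voxel
    per-frame motions of the reference phantoms with margin while
    keeping the block smaller than the muscle band cross-section, so
    estimates are not blended with stationary background.
    ``refine_iterations`` adds warp-and-refine passes that remove the
    subvoxel peak-locking bias of a single correlation pass.  ``stride``
    is the block-center spacing in voxels; the resulting subgrid field
    is densified by trilinear interpolation where full-grid vectors are
    needed.
    """

    block_size: tuple[int, int, int] = (7, 7, 7)
    search_radius: tuple[int, int, int] = (5, 5, 5)
    subvoxel: bool = True
    min_quality: float = 0.5
    median_filter_radius: int = 1
    stride: int = 2
    refine_iterations: int = 3

    def __post_init__(self) -> None:
        self.block_size = tuple(int(b) for b in self.block_size)
        self.search_radius = tuple(int(r) for r in self.search_radius)
        if len(self.block_size) != 3 or any(b < 3 for b in self.block_size):
            raise SpecificationError("block_size must be >= 3 per axis")
        if any(b % 2 == 0 for b in self.block_size):
            raise SpecificationError("block_size must be odd per axis")
        if len(self.search_radius) != 3 or any(r < 1 for r in self.search_radius):
            raise SpecificationError("search_radius must be >= 1 per axis")
        if self.stride < 1:
            raise SpecificationError("stride must be >= 1")
        if self.median_filter_radius < 1:
            raise SpecificationError("median_filter_radius must be >= 1")
        if self.refine_iterations < 0:
            raise SpecificationError("refine_iterations must be >= 0")


@dataclass
class DisplacementField:
    """Per-voxel 3-vector motion (mm) on a regular subgrid with quality.

    ``vectors[i, j, k]`` is the displacement at voxel index
    ``(grid_x[i], grid_y[j], grid_z[k])``; NaN marks undefined
    estimates.  ``quality`` holds the NCC peak in [-1, 1].
    """

    vectors: np.ndarray  # (gx, gy, gz, 3) mm
    quality: np.ndarray  # (gx, gy, gz)
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_z: np.ndarray
    stride: int
    spacing: tuple[float, float, float]
    volume_shape: tuple[int, int, int]
    frame_pair: tuple[int, int] = (0, 1)
    interpolated: np.ndarray | None = None  # set by quality_filter

    def __post_init__(self) -> None:
        if self.vectors.shape[:3] != self.quality.shape:
            raise InputError("vectors and quality must share one grid")
        finite_q = self.quality[np.isfinite(self.quality)]
        if finite_q.size and (finite_q.min() < -1.0 - 1e-9 or finite_q.max() > 1.0 + 1e-9):
            raise InputError("quality values must lie in [-1, 1]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.vectors).all(axis=-1)

    def dense(self) -> np.ndarray:
        """Full-grid (x, y, z, 3) field in mm by trilinear interpolation.

        Undefined subgrid nodes are filled from the nearest defined node
        before interpolation, so the result is defined everywhere; keep
        the subgrid ``defined`` mask when validity matters.
        """
        filled = fill_undefined(self.vectors)
        shape = self.volume_shape
        axes = [np.arange(n) for n in shape]
        # map full-grid voxel index to fractional subgrid coordinate
        coords = np.meshgrid(
            np.interp(axes[0], self.grid_x, np.arange(self.grid_x.size)),
            np.interp(axes[1], self.grid_y, np.arange(self.grid_y.size)),
            np.interp(axes[2], self.grid_z, np.arange(self.grid_z.size)),
            indexing="ij",
        )
        coords = np.stack([c.ravel() for c in coords])
        out = np.empty((*shape, 3), dtype=float)
        for c in range(3):
            out[..., c] = map_coordinates(
                filled[..., c], coords, order=1, mode="nearest"
            ).reshape(shape)
        return out


def _smooth_valid(vectors: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a vector subgrid over its finite entries only."""
    from scipy.ndimage import gaussian_filter

    valid = np.isfinite(vectors).all(axis=-1)
    if not valid.any():
        return vectors
    den = gaussian_filter(valid.astype(float), sigma)
    out = np.full_like(vectors, np.nan)
    for c in range(3):
        num = gaussian_filter(np.where(valid, vectors[..., c], 0.0), sigma)
        out[..., c] = np.where(valid & (den > 1e-12), num / np.maximum(den, 1e-12), np.nan)
    return out


def fill_undefined(vectors: np.ndarray) -> np.ndarray:
    """Replace NaN vectors with the nearest defined vector (EDT lookup)."""
    defined = np.isfinite(vectors).all(axis=-1)
    if defined.all():
        return vectors
    if not defined.any():
        raise InputError("displacement field has no defined vectors")
    _, idx = distance_transform_edt(~defined, return_indices=True)
    return vectors[idx[0], idx[1], idx[2]]


def estimate_displacement(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    params: TrackingParams,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
    frame_pair: tuple[int, int] = (0, 1),
) -> DisplacementField:
    """Estimate the displacement field carrying ``vol_a`` onto ``vol_b``.

    Block centers lie on a regular ``stride`` subgrid; with ``mask``
    given, only centers inside the mask are matched (the rest stay
    undefined), which keeps runtime proportional to the region of
    interest.  Output vectors are in mm (voxel estimate x spacing).
    """
    vol_a = np.ascontiguousarray(vol_a, dtype=np.float32)
    vol_b = np.ascontiguousarray(vol_b, dtype=np.float32)
    if vol_a.ndim != 3:
        raise InputError("volumes must be 3D")
    if vol_a.shape != vol_b.shape:
        raise InputError(f"volume shapes differ: {vol_a.shape} vs {vol_b.shape}")
    if any(b > n for b, n in zip(params.block_size, vol_a.shape)):
        raise SpecificationError(
            f"block {params.block_size} larger than volume {vol_a.shape}"
        )

    gx = np.arange(0, vol_a.shape[0], params.stride)
    gy = np.arange(0, vol_a.shape[1], params.stride)
    gz = np.arange(0, vol_a.shape[2], params.stride)
    ii, jj, kk = np.meshgrid(gx, gy, gz, indexing="ij")
    centers = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(np.int64)
    sel = np.ones(centers.shape[0], dtype=bool)
    if mask is not None:
        if mask.shape != vol_a.shape:
            raise InputError("mask grid must match the volumes")
        sel = mask[centers[:, 0], centers[:, 1], centers[:, 2]].astype(bool)

    bx, by, bz = (b // 2 for b in params.block_size)
    sx, sy, sz = params.search_radius
    disp = np.full((centers.shape[0], 3), np.nan)
    qual = np.full(centers.shape[0], np.nan)
    if sel.any():
        d, q = match_blocks(
            vol_a, vol_b, centers[sel], bx, by, bz, sx, sy, sz, params.subvoxel
        )
        disp[sel] = d
        qual[sel] = q

    shape_sub = (gx.size, gy.size, gz.size)
    field = DisplacementField(
        vectors=disp.reshape(*shape_sub, 3) * np.asarray(spacing),
        quality=qual.reshape(shape_sub),
        grid_x=gx,
        grid_y=gy,
        grid_z=gz,
        stride=params.stride,
        spacing=tuple(float(s) for s in spacing),
        volume_shape=vol_a.shape,
        frame_pair=tuple(frame_pair),
    )

    # warp-and-refine: re-match against vol_b warped back by the current
    # estimate.  A Lucas-Kanade step measures the residual, which is
    # exactly zero at true alignment, so iterating removes the
    # pattern-dependent bias of the correlation-peak readout.  The field
    # is smoothed each pass (demons-style) because block-averaged
    # residuals cannot see - and would otherwise freeze in - error at
    # scales below the block size.
    n_refine = params.refine_iterations if params.subvoxel else 0
    for it in range(n_refine):
        if not sel.any() or not np.isfinite(field.vectors).any():
            break
        if it == 0:
            # smooth the base estimate once: its sub-block-scale wiggles
            # are invisible to the refinement and would freeze in
            field.vectors[...] = _smooth_valid(field.vectors, sigma=1.0)
        u_vox = field.dense() / np.asarray(spacing)
        axes = [np.arange(n, dtype=float) for n in vol_a.shape]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        coords = np.stack(
            [xx + u_vox[..., 0], yy + u_vox[..., 1], zz + u_vox[..., 2]]
        ).reshape(3, -1)
        warped = map_coordinates(vol_b, coords, order=3, mode="nearest").reshape(
            vol_a.shape
        ).astype(np.float32)
        rd = lk_blocks(vol_a, warped, centers[sel], bx, by, bz)
        # the residual after warping is small and spatially smooth, so
        # damp the estimator's fresh noise before composing
        rd_grid = np.full((*shape_sub, 3), np.nan)
        rd_grid.reshape(-1, 3)[sel] = rd
        rd_grid = _smooth_valid(rd_grid, sigma=1.0)
        rd = rd_grid.reshape(-1, 3)[sel]
        vec = field.vectors.reshape(-1, 3)
        base = vec[sel]
        ok = np.isfinite(base).all(axis=1) & np.isfinite(rd).all(axis=1)
        base[ok] += rd[ok] * np.asarray(spacing)
        vec[sel] = base
    return field


def zero_field(
    volume_shape: tuple[int, int, int],
    params: TrackingParams,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
) -> DisplacementField:
    """An all-zero displacement subgrid (NaN outside ``mask`` nodes)."""
    gx = np.arange(0, volume_shape[0], params.stride)
    gy = np.arange(0, volume_shape[1], params.stride)
    gz = np.arange(0, volume_shape[2], params.stride)
    shape_sub = (gx.size, gy.size, gz.size)
    vectors = np.zeros((*shape_sub, 3))
    quality = np.ones(shape_sub)
    if mask is not None:
        ii, jj, kk = np.meshgrid(gx, gy, gz, indexing="ij")
        inside = mask[ii, jj, kk]
        vectors[~inside] = np.nan
        quality[~inside] = np.nan
    return DisplacementField(
        vectors=vectors,
        quality=quality,
        grid_x=gx,
        grid_y=gy,
        grid_z=gz,
        stride=params.stride,
        spacing=tuple(float(s) for s in spacing),
        volume_shape=tuple(volume_shape),
    )


def refine_displacement(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    field: DisplacementField,
    iterations: int = 3,
    block_size: tuple[int, int, int] = (11, 11, 11),
    spacing: tuple[float, float, float] | None = None,
) -> DisplacementField:
    """Iteratively refine an existing field by warp + Lucas-Kanade.

    ``vol_b`` is warped back by the current estimate and the per-block
    linearized residual is composed on.  Because the residual after a
    good initialization is spatially smooth, a block larger than the
    original matching block suppresses estimation noise without the
    spatial blending a large correlation block would cause.  Used to
    re-register accumulated displacement fields directly to the rest
    frame, which removes the drift a chain of inter-volume compositions
    builds up.
    """
    vol_a = np.ascontiguousarray(vol_a, dtype=np.float32)
    vol_b = np.ascontiguousarray(vol_b, dtype=np.float32)
    spacing = np.asarray(spacing if spacing is not None else field.spacing, float)
    bx, by, bz = (int(b) // 2 for b in block_size)
    ii, jj, kk = np.meshgrid(field.grid_x, field.grid_y, field.grid_z, indexing="ij")
    centers = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(np.int64)
    sel = np.isfinite(field.vectors).all(axis=-1).ravel()
    out = replace(field, vectors=field.vectors.copy())
    if not sel.any():
        return out
    axes = [np.arange(n, dtype=float) for n in vol_a.shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    for _ in range(int(iterations)):
        u_vox = out.dense() / spacing
        coords = np.stack(
            [xx + u_vox[..., 0], yy + u_vox[..., 1], zz + u_vox[..., 2]]
        ).reshape(3, -1)
        warped = map_coordinates(vol_b, coords, order=3, mode="nearest").reshape(
            vol_a.shape
        ).astype(np.float32)
        rd = lk_blocks(vol_a, warped, centers[sel], bx, by, bz)
        rd_grid = np.full(field.vectors.shape, np.nan)
        rd_grid.reshape(-1, 3)[sel] = rd
        rd_grid = _smooth_valid(rd_grid, sigma=1.0)
        rd = rd_grid.reshape(-1, 3)[sel]
        vec = out.vectors.reshape(-1, 3)
        base = vec[sel]
        ok = np.isfinite(base).all(axis=1) & np.isfinite(rd).all(axis=1)
        base[ok] += rd[ok] * spacing
        vec[sel] = base
    return out


def quality_filter(field: DisplacementField, params: TrackingParams) -> DisplacementField:
    """Repair low-quality vectors from the neighborhood median.

    Vectors with ``quality < min_quality`` (or undefined ones inside the
    estimated region) are replaced by the component-wise median of valid
    neighbors within ``median_filter_radius`` subgrid steps; a vector
    with no valid neighbor stays undefined.  Replaced vectors are marked
    in ``interpolated`` and keep their original (low) quality score.
    """
    q = field.quality
    vec = field.vectors.copy()
    estimated = np.isfinite(q)
    valid = estimated & (q >= params.min_quality) & field.defined
    bad = estimated & ~valid
    interpolated = np.zeros(q.shape, dtype=bool)
    r = params.median_filter_radius
    for i, j, k in np.argwhere(bad):
        sl = (
            slice(max(i - r, 0), i + r + 1),
            slice(max(j - r, 0), j + r + 1),
            slice(max(k - r, 0), k + r + 1),
        )
        nb_valid = valid[sl]
        if not nb_valid.any():
            vec[i, j, k] = np.nan
            continue
        vec[i, j, k] = np.median(field.vectors[sl][nb_valid], axis=0)
        interpolated[i, j, k] = True
    return replace(field, vectors=vec, interpolated=interpolated)
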