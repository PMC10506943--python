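"""Fiber-direction strain from projected displacements.

Strain is the spatial gradient of tangential displacement along the
fiber (arc) coordinate, estimated per voxel by a 2x2x2 least-squares
strain estimator (LSQSE): over the 8-voxel neighborhood (the voxel plus
its +1 neighbors along each axis), the projected displacement is
regressed on the arc coordinate s, and the slope x 100 is the percent
strain.  Negative strain is shortening (contraction), positive is
elongation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .centerline import ArcCoordinateMap, build_arc_map, extract_centerline
from .config import RunConfig
from .core import VolumeSequence, check_same_grid
from .errors import EmptyRegionError, InputError
from .propagation import sample_dense, warp_mask
from .tracking import (
    estimate_displacement,
    quality_filter,
    refine_displacement,
    zero_field,
)


def lsq_strain(
    proj: np.ndarray,
    amap_or_s,
    mask: np.ndarray,
) -> np.ndarray:
    """Per-voxel percent strain by the 2x2x2 least-squares estimator.

    Parameters
    ----------
    proj:
        Projected (tangential) displacement in mm — either a flat array
        aligned with the arc map's voxels or a full-grid array with NaN
        outside the mask.
    amap_or_s:
        An :class:`ArcCoordinateMap` or a full-grid array of arc
        coordinates s (mm, NaN outside the mask).
    mask:
        Binary mask on the volume grid.

    Returns
    -------
    Full-grid percent-strain array, NaN where undefined.  A voxel is
    undefined when fewer than 4 neighborhood members are valid or the
    sample variance of s within the neighborhood falls below 1e-6 mm^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if isinstance(amap_or_s, ArcCoordinateMap):
        s_grid = amap_or_s.s_grid(mask.shape)
    else:
        s_grid = np.asarray(amap_or_s, dtype=float)
        check_same_grid(s_grid, mask, "arc-coordinate grid and mask")
    proj = np.asarray(proj, dtype=float)
    if proj.ndim == 1:
        if isinstance(amap_or_s, ArcCoordinateMap):
            v = amap_or_s.voxels
        else:
            v = np.argwhere(mask)
            if proj.shape[0] != v.shape[0]:
                raise InputError(
                    "flat proj length must match the mask voxel count"
                )
        p_grid = np.full(mask.shape, np.nan)
        p_grid[v[:, 0], v[:, 1], v[:, 2]] = proj
    else:
        check_same_grid(proj, mask, "projected displacement and mask")
        p_grid = proj

    return _lsq_slope_grid(p_grid, s_grid, mask) * 100.0


def _lsq_slope_grid(p_grid: np.ndarray, s_grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel 2x2x2 OLS slope of ``p_grid`` against ``s_grid`` (per mm).

    NaN where fewer than 4 valid neighborhood members or where the
    sample variance of s falls below 1e-6 mm^2.
    """
    valid = mask & np.isfinite(p_grid) & np.isfinite(s_grid)
    nx, ny, nz = mask.shape
    # pad far ends so every voxel sees a (possibly clipped) +1 neighborhood
    pad = [(0, 1)] * 3
    vp = np.pad(valid, pad, constant_values=False)
    sp = np.pad(np.where(valid, s_grid, 0.0), pad)
    pp = np.pad(np.where(valid, p_grid, 0.0), pad)

    n = np.zeros(mask.shape)
    Ss = np.zeros(mask.shape)
    Sp = np.zeros(mask.shape)
    Sss = np.zeros(mask.shape)
    Ssp = np.zeros(mask.shape)
    for dx, dy, dz in product((0, 1), repeat=3):
        v = vp[dx : dx + nx, dy : dy + ny, dz : dz + nz]
        sv = sp[dx : dx + nx, dy : dy + ny, dz : dz + nz]
        pv = pp[dx : dx + nx, dy : dy + ny, dz : dz + nz]
        n += v
        Ss += sv
        Sp += pv
        Sss += sv * sv
        Ssp += sv * pv

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = n * Sss - Ss * Ss
        var_s = np.where(n > 1, (Sss - Ss * Ss / np.maximum(n, 1)) / np.maximum(n - 1, 1), 0.0)
        slope = (n * Ssp - Ss * Sp) / denom
    ok = mask & (n >= 4) & (var_s >= 1e-6)
    return np.where(ok, slope, np.nan)


def lsq_strain_tensorial(
    vec_grid: np.ndarray,
    s_grid: np.ndarray,
    tangent_grid: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Fiber-direction percent strain from a 3-vector displacement grid.

    Each displacement component is regressed on the arc coordinate over
    the 2x2x2 neighborhood (same estimator as :func:`lsq_strain`), and
    the slope vector is projected on the local unit tangent:
    ``strain = t . d(u)/ds * 100``.  For motion along the fiber this
    equals the slope of the projected scalar displacement; for a rigid
    translation every component slope vanishes, so the estimate is
    exactly translation-insensitive even on a curved fiber, where
    projecting first would leak the tangent's own rotation
    (``u . dt/ds``) into the strain.
    """
    strain = np.zeros(mask.shape)
    for c in range(3):
        strain = strain + _lsq_slope_grid(vec_grid[..., c], s_grid, mask) * tangent_grid[..., c]
    return strain * 100.0


@dataclass
class StrainSeries:
    """Per-frame percent-strain fields with analysis provenance.

    ``strain[t]`` is a full-grid array (NaN outside the rest mask or
    where the estimator lacks support).  The accompanying arrays carry
    the material-voxel bookkeeping: rest-frame voxels, their cumulative
    3-vector displacement and accumulated projected scalar per frame,
    and the per-frame propagated masks.
    """

    strain: np.ndarray  # (t, x, y, z) percent
    masks: np.ndarray  # (t, x, y, z) bool, propagated segmentation
    rest_voxels: np.ndarray  # (n, 3)
    accumulated: np.ndarray  # (t, n, 3) mm
    projected: np.ndarray  # (t, n) mm
    rest_centerline: object
    rest_arc_map: ArcCoordinateMap
    mode: str

    @property
    def n_frames(self) -> int:
        return int(self.strain.shape[0])


def masked_smooth(values: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian smoothing restricted to a mask (normalized convolution).

    Averages only over in-mask finite values, so the estimate is never
    pulled toward out-of-mask (e.g. stationary background) data.  Works
    on scalar grids or on vector grids with a trailing component axis.
    """
    if np.ndim(sigma_vox) == 0 and float(np.max(sigma_vox)) == 0.0:
        return values
    if values.ndim == mask.ndim + 1:
        out = np.stack(
            [masked_smooth(values[..., c], mask, sigma_vox) for c in range(values.shape[-1])],
            axis=-1,
        )
        return out
    ok = mask & np.isfinite(values)
    num = gaussian_filter(np.where(ok, values, 0.0), sigma_vox)
    den = gaussian_filter(ok.astype(float), sigma_vox)
    out = np.full(values.shape, np.nan)
    nz = ok & (den > 1e-12)
    out[nz] = num[nz] / den[nz]
    return out


def compute_strain_series(
    volumes: VolumeSequence,
    rest_mask: np.ndarray,
    config: RunConfig | None = None,
    mode: str | None = None,
) -> StrainSeries:
    """Run tracking -> propagation -> projection -> LSQSE over a sequence.

    Inter-volume displacements are composed Lagrangianly and the
    accumulated field is re-registered against the rest frame each frame
    (drift correction).  ``incremental`` mode (default) recomputes the
    centerline on the propagated mask at every frame and takes strain
    along the tangent at each material point's current position -
    correcting for the changing fiber direction during contraction.
    ``terminal`` mode keeps the rest-frame tangents.  Both regress
    against the rest-frame arc coordinate.
    """
    config = config or RunConfig()
    mode = mode or config.projection_mode
    if mode not in ("incremental", "terminal"):
        raise InputError(f"unknown mode {mode!r}")
    rest_mask = np.asarray(rest_mask, dtype=bool)
    check_same_grid(rest_mask, volumes.frame(0), "rest mask and volumes")

    spacing = volumes.spacing
    cl0 = extract_centerline(rest_mask, spacing, config.centerline_degree)
    if config.orientation == "left_at_s0":
        cl0 = cl0.reversed()
    amap0 = build_arc_map(rest_mask, cl0, spacing)
    voxels = amap0.voxels
    nvox = voxels.shape[0]
    T = volumes.n_frames

    track_margin = max(config.tracking.search_radius) + max(config.tracking.block_size) // 2
    s_grid0 = amap0.s_grid(rest_mask.shape)

    accumulated = np.zeros((T, nvox, 3))
    projected = np.zeros((T, nvox))
    masks = np.zeros((T, *rest_mask.shape), dtype=bool)
    masks[0] = rest_mask
    strain = np.full((T, *rest_mask.shape), np.nan)
    strain[0] = lsq_strain(projected[0], amap0, rest_mask)

    roi0 = binary_dilation(rest_mask, iterations=track_margin)
    acc_field = zero_field(rest_mask.shape, config.tracking, spacing, mask=roi0)
    node_vox = np.stack(
        np.meshgrid(acc_field.grid_x, acc_field.grid_y, acc_field.grid_z, indexing="ij"),
        axis=-1,
    ).reshape(-1, 3).astype(float)

    mask_t = rest_mask
    cl_t = cl0
    sigma_p = config.projection_smoothing_mm / np.asarray(spacing)
    tang0_grid = _scatter(amap0.tangent, voxels, rest_mask.shape)
    for t in range(T - 1):
        roi = binary_dilation(mask_t, iterations=track_margin)
        field = estimate_displacement(
            volumes.frame(t),
            volumes.frame(t + 1),
            config.tracking,
            spacing=spacing,
            mask=roi,
            frame_pair=(t, t + 1),
        )
        field = quality_filter(field, config.tracking)
        dense = field.dense()
        if config.increment_smoothing_mm > 0:
            sigma_vox = config.increment_smoothing_mm / np.asarray(spacing)
            smoothed = masked_smooth(dense, mask_t, sigma_vox)
            keep = np.isfinite(smoothed).all(axis=-1)
            dense = np.where(keep[..., None], smoothed, dense)

        # Lagrangian composition of the inter-volume increment on the
        # rest-frame subgrid, then drift-correcting re-registration of
        # the accumulated field directly against the rest frame: the
        # composition chain supplies the initialization (and keeps each
        # correlation search small), the re-registration removes the
        # error random walk the chain would otherwise accumulate.
        flat = acc_field.vectors.reshape(-1, 3)
        pos_nodes = node_vox + flat / np.asarray(spacing)
        inc_nodes = sample_dense(dense, pos_nodes)
        ok = np.isfinite(flat).all(axis=1) & np.isfinite(inc_nodes).all(axis=1)
        flat[ok] += inc_nodes[ok]
        flat[~ok & np.isfinite(flat).all(axis=1)] = np.nan
        acc_field = refine_displacement(
            volumes.frame(0), volumes.frame(t + 1), acc_field,
            iterations=config.tracking.refine_iterations,
            spacing=spacing,
        )
        dense_acc = acc_field.dense()
        accumulated[t + 1] = dense_acc[voxels[:, 0], voxels[:, 1], voxels[:, 2]]

        mask_t = warp_mask(rest_mask, dense_acc, spacing)
        masks[t + 1] = mask_t

        acc_grid = _scatter(accumulated[t + 1], voxels, rest_mask.shape)
        if config.projection_smoothing_mm > 0:
            acc_grid = masked_smooth(acc_grid, rest_mask, sigma_p)

        if mode == "incremental":
            # angle correction: fiber direction re-derived from the
            # propagated mask each frame; strain taken along the tangent
            # at each material point's current position.
            try:
                cl_t = extract_centerline(mask_t, spacing, config.centerline_degree)
                if config.orientation == "left_at_s0":
                    cl_t = cl_t.reversed()
            except Exception:
                pass  # keep the previous frame's centerline on a bad mask
            pos_vox = voxels + accumulated[t + 1] / np.asarray(spacing)
            tang = _tangent_at_positions(cl_t, pos_vox, spacing)
            tang_grid = _scatter(tang, voxels, rest_mask.shape)
        else:
            tang = amap0.tangent
            tang_grid = tang0_grid
        projected[t + 1] = np.einsum("ij,ij->i", accumulated[t + 1], tang)
        strain[t + 1] = lsq_strain_tensorial(acc_grid, s_grid0, tang_grid, rest_mask)

    return StrainSeries(
        strain=strain,
        masks=masks,
        rest_voxels=voxels,
        accumulated=accumulated,
        projected=projected,
        rest_centerline=cl0,
        rest_arc_map=amap0,
        mode=mode,
    )


def _scatter(values: np.ndarray, voxels: np.ndarray, shape) -> np.ndarray:
    """Place per-voxel rows (n,) or (n, k) on a NaN-filled grid."""
    if values.ndim == 1:
        out = np.full(shape, np.nan)
    else:
        out = np.full((*shape, values.shape[1]), np.nan)
    out[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = values
    return out


def _tangent_at_positions(cl, pos_vox: np.ndarray, spacing) -> np.ndarray:
    """Unit tangent of the nearest centerline sample for each position."""
    from scipy.spatial import cKDTree

    pts = np.asarray(pos_vox, float) * np.asarray(spacing, float)
    ok = np.isfinite(pts).all(axis=1)
    out = np.full(pts.shape, np.nan)
    if ok.any():
        _, idx = cKDTree(cl.points).query(pts[ok])
        out[ok] = cl.tangents[idx]
    return out


def select_max_contraction(series: StrainSeries, partition) -> int:
    """Frame with the most negative mid-region median strain.

    Ties resolve to the earliest frame.  The mid region is taken from a
    :class:`~prmstrain.regions.RegionPartition` on the rest grid.
    """
    mid = partition.label_grid(series.strain.shape[1:]) == 2
    medians = np.full(series.n_frames, np.nan)
    for t in range(series.n_frames):
        vals = series.strain[t][mid]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            medians[t] = np.median(vals)
    if not np.isfinite(medians).any():
        raise EmptyRegionError("mid region has no defined strain in any frame")
    medians = np.where(np.isfinite(medians), medians, np.inf)
    return int(np.argmin(medians))
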