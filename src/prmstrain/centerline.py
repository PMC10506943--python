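"""Centerline extraction and tangential projection.

The muscle centerline stands in for the local fiber direction (motivated
by MR tractography of the pelvic floor): the segmentation is reduced to
a curve by 3D skeletonization, the longest geodesic path through the
skeleton is kept, each coordinate is smoothed by a least-squares
polynomial in normalized chord length (with one outlier-rejection pass),
and displacement vectors are projected onto the tangent at the closest
centerline point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .core import voxel_positions_mm
from .errors import DisconnectedMaskError, InputError, SpecificationError


@dataclass
class Centerline:
    """A fitted space curve with arc-length parameterization.

    ``points`` are densely sampled positions (mm), ``tangents`` the unit
    tangents of the fitted polynomial, ``arc_length`` the cumulative arc
    coordinate s (mm) starting at 0.  By default s = 0 is the end with
    the smaller x-coordinate, labeled "right" (ultrasound display
    convention places the patient's right on the image left).
    """

    points: np.ndarray
    tangents: np.ndarray
    arc_length: np.ndarray
    poly_degree: int

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InputError("centerline tangents must be unit-norm")
        if np.any(np.diff(self.arc_length) <= 0):
            raise InputError("arc_length must be strictly increasing")
        cosang = np.sum(self.tangents[:-1] * self.tangents[1:], axis=1)
        if np.any(cosang < 0):
            raise InputError("centerline folds back (tangent turn >= 90 deg)")

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def reversed(self) -> "Centerline":
        L = self.total_length
        return Centerline(
            points=self.points[::-1].copy(),
            tangents=-self.tangents[::-1],
            arc_length=L - self.arc_length[::-1],
            poly_degree=self.poly_degree,
        )


@dataclass
class ArcCoordinateMap:
    """Closest-centerline-point lookup for each mask voxel.

    For voxel ``voxels[i]``: ``s[i]`` is the arc coordinate of its
    nearest centerline sample, ``tangent[i]`` the unit tangent there and
    ``distance[i]`` the Euclidean distance to it.
    """

    voxels: np.ndarray  # (n, 3) int indices
    s: np.ndarray
    tangent: np.ndarray
    distance: np.ndarray
    total_length: float

    def s_grid(self, shape) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = self.s
        return out


def _skeleton_longest_path(skel_coords: np.ndarray, spacing) -> np.ndarray:
    """Order the skeleton by its longest geodesic path (double Dijkstra)."""
    pts = voxel_positions_mm(skel_coords, spacing)
    tree = cKDTree(skel_coords.astype(float))
    pairs = tree.query_pairs(r=np.sqrt(3.0) + 1e-6, output_type="ndarray")
    n = len(skel_coords)
    if len(pairs) == 0:
        return skel_coords[:1]
    w = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    g = coo_matrix(
        (np.r_[w, w], (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]])),
        shape=(n, n),
    ).tocsr()

    # restrict to the largest connected piece of the skeleton graph
    d0 = dijkstra(g, indices=0)
    if not np.isfinite(d0).all():
        from scipy.sparse.csgraph import connected_components

        ncomp, labels = connected_components(g, directed=False)
        keep = labels == np.bincount(labels).argmax()
        sub = _skeleton_longest_path(skel_coords[keep], spacing)
        return sub

    a = int(np.argmax(d0))
    da, pred = dijkstra(g, indices=a, return_predecessors=True)
    b = int(np.argmax(da))
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    return skel_coords[np.array(path[::-1])]


def extract_centerline(
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    degree: int = 5,
) -> Centerline:
    """Fit the centerline of a tubular binary mask.

    Step 1: the mask is eroded to its 3D skeleton and the longest
    geodesic path through it is kept.  Step 2: the ordered path,
    parameterized by normalized cumulative chord length, is fitted per
    coordinate by a least-squares polynomial; points farther than 2
    voxels from the fit are dropped and the fit repeated once.  The
    curve is resampled at <= 0.5 voxel spacing with tangents from the
    analytic polynomial derivative.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("mask is empty")
    ncomp = cc_label(mask, structure=np.ones((3, 3, 3), int))[1]
    if ncomp != 1:
        raise DisconnectedMaskError(
            f"mask must be a single connected component; found {ncomp}"
        )
    degree = int(degree)
    if degree < 1:
        raise SpecificationError("polynomial degree must be >= 1")

    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    path = _skeleton_longest_path(coords, spacing)
    if len(path) < degree + 1:
        raise SpecificationError(
            f"skeleton path has {len(path)} points; need degree+1 = {degree + 1}"
        )

    sp = np.asarray(spacing, float)
    pts = voxel_positions_mm(path, spacing)
    vox_mm = float(np.mean(sp))

    def fit(points: np.ndarray):
        chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
        t = chord / chord[-1]
        polys = [
            np.polynomial.Polynomial.fit(t, points[:, c], deg=min(degree, len(points) - 1))
            for c in range(3)
        ]
        return t, polys

    t, polys = fit(pts)
    fitted = np.stack([p(t) for p in polys], axis=1)
    resid = np.linalg.norm(fitted - pts, axis=1)
    keep = resid <= 2.0 * vox_mm
    if keep.sum() >= degree + 1 and not keep.all():
        t, polys = fit(pts[keep])

    # dense resample at <= 0.5 voxel spacing
    chord_est = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    n_fine = max(16, int(np.ceil(chord_est / (0.5 * float(sp.min())))) + 1)
    tf = np.linspace(0.0, 1.0, n_fine)
    points = np.stack([p(tf) for p in polys], axis=1)
    deriv = np.stack([p.deriv()(tf) for p in polys], axis=1)
    norms = np.linalg.norm(deriv, axis=1)
    if np.any(norms < 1e-12):
        raise SpecificationError("degenerate centerline fit (vanishing derivative)")
    tangents = deriv / norms[:, None]

    # the skeleton stops roughly one tube radius short of the band ends;
    # extend each end linearly along its tangent while still inside the
    # mask so that end voxels get distinct arc coordinates instead of
    # piling up on the last fitted sample.
    step = 0.5 * float(sp.min())
    points, tangents = _extend_end(points, tangents, mask, sp, step, head=True)
    points, tangents = _extend_end(points, tangents, mask, sp, step, head=False)

    if points[0, 0] > points[-1, 0]:  # s = 0 at the smaller-x ("right") end
        points = points[::-1].copy()
        tangents = -tangents[::-1]

    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    ok = np.r_[True, steps > 1e-12]
    points, tangents = points[ok], tangents[ok]
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    return Centerline(points=points, tangents=tangents, arc_length=arc, poly_degree=degree)


def _extend_end(points, tangents, mask, spacing, step, head, max_steps=40):
    """Linearly extend one end of the curve while it stays in the mask."""
    if head:
        p, t = points[0], -tangents[0]
    else:
        p, t = points[-1], tangents[-1]
    extra = []
    for k in range(1, max_steps + 1):
        q = p + k * step * t
        idx = np.rint(q / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)) or not mask[tuple(idx)]:
            break
        extra.append(q)
    if not extra:
        return points, tangents
    extra = np.asarray(extra)
    if head:
        points = np.vstack([extra[::-1], points])
        tangents = np.vstack([np.tile(tangents[0], (len(extra), 1)), tangents])
    else:
        points = np.vstack([points, extra])
        tangents = np.vstack([tangents, np.tile(tangents[-1], (len(extra), 1))])
    return points, tangents


def build_arc_map(
    mask: np.ndarray,
    cl: Centerline,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ArcCoordinateMap:
    """Map each mask voxel to its closest centerline sample.

    Ties in Euclidean distance resolve to the smaller arc coordinate.
    """
    mask = np.asarray(mask, dtype=bool)
    voxels = np.argwhere(mask)
    pts = voxel_positions_mm(voxels, spacing)
    tree = cKDTree(cl.points)
    dist2, idx2 = tree.query(pts, k=2)
    idx = idx2[:, 0].copy()
    tie = np.isclose(dist2[:, 0], dist2[:, 1], rtol=0.0, atol=1e-9)
    idx[tie] = np.minimum(idx2[tie, 0], idx2[tie, 1])
    return ArcCoordinateMap(
        voxels=voxels,
        s=cl.arc_length[idx],
        tangent=cl.tangents[idx],
        distance=dist2[:, 0] if idx2.ndim == 2 else dist2,
        total_length=cl.total_length,
    )


def project_displacements(vectors: np.ndarray, amap: ArcCoordinateMap) -> np.ndarray:
    """Scalar tangential displacement (mm): vector . tangent per voxel.

    Positive along increasing s; undefined (NaN) vectors stay undefined.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape != amap.tangent.shape:
        raise InputError(
            f"vectors shape {vectors.shape} does not match map {amap.tangent.shape}"
        )
    return np.einsum("ij,ij->i", vectors, amap.tangent)
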