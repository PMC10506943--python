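"""Centerline fitting, arc-coordinate mapping and tangential projection."""

import numpy as np
import pytest

from prmstrain.centerline import (
    build_arc_map,
    extract_centerline,
    project_displacements,
)
from prmstrain.errors import DisconnectedMaskError, InputError


def _cylinder_mask(shape=(48, 16, 16), axis_y=8.0, axis_z=8.0, radius=4.0, length=(4, 44)):
    x, y, z = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    return (
        ((y - axis_y) ** 2 + (z - axis_z) ** 2 <= radius**2)
        & (x >= length[0])
        & (x < length[1])
    )


def _half_torus_mask(shape=(56, 40, 16), R=20.0, r=3.5):
    c = (np.asarray(shape) - 1) / 2.0
    x, y, z = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    rho = np.hypot(x - c[0], y - c[1])
    d = np.sqrt((rho - R) ** 2 + (z - c[2]) ** 2)
    return (d <= r) & (y >= c[1])


class TestExtractCenterline:
    def test_cylinder_axis_recovered(self):
        mask = _cylinder_mask()
        cl = extract_centerline(mask, (1.0, 1.0, 1.0), degree=3)
        # fitted line within 1 voxel of the true axis, tangents within 5 deg
        off_axis = np.hypot(cl.points[:, 1] - 8.0, cl.points[:, 2] - 8.0)
        assert off_axis.max() < 1.0
        ang = np.degrees(np.arccos(np.clip(np.abs(cl.tangents[:, 0]), 0, 1)))
        assert ang.max() < 5.0

    def test_half_torus_arc_recovered(self):
        mask = _half_torus_mask()
        c = (np.asarray(mask.shape) - 1) / 2.0
        cl = extract_centerline(mask, (1.0, 1.0, 1.0), degree=5)
        rho = np.hypot(cl.points[:, 0] - c[0], cl.points[:, 1] - c[1])
        d = np.sqrt((rho - 20.0) ** 2 + (cl.points[:, 2] - c[2]) ** 2)
        assert np.percentile(d, 95) < 1.5
        # tangent error away from the curve ends
        sel = (cl.arc_length > 5) & (cl.arc_length < cl.total_length - 5)
        phi = np.arctan2(cl.points[:, 1] - c[1], cl.points[:, 0] - c[0])
        ana = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=1)
        dots = np.abs(np.einsum("ij,ij->i", cl.tangents, ana))
        assert np.degrees(np.arccos(np.clip(dots[sel], 0, 1))).max() < 10.0

    def test_digital_segment_is_its_own_skeleton(self):
        mask = np.zeros((40, 9, 9), bool)
        mask[5:35, 4, 4] = True
        cl = extract_centerline(mask, (1.0, 1.0, 1.0), degree=2)
        vox = np.argwhere(mask).astype(float)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cl.points).query(vox)
        assert d.max() < 0.5

    def test_orientation_starts_at_smaller_x(self):
        cl = extract_centerline(_cylinder_mask(), (1.0, 1.0, 1.0), degree=3)
        assert cl.points[0, 0] < cl.points[-1, 0]

    def test_reversed_flips_s_and_tangents(self):
        cl = extract_centerline(_cylinder_mask(), (1.0, 1.0, 1.0), degree=3)
        rev = cl.reversed()
        assert rev.total_length == pytest.approx(cl.total_length)
        np.testing.assert_allclose(rev.points[0], cl.points[-1])
        np.testing.assert_allclose(rev.tangents[0], -cl.tangents[-1])

    def test_disconnected_mask_reports_component_count(self):
        mask = _cylinder_mask()
        mask2 = mask.copy()
        mask2[20:24] = False
        with pytest.raises(DisconnectedMaskError, match="2"):
            extract_centerline(mask2, (1.0, 1.0, 1.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            extract_centerline(np.zeros((8, 8, 8), bool), (1.0, 1.0, 1.0))


class TestArcMap:
    def test_voxel_on_centerline_and_brute_force_oracle(self, rng):
        mask = _cylinder_mask()
        cl = extract_centerline(mask, (1.0, 1.0, 1.0), degree=3)
        amap = build_arc_map(mask, cl, (1.0, 1.0, 1.0))
        # brute force nearest-point search on a random voxel subset
        pick = rng.choice(amap.voxels.shape[0], size=50, replace=False)
        for i in pick:
            p = amap.voxels[i].astype(float)
            d = np.linalg.norm(cl.points - p, axis=1)
            j = int(np.argmin(d))
            assert amap.distance[i] == pytest.approx(d[j], abs=1e-9)
            assert amap.s[i] == pytest.approx(cl.arc_length[j], abs=1e-6)
        assert amap.s.min() >= 0.0
        assert amap.s.max() <= cl.total_length + 1e-9
        np.testing.assert_allclose(np.linalg.norm(amap.tangent, axis=1), 1.0, atol=1e-6)

    def test_tie_takes_smaller_s(self):
        from prmstrain.centerline import ArcCoordinateMap, Centerline

        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        tang = np.tile([1.0, 0, 0], (3, 1))
        cl = Centerline(pts, tang, np.array([0.0, 2.0, 4.0]), 1)
        mask = np.zeros((5, 3, 3), bool)
        mask[1, 0, 0] = True  # x=1: equidistant from samples at x=0 and x=2
        amap = build_arc_map(mask, cl, (1.0, 1.0, 1.0))
        assert amap.s[0] == 0.0


class TestProjection:
    def _map_with_tangent(self, tangent):
        from prmstrain.centerline import ArcCoordinateMap

        return ArcCoordinateMap(
            voxels=np.zeros((1, 3), int),
            s=np.zeros(1),
            tangent=np.asarray([tangent], float),
            distance=np.zeros(1),
            total_length=1.0,
        )

    def test_parallel_orthogonal_and_oblique(self):
        t = [1.0, 0.0, 0.0]
        assert project_displacements(np.array([[3.0, 0, 0]]), self._map_with_tangent(t))[0] == 3.0
        assert project_displacements(np.array([[0.0, 2, 0]]), self._map_with_tangent(t))[0] == 0.0
        assert project_displacements(np.array([[1.0, 1, 0]]), self._map_with_tangent(t))[0] == 1.0

    def test_projection_bound_and_nan_propagation(self, rng):
        n = 500
        v = rng.normal(size=(n, 3))
        t = rng.normal(size=(n, 3))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        from prmstrain.centerline import ArcCoordinateMap

        amap = ArcCoordinateMap(
            voxels=np.zeros((n, 3), int),
            s=np.zeros(n),
            tangent=t,
            distance=np.zeros(n),
            total_length=1.0,
        )
        v[7] = np.nan
        p = project_displacements(v, amap)
        assert np.isnan(p[7])
        ok = np.isfinite(p)
        assert np.all(np.abs(p[ok]) <= np.linalg.norm(v[ok], axis=1) + 1e-12)

    def test_phantom_tangential_motion_recovered(self, small_phantom):
        # projecting the true 3-vector motion on the analytic tangents
        # recovers the generator's scalar u(s) away from the tapers
        from prmstrain.phantom import _arc_coordinates, tangential_displacement
        from prmstrain.core import voxel_positions_mm

        ds = small_phantom
        spec = ds.spec
        v = np.argwhere(ds.rest_mask)
        pts = voxel_positions_mm(v, spec.spacing)
        s, d, tang, _ = _arc_coordinates(spec, pts)
        p = np.einsum("ij,ij->i", ds.true_displacement[-1][ds.rest_mask], tang)
        expected = tangential_displacement(spec, s)
        assert np.abs(p - expected).max() < 0.1
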