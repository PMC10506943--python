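"""Least-squares strain estimation and max-contraction selection."""

import numpy as np
import pytest
from itertools import product

from prmstrain.centerline import ArcCoordinateMap
from prmstrain.errors import EmptyRegionError
from prmstrain.regions import RegionPartition
from prmstrain.strain import StrainSeries, lsq_strain, masked_smooth, select_max_contraction


def _linear_setup(shape=(10, 8, 8), slope=0.02, offset=0.0):
    """p(s) = slope * s with s increasing along x."""
    mask = np.ones(shape, bool)
    x = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")[0]
    s_grid = x.copy()  # s = x in mm
    p_grid = slope * s_grid + offset
    return p_grid, s_grid, mask


class TestLsqStrain:
    def test_exact_linear_field(self):
        p, s, mask = _linear_setup(slope=0.02)
        out = lsq_strain(p, s, mask)
        ok = np.isfinite(out)
        assert ok.any()
        np.testing.assert_allclose(out[ok], 2.0, atol=1e-10)

    def test_constant_field_gives_zero(self):
        p, s, mask = _linear_setup(slope=0.0, offset=1.7)
        out = lsq_strain(p, s, mask)
        np.testing.assert_allclose(out[np.isfinite(out)], 0.0, atol=1e-10)

    def test_translation_and_scaling_invariances(self):
        p, s, mask = _linear_setup(slope=0.015)
        base = lsq_strain(p, s, mask)
        shifted = lsq_strain(p + 5.0, s, mask)
        scaled = lsq_strain(3.0 * p, s, mask)
        ok = np.isfinite(base)
        np.testing.assert_allclose(shifted[ok], base[ok], atol=1e-9)
        np.testing.assert_allclose(scaled[ok], 3.0 * base[ok], atol=1e-9)

    def test_matches_normal_equation_oracle_on_random_neighborhoods(self, rng):
        # 1000 random 8-sample neighborhoods checked against the
        # closed-form normal equations
        for _ in range(1000):
            s8 = rng.uniform(0, 10, size=8)
            p8 = rng.normal(size=8)
            mask = np.ones((2, 2, 2), bool)
            s_grid = s8.reshape(2, 2, 2)
            p_grid = p8.reshape(2, 2, 2)
            out = lsq_strain(p_grid, s_grid, mask)
            n = 8
            slope = (n * (s8 * p8).sum() - s8.sum() * p8.sum()) / (
                n * (s8**2).sum() - s8.sum() ** 2
            )
            assert out[0, 0, 0] == pytest.approx(100.0 * slope, rel=1e-10)

    def test_low_support_and_degenerate_abscissa_undefined(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, :3] = True  # only 3 members
        s = np.where(mask, 1.0, np.nan) * np.arange(4)
        p = np.zeros((4, 4, 4))
        out = lsq_strain(p, s, mask)
        assert np.isnan(out[0, 0, 0])
        # constant s: variance below threshold
        mask2 = np.ones((3, 3, 3), bool)
        s2 = np.full((3, 3, 3), 2.0)
        out2 = lsq_strain(np.zeros((3, 3, 3)), s2, mask2)
        assert np.isnan(out2).all()

    def test_flat_proj_with_arc_map(self):
        vox = np.array(list(product(range(2), repeat=3)))
        amap = ArcCoordinateMap(
            voxels=vox,
            s=vox[:, 0].astype(float),
            tangent=np.tile([1.0, 0, 0], (8, 1)),
            distance=np.zeros(8),
            total_length=1.0,
        )
        mask = np.ones((2, 2, 2), bool)
        p = 0.05 * vox[:, 0].astype(float)
        out = lsq_strain(p, amap, mask)
        np.testing.assert_allclose(out[np.isfinite(out)], 5.0, atol=1e-9)


class TestMaskedSmooth:
    def test_preserves_linear_field_inside_mask(self):
        p, s, mask = _linear_setup(shape=(24, 8, 8), slope=0.03)
        sm = masked_smooth(p, mask, 1.5)
        interior = np.zeros_like(mask)
        interior[8:-8, 2:-2, 2:-2] = True
        np.testing.assert_allclose(sm[interior], p[interior], atol=1e-6)

    def test_ignores_out_of_mask_values(self):
        vals = np.full((8, 8, 8), 100.0)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        vals[mask] = 1.0
        sm = masked_smooth(vals, mask, 2.0)
        np.testing.assert_allclose(sm[mask], 1.0, atol=1e-9)
        assert np.isnan(sm[~mask]).all()


def _series_with_mid_medians(values):
    """Minimal StrainSeries + partition whose mid medians equal `values`."""
    shape = (4, 4, 4)
    T = len(values)
    strain = np.full((T, *shape), np.nan)
    vox = np.array(list(product(range(2), repeat=3)))
    labels = np.full(8, 2, np.uint8)
    labels[0] = 1
    labels[-1] = 3
    for t, v in enumerate(values):
        for x, y, z in vox:
            strain[t, x, y, z] = v
    part = RegionPartition(
        voxels=vox, labels=labels, s_lo=0.1, s_hi=0.9, end_fraction=1 / 3, orientation="right_at_s0"
    )
    series = StrainSeries(
        strain=strain,
        masks=np.ones((T, *shape), bool),
        rest_voxels=vox,
        accumulated=np.zeros((T, 8, 3)),
        projected=np.zeros((T, 8)),
        rest_centerline=None,
        rest_arc_map=None,
        mode="incremental",
    )
    return series, part


class TestSelectMaxContraction:
    def test_monotone_ramp_selects_last_frame(self):
        series, part = _series_with_mid_medians([0.0, -2.0, -5.0, -9.0])
        assert select_max_contraction(series, part) == 3

    def test_up_down_ramp_selects_peak(self):
        series, part = _series_with_mid_medians([0.0, -4.0, -8.0, -3.0, 0.0])
        assert select_max_contraction(series, part) == 2

    def test_tie_takes_earliest(self):
        series, part = _series_with_mid_medians([0.0, -8.0, -8.0])
        assert select_max_contraction(series, part) == 1

    def test_single_frame_returns_zero(self):
        series, part = _series_with_mid_medians([0.0])
        assert select_max_contraction(series, part) == 0

    def test_all_undefined_mid_raises(self):
        series, part = _series_with_mid_medians([0.0])
        series.strain[:] = np.nan
        with pytest.raises(EmptyRegionError):
            select_max_contraction(series, part)
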