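"""Phantom generator: determinism, analytic profiles, ground-truth
consistency."""

import numpy as np
import pytest

from prmstrain.errors import DomainError, SpecificationError
from prmstrain.phantom import (
    CohortSpec,
    analytic_strain_profile,
    arc_points,
    arc_tangents,
    generate_cohort_ratios,
    generate_phantom,
    strain_profile,
    tangential_displacement,
)
from tests.conftest import small_spec


class TestSpecValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"arc_span": 0.0},
            {"arc_span": 360.0},
            {"tube_radius": 30.0},
            {"n_frames": 1},
            {"peak_mid_strain": 0.05},
            {"contraction_ramp": (0.5, 1.0, 1.0, 1.0, 1.0)},  # must start at 0
            {"contraction_ramp": (0.0, 0.6, 0.4, 0.8, 1.0)},  # non-decreasing
            {"condition": "bilateral"},
        ],
    )
    def test_invalid_specs_rejected(self, overrides):
        with pytest.raises(SpecificationError):
            small_spec(**overrides)


class TestStrainProfile:
    def test_mid_and_end_values(self):
        spec = small_spec()
        L = spec.arc_length
        last = spec.n_frames - 1
        assert analytic_strain_profile(spec, L / 2, last) == pytest.approx(-10.0)
        assert analytic_strain_profile(spec, 0.0, last) == pytest.approx(20.0)
        assert analytic_strain_profile(spec, L, last) == pytest.approx(20.0)

    def test_rest_frame_is_zero(self):
        spec = small_spec()
        s = np.linspace(0, spec.arc_length, 50)
        assert np.all(analytic_strain_profile(spec, s, 0) == 0.0)

    def test_out_of_range_position_rejected(self):
        spec = small_spec()
        with pytest.raises(DomainError):
            analytic_strain_profile(spec, -1.0, 1)
        with pytest.raises(DomainError):
            analytic_strain_profile(spec, spec.arc_length + 1.0, 1)

    def test_taper_matches_displacement_derivative(self):
        # finite-difference oracle: e(s) must be du/ds everywhere,
        # including inside the cosine transition bands
        spec = small_spec()
        L = spec.arc_length
        s = np.linspace(1e-3, L - 1e-3, 4001)
        du = np.gradient(tangential_displacement(spec, s), s)
        np.testing.assert_allclose(du, strain_profile(spec, s), atol=5e-4)

    def test_avulsed_end_carries_mid_strain(self):
        spec = small_spec(condition="avulsed_left")
        last = spec.n_frames - 1
        assert analytic_strain_profile(spec, spec.arc_length, last) == pytest.approx(-10.0)
        assert analytic_strain_profile(spec, 0.0, last) == pytest.approx(20.0)

    def test_anchoring(self):
        # intact: both ends fixed; avulsed: only the intact end
        L = small_spec().arc_length
        ends = np.array([0.0, L])
        u = tangential_displacement(small_spec(), ends)
        assert np.all(np.abs(u) < 0.05)
        u_l = tangential_displacement(small_spec(condition="avulsed_left"), ends)
        assert abs(u_l[0]) < 0.05 and abs(u_l[1]) > 1.0
        u_r = tangential_displacement(small_spec(condition="avulsed_right"), ends)
        assert abs(u_r[1]) < 0.05 and abs(u_r[0]) > 1.0


class TestGeneratePhantom:
    def test_seeded_determinism(self):
        a = generate_phantom(small_spec(), seed=5)
        b = generate_phantom(small_spec(), seed=5)
        assert np.array_equal(a.volumes.data, b.volumes.data)
        assert np.array_equal(a.rest_mask, b.rest_mask)
        assert np.array_equal(a.true_displacement, b.true_displacement)

    def test_zero_ramp_freezes_frames(self):
        spec = small_spec(contraction_ramp=(0.0,) * 5, noise_level=0.0)
        ds = generate_phantom(spec, seed=5)
        for t in range(1, 5):
            assert np.array_equal(ds.volumes.frame(t), ds.volumes.frame(0))
        assert np.nanmax(np.abs(ds.true_strain)) == 0.0

    def test_frame0_displacement_zero_and_monotone_magnitude(self, small_phantom):
        ds = small_phantom
        assert np.all(ds.true_displacement[0] == 0.0)
        mag = np.linalg.norm(ds.true_displacement, axis=-1)
        assert np.all(np.diff(mag, axis=0) >= -1e-9)

    def test_intensities_non_negative(self, small_phantom):
        assert small_phantom.volumes.data.min() >= 0.0

    def test_mid_region_truth_at_full_activation(self, small_phantom):
        spec = small_phantom.spec
        mid = spec.arc_length / 2
        assert analytic_strain_profile(spec, mid, spec.n_frames - 1) == pytest.approx(-10.0)
        # strain field inside the band carries the same value
        truth = small_phantom.true_strain[-1]
        vals = truth[np.isfinite(truth)]
        assert np.nanmin(vals) == pytest.approx(-10.0, abs=1e-4)
        assert np.nanmax(vals) == pytest.approx(20.0, abs=1e-4)

    def test_numerical_strain_of_truth_matches_profile(self, small_phantom):
        # finite differences of the true displacement along the analytic
        # centerline reproduce the analytic profile away from the tapers
        ds = small_phantom
        spec = ds.spec
        L = spec.arc_length
        s = np.linspace(0.5, L - 0.5, 400)
        pts = arc_points(spec, s)
        tang = arc_tangents(spec, s)
        from prmstrain.propagation import sample_dense

        u3 = sample_dense(ds.true_displacement[-1].astype(float), pts / np.asarray(spec.spacing))
        p = np.einsum("ij,ij->i", u3, tang)
        num = np.gradient(p, s) * 100.0
        ana = strain_profile(spec, s) * 100.0
        w = spec.taper_frac * L
        away = np.ones_like(s, bool)
        for b in (L / 6, 5 * L / 6):
            away &= np.abs(s - b) > w
        away &= (s > 1.5) & (s < L - 1.5)
        assert np.abs(num - ana)[away].max() < 0.5


class TestCohortRatios:
    def test_degenerate_spread_returns_median(self):
        cs = CohortSpec(ratio_log_sd=(0.0, 0.0), seed=1)
        a, b = generate_cohort_ratios(cs)
        assert np.allclose(a, 0.36) and np.allclose(b, 1.54)

    def test_seeded_determinism(self):
        a1, b1 = generate_cohort_ratios(CohortSpec(seed=9))
        a2, b2 = generate_cohort_ratios(CohortSpec(seed=9))
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_large_sample_median(self):
        cs = CohortSpec(n_per_group=(10000, 10000), seed=2)
        _, b = generate_cohort_ratios(cs)
        assert np.median(b) == pytest.approx(1.54, rel=0.05)

    def test_invalid_cohort_rejected(self):
        with pytest.raises(SpecificationError):
            CohortSpec(n_per_group=(1, 10))
        with pytest.raises(SpecificationError):
            CohortSpec(ratio_median=(0.0, 1.0))
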