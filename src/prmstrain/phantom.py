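"""Synthetic speckle phantoms of a sling-shaped muscle under contraction.

The puborectal muscle is a C-shaped band whose two ends attach to the
pubic symphysis.  The phantom emulates a transperineal 3D ultrasound
acquisition of such a band over a rest-to-contraction cycle:

* geometry: a circular arc (default half-annulus) in one grid plane,
  extruded to a tube of radius ``tube_radius`` — the simplest shape with
  a curved fiber direction and two distinguishable ends;
* tissue: point scatterers placed uniformly at random with Rayleigh
  amplitudes, rendered per frame by point-spread-function blurring plus
  additive noise, which produces fully developed, trackable speckle;
* motion: a known tangential contraction field.  The strain profile
  ``e(s)`` along the arc is piecewise constant with cosine-tapered
  transitions: the mid section (2/3 of the arc) contracts with
  ``peak_mid_strain`` while anchored end sections elongate.  For an
  intact muscle both ends are anchored to the bone, which forces the
  balancing end strain ``-2 * peak_mid_strain`` (zero net end-to-end
  displacement).  For a unilateral avulsion the detached end co-contracts
  with the mid section (strain ``peak_mid_strain``) and only the intact
  end is anchored.

Every dataset carries its analytic ground truth (displacement, strain,
centerline), so tracking and strain estimation can be scored against
exact answers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import VolumeSequence
from .errors import DomainError, SpecificationError

CONDITIONS = ("intact", "avulsed_left", "avulsed_right")

#: Volume rate of the emulated clinical acquisition (Hz).
VOLUME_RATE_HZ = 1.5


@dataclass
class PhantomSpec:
    """Parameters of one synthetic muscle phantom.

    Defaults are the package's reference study conditions: a 64 mm cube
    at 1 mm isotropic spacing, 8 frames at the 1.5 Hz clinical volume
    rate ramping linearly from rest to full activation, and a peak mid
    strain of -10%.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_frames: int = 8
    frame_interval: float = 1.0 / VOLUME_RATE_HZ
    arc_radius: float = 20.0
    arc_span: float = 180.0
    tube_radius: float = 4.0
    scatterer_density: float = 2.0
    psf_sigma: tuple[float, float, float] = (1.2, 1.2, 1.2)
    noise_level: float = 0.05
    condition: str = "intact"
    peak_mid_strain: float = -0.10
    contraction_ramp: tuple[float, ...] | None = None
    taper_frac: float = 0.10
    #: rigid whole-volume translation per frame (mm); adds no strain and
    #: serves as the rigid-motion null condition
    bulk_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.contraction_ramp is None:
            self.contraction_ramp = tuple(np.linspace(0.0, 1.0, self.n_frames))
        else:
            self.contraction_ramp = tuple(float(a) for a in self.contraction_ramp)
        self.validate()

    def validate(self) -> None:
        if self.n_frames < 2:
            raise SpecificationError("n_frames must be >= 2")
        if not (0.0 < self.arc_span < 360.0):
            raise SpecificationError("arc_span must lie in (0, 360) degrees")
        if not (0.0 < self.tube_radius < self.arc_radius):
            raise SpecificationError("tube_radius must satisfy 0 < tube_radius < arc_radius")
        if len(self.contraction_ramp) != self.n_frames:
            raise SpecificationError("contraction_ramp must have length n_frames")
        if abs(self.contraction_ramp[0]) > 0:
            raise SpecificationError("contraction_ramp must start at 0 (rest frame)")
        if any(b < a - 1e-12 for a, b in zip(self.contraction_ramp, self.contraction_ramp[1:])):
            raise SpecificationError("contraction_ramp must be non-decreasing")
        if any(a < 0 or a > 1 for a in self.contraction_ramp):
            raise SpecificationError("contraction_ramp values must lie in [0, 1]")
        if self.peak_mid_strain >= 0:
            raise SpecificationError("peak_mid_strain must be negative (contraction)")
        if self.condition not in CONDITIONS:
            raise SpecificationError(f"condition must be one of {CONDITIONS}")
        if any(s <= 0 for s in self.spacing) or len(self.spacing) != 3:
            raise SpecificationError("spacing must be 3 positive mm values")
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise SpecificationError("grid_shape must be 3 integers >= 8")
        if self.scatterer_density <= 0:
            raise SpecificationError("scatterer_density must be positive")
        if self.noise_level < 0:
            raise SpecificationError("noise_level must be non-negative")
        if not (0.0 < self.taper_frac < 1.0 / 3.0):
            raise SpecificationError("taper_frac must lie in (0, 1/3)")

    @property
    def arc_length(self) -> float:
        """Total centerline arc length in mm."""
        return self.arc_radius * math.radians(self.arc_span)

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, float) - 1.0) / 2.0 * np.asarray(self.spacing)


@dataclass
class CenterlineTruth:
    """Analytic arc samples: positions, unit tangents, arc coordinate."""

    s: np.ndarray
    points: np.ndarray
    tangents: np.ndarray


@dataclass
class PhantomDataset:
    """A rendered phantom plus its analytic ground truth."""

    spec: PhantomSpec
    seed: int
    volumes: VolumeSequence
    rest_mask: np.ndarray
    true_displacement: np.ndarray  # (t, x, y, z, 3) mm, cumulative from frame 0
    true_strain: np.ndarray  # (t, x, y, z) percent, NaN outside the band
    true_centerline: CenterlineTruth


# ---------------------------------------------------------------------------
# Arc geometry.  The arc lies in the z = center plane.  Parameterizing the
# position angle as alpha(s) = pi - s / R, the s = 0 end sits at x = -R
# (the image-left end, labeled "right" by ultrasound display convention)
# and s = L at angle pi - span.

def _arc_alpha(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    return math.pi - np.asarray(s, float) / spec.arc_radius


def arc_points(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Centerline positions (mm) at arc coordinates ``s``."""
    alpha = _arc_alpha(spec, s)
    c = spec.center_mm
    return np.stack(
        [
            c[0] + spec.arc_radius * np.cos(alpha),
            c[1] + spec.arc_radius * np.sin(alpha),
            np.full_like(alpha, c[2]),
        ],
        axis=-1,
    )


def arc_tangents(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Unit tangents d(position)/ds at arc coordinates ``s``."""
    alpha = _arc_alpha(spec, s)
    return np.stack([np.sin(alpha), -np.cos(alpha), np.zeros_like(alpha)], axis=-1)


def _arc_coordinates(spec: PhantomSpec, pts: np.ndarray):
    """Arc coordinate, distance to centerline and tangent for points (n, 3).

    Points whose azimuth falls outside the arc span are assigned the
    nearer endpoint (clamped s) with the Euclidean endpoint distance, so
    the derived motion field is continuous everywhere.
    """
    pts = np.asarray(pts, float)
    c = spec.center_mm
    dx, dy, dz = pts[:, 0] - c[0], pts[:, 1] - c[1], pts[:, 2] - c[2]
    rho = np.hypot(dx, dy)
    alpha = np.arctan2(dy, dx)
    span = math.radians(spec.arc_span)
    L = spec.arc_length

    s = (math.pi - alpha) * spec.arc_radius
    in_span = (s >= 0.0) & (s <= L)
    d = np.sqrt((rho - spec.arc_radius) ** 2 + dz**2)

    # out-of-span: clamp to nearer endpoint
    out = ~in_span
    if np.any(out):
        ends = arc_points(spec, np.array([0.0, L]))
        d0 = np.linalg.norm(pts[out] - ends[0], axis=1)
        d1 = np.linalg.norm(pts[out] - ends[1], axis=1)
        s_out = np.where(d0 <= d1, 0.0, L)
        s = s.copy()
        s[out] = s_out
        d[out] = np.minimum(d0, d1)
    tang = arc_tangents(spec, s)
    return s, d, tang, in_span


# ---------------------------------------------------------------------------
# Strain profile along the arc and its cumulative (displacement) integral.

def _profile_sections(spec: PhantomSpec):
    """End values, section boundaries and anchor of the strain profile."""
    L = spec.arc_length
    w = spec.taper_frac * L
    s1, s2 = L / 6.0, 5.0 * L / 6.0
    e_mid = spec.peak_mid_strain
    e_balance = -2.0 * e_mid  # zero net displacement over an anchored arc
    if spec.condition == "intact":
        e_right, e_left = e_balance, e_balance
        anchor = 0.0  # both ends anchored; integral vanishes by construction
    elif spec.condition == "avulsed_left":
        e_right, e_left = e_balance, e_mid
        anchor = 0.0  # s = 0 (right) end stays attached
    else:  # avulsed_right
        e_right, e_left = e_mid, e_balance
        anchor = L
    return e_right, e_mid, e_left, s1, s2, w, anchor


def strain_profile(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Dimensionless tangential strain e(s) at full activation."""
    e_r, e_m, e_l, s1, s2, w, _ = _profile_sections(spec)
    s = np.asarray(s, float)

    def taper(a, b, t0):
        u = np.clip((s - t0) / w, 0.0, 1.0)
        return a + (b - a) * 0.5 * (1.0 - np.cos(math.pi * u))

    out = np.full(s.shape, e_m)
    out = np.where(s < s1 + w / 2, taper(e_r, e_m, s1 - w / 2), out)
    out = np.where(s <= s1 - w / 2, e_r, out)
    out = np.where(s > s2 - w / 2, taper(e_m, e_l, s2 - w / 2), out)
    out = np.where(s >= s2 + w / 2, e_l, out)
    return out


def _cumint_profile(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Closed-form integral of ``strain_profile`` from 0 to s (mm)."""
    e_r, e_m, e_l, s1, s2, w, _ = _profile_sections(spec)
    s = np.asarray(s, float)

    def taper_int(a, b, t0):
        # integral of the cosine taper from t0 to min(s, t0+w), clipped
        x = np.clip(s - t0, 0.0, w)
        return a * x + (b - a) * 0.5 * (x - (w / math.pi) * np.sin(math.pi * x / w))

    b1, b2, b3, b4 = s1 - w / 2, s1 + w / 2, s2 - w / 2, s2 + w / 2
    out = e_r * np.clip(s, 0.0, b1)
    out += taper_int(e_r, e_m, b1)
    out += e_m * np.clip(s - b2, 0.0, b3 - b2)
    out += taper_int(e_m, e_l, b3)
    out += e_l * np.clip(s - b4, 0.0, None)
    return out


def tangential_displacement(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Scalar tangential displacement u(s) (mm) at full activation.

    Zero at the anchored end(s): for an intact muscle the profile
    integrates to zero end-to-end, so both ends are fixed; for an
    avulsion only the intact end is fixed.
    """
    *_, anchor = _profile_sections(spec)
    u = _cumint_profile(spec, s)
    u0 = _cumint_profile(spec, np.asarray([anchor]))[0]
    return u - u0


def analytic_strain_profile(spec: PhantomSpec, arc_position, frame: int):
    """Ground-truth percent strain at ``arc_position`` (mm) and ``frame``."""
    s = np.asarray(arc_position, float)
    if np.any(s < -1e-9) or np.any(s > spec.arc_length + 1e-9):
        raise DomainError(
            f"arc_position must lie in [0, {spec.arc_length:.3f}] mm"
        )
    if not (0 <= frame < spec.n_frames):
        raise DomainError(f"frame must lie in [0, {spec.n_frames})")
    a = spec.contraction_ramp[frame]
    out = a * strain_profile(spec, np.clip(s, 0.0, spec.arc_length)) * 100.0
    return float(out) if np.isscalar(arc_position) else out


def _radial_falloff(spec: PhantomSpec, d: np.ndarray) -> np.ndarray:
    """Motion weight vs distance from the centerline: 1 inside the tube,
    cosine decay to 0 over one extra tube radius."""
    r = spec.tube_radius
    u = np.clip((d - r) / r, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(math.pi * u))


def motion_field_at(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Full-activation 3D displacement (mm) at rest positions (n, 3)."""
    s, d, tang, _ = _arc_coordinates(spec, pts)
    u = tangential_displacement(spec, s) * _radial_falloff(spec, d)
    return u[:, None] * tang


# ---------------------------------------------------------------------------
# Rendering.

def _render_gaussians(
    pos_vox: np.ndarray,
    amp: np.ndarray,
    shape,
    sigma_vox: np.ndarray,
) -> np.ndarray:
    """Sum separable Gaussian point-spread contributions on the grid.

    Each scatterer deposits ``amp * exp(-d^2 / 2 sigma^2)`` per axis,
    truncated at ~2.8 sigma.  Unlike splat-then-blur, the image is an
    exact continuous function of scatterer position, so a rigidly
    translated phantom really is a translation of the same speckle
    (no grid-phase modulation that a tracker would mistake for motion).
    """
    from ._blockmatch import render_gaussians

    nx, ny, nz = (int(n) for n in shape)
    radii = np.maximum(np.ceil(2.8 * sigma_vox).astype(int), 1)
    norm = 1.0 / float(np.prod(np.sqrt(2.0 * math.pi) * sigma_vox))
    return render_gaussians(
        np.ascontiguousarray(pos_vox, float),
        np.ascontiguousarray(amp * norm, float),
        nx, ny, nz,
        float(sigma_vox[0]), float(sigma_vox[1]), float(sigma_vox[2]),
        int(radii[0]), int(radii[1]), int(radii[2]),
    )


def _grid_positions_mm(spec: PhantomSpec) -> np.ndarray:
    axes = [np.arange(n) * sp for n, sp in zip(spec.grid_shape, spec.spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomDataset:
    """Render a seeded phantom sequence with analytic ground truth.

    Deterministic given ``(spec, seed)``.  Scatterers move with the
    analytic tangential motion field evaluated at their rest positions
    (Lagrangian motion); each frame is the PSF-blurred scatterer image
    plus additive Gaussian noise, clipped to non-negative intensities.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, float)
    extent = (np.asarray(shape, float) - 1.0) * spacing

    n_scat = max(1, int(round(spec.scatterer_density * float(np.prod(extent)))))
    pos = rng.uniform(0.0, 1.0, size=(n_scat, 3)) * extent
    amp = rng.rayleigh(1.0, size=n_scat)
    disp_full = motion_field_at(spec, pos)
    bulk = np.asarray(spec.bulk_velocity, float)

    sigma_vox = np.asarray(spec.psf_sigma, float) / spacing
    frames = np.empty((spec.n_frames, *shape), dtype=np.float32)
    reference_mean = None
    for t, act in enumerate(spec.contraction_ramp):
        img = _render_gaussians(
            (pos + act * disp_full + t * bulk) / spacing, amp, shape, sigma_vox
        )
        if reference_mean is None:
            reference_mean = float(img.mean())
        if spec.noise_level > 0:
            img = img + rng.normal(0.0, spec.noise_level * reference_mean, size=shape)
        np.clip(img, 0.0, None, out=img)
        frames[t] = img.astype(np.float32)

    grid_pts = _grid_positions_mm(spec)
    s, d, _, in_span = _arc_coordinates(spec, grid_pts)
    rest_mask = ((d <= spec.tube_radius) & in_span).reshape(shape)

    U = motion_field_at(spec, grid_pts).reshape(*shape, 3).astype(np.float32)
    ramp = np.asarray(spec.contraction_ramp, np.float32)
    true_disp = ramp[:, None, None, None, None] * U[None]
    if np.any(bulk != 0.0):
        t_idx = np.arange(spec.n_frames, dtype=np.float32)
        true_disp = true_disp + t_idx[:, None, None, None, None] * bulk.astype(
            np.float32
        )

    e_pct = (strain_profile(spec, s) * 100.0).reshape(shape).astype(np.float32)
    e_pct = np.where(rest_mask, e_pct, np.nan)
    true_strain = ramp[:, None, None, None] * e_pct[None]

    s_fine = np.linspace(0.0, spec.arc_length, 512)
    truth_cl = CenterlineTruth(
        s=s_fine,
        points=arc_points(spec, s_fine),
        tangents=arc_tangents(spec, s_fine),
    )
    volumes = VolumeSequence(frames, tuple(spacing), spec.frame_interval)
    return PhantomDataset(
        spec=spec,
        seed=int(seed),
        volumes=volumes,
        rest_mask=rest_mask,
        true_displacement=true_disp,
        true_strain=true_strain,
        true_centerline=truth_cl,
    )


# ---------------------------------------------------------------------------
# Cohort-level ratio sampling.

@dataclass
class CohortSpec:
    """Log-normal normalized-strain-ratio populations for two groups.

    Default medians 0.36 (intact) and 1.54 (unilateral avulsion) match
    the reference clinical cohort; the log-scale spread is chosen so a
    sample of ~10 spans roughly the reported extremes.
    """

    n_per_group: tuple[int, int] = (8, 10)
    ratio_median: tuple[float, float] = (0.36, 1.54)
    ratio_log_sd: tuple[float, float] = (0.75, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 2 for n in self.n_per_group):
            raise SpecificationError("n_per_group must be >= 2 in each group")
        if any(m <= 0 for m in self.ratio_median):
            raise SpecificationError("ratio medians must be positive")
        if any(sd < 0 for sd in self.ratio_log_sd):
            raise SpecificationError("ratio_log_sd must be non-negative")


def generate_cohort_ratios(cspec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two groups' normalized strain ratios (log-normal)."""
    rng = np.random.default_rng(cspec.seed)
    out = []
    for n, med, sd in zip(cspec.n_per_group, cspec.ratio_median, cspec.ratio_log_sd):
        out.append(np.exp(rng.normal(math.log(med), sd, size=int(n))))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Persistence.

def write_phantom(ds: PhantomDataset, out_dir: str | Path) -> dict:
    """Write volumes, mask and ground truth as NIfTI + a JSON sidecar."""
    from . import io as pio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volumes": out_dir / "volumes.nii.gz",
        "rest_mask": out_dir / "rest_mask.nii.gz",
        "true_strain": out_dir / "true_strain.nii.gz",
        "sidecar": out_dir / "phantom.json",
    }
    pio.write_volume_sequence(paths["volumes"], ds.volumes)
    pio.write_mask(paths["rest_mask"], ds.rest_mask, ds.volumes.spacing)
    pio.write_frames_scalar(paths["true_strain"], ds.true_strain, ds.volumes.spacing)
    for comp, name in enumerate("xyz"):
        p = out_dir / f"true_displacement_{name}.nii.gz"
        pio.write_frames_scalar(p, ds.true_displacement[..., comp], ds.volumes.spacing)
        paths[f"true_displacement_{name}"] = p
    sidecar = {
        "seed": ds.seed,
        "spec": asdict(ds.spec),
        "arc_length_mm": ds.spec.arc_length,
        "files": {k: str(v.name) for k, v in paths.items() if k != "sidecar"},
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
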