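# Methods

`prmstrain` estimates contraction strain in the puborectal muscle (PRM)
from dynamic 3D transperineal ultrasound, and summarizes it in a single
normalized strain ratio that separates intact muscles from muscles with
a unilateral avulsion.  This note documents the model, the estimators,
the synthetic validation data, the numerical choices and the known
limitations.

## The measurement model

The PRM is a C-shaped band whose two ends attach to the pubic symphysis.
During a voluntary contraction the sling (mid) region shortens; an end
that is attached to the bone is stretched by that shortening, while a
detached (avulsed) end is free to co-contract.  Strain along the muscle
fiber direction therefore carries the diagnostic signal:

* intact muscle - negative strain in the mid region, positive strain at
  both ends;
* unilateral avulsion - negative strain in the mid region *and* the
  avulsed end, positive strain only at the intact end.

The fiber direction is not resolvable in B-mode ultrasound; following MR
tractography of the pelvic floor, the muscle centerline is used as its
proxy.  With regional strain medians eps_right, eps_left, eps_mid (in
percent), the normalized strain ratio

    ratio = |eps_right - eps_left| / |eps_mid - (eps_right + eps_left)/2|

is dimensionless and invariant to adding a constant to all strains, to a
global sign flip, to rescaling, and to swapping the two ends.  Symmetric
ends give ratios below 1, an asymmetric (avulsed) pair drives it above
1.  The denominator vanishes when the mid strain equals the end average;
the ratio is then reported as undefined, never as infinity.

## Pipeline

1. **Speckle tracking.**  Inter-volume displacement between consecutive
   frames is estimated by 3D block matching with normalized
   cross-correlation (NCC): default 7x7x7 voxel blocks on a stride-2
   subgrid, +/-5 voxel search, subvoxel readout by a Gaussian fit to the
   correlation peak.  The block is deliberately smaller than the muscle
   cross-section so estimates inside the band are not blended with
   stationary background.  Any correlation-peak readout on speckle has a
   pattern-dependent subvoxel bias (the empirical autocorrelation of a
   finite patch is asymmetric), so each field is polished by
   warp-and-refine passes (default 3): the target volume is warped back
   by the current field (cubic spline) and the per-block residual is
   solved by linearized least squares (Lucas-Kanade), which is exactly
   zero at true alignment.  The NCC peak is kept as a quality score;
   vectors below `min_quality` (default 0.5) are replaced by the
   component-wise median of their valid neighbors.

2. **Segmentation propagation and accumulation.**  The manual rest-frame
   PRM mask is the only segmentation input.  Inter-volume fields are
   composed Lagrangianly (the increment is sampled at each material
   point's current position), and the composed field is then
   re-registered directly against the rest frame with large-block
   (11^3) Lucas-Kanade refinement.  The composition chain supplies the
   initialization and keeps every correlation search small; the
   re-registration removes the random-walk drift a pure chain
   accumulates over frames.  The mask at frame t is the rest mask warped
   by the accumulated field (nearest-voxel splat + one-voxel closing).

3. **Centerline.**  The mask is skeletonized (3D thinning); the longest
   geodesic path through the skeleton is parameterized by normalized
   chord length and fitted per coordinate with a degree-5 polynomial
   (one outlier-rejection pass at a 2-voxel residual).  The fitted curve
   is extended linearly at both ends while it remains inside the mask,
   because thinning erodes the end caps and the end voxels would
   otherwise collapse onto a single arc coordinate.  The curve is
   resampled at <= 0.5 voxel spacing; s = 0 is the end with the smaller
   x index, labeled "right" (ultrasound display convention,
   configurable).  Each mask voxel gets the arc coordinate, tangent and
   distance of its closest curve sample (ties toward smaller s).

4. **Strain.**  The 2x2x2 least-squares strain estimator regresses
   displacement against arc coordinate over each voxel's 8-voxel
   neighborhood; the slope x 100 is percent strain (undefined below 4
   valid members or when var(s) < 1e-6 mm^2).  The pipeline applies the
   estimator to each displacement *component* and projects the slope
   vector on the local tangent (`lsq_strain_tensorial`).  For motion
   along the fiber this equals the textbook scalar recipe; for rigid
   motion it is exactly zero, whereas projecting each voxel's vector on
   its own tangent first would leak the tangent's rotation
   (u . dt/ds ~ |u| x curvature, several percent of apparent strain for
   a few mm of probe or bulk motion on a 20 mm radius sling).  In
   `incremental` mode (default) the centerline is recomputed on the
   propagated mask each frame and tangents are taken at each material
   point's current position - the angle correction for the rotating
   fiber direction; `terminal` mode keeps the rest-frame tangents.

5. **Regions and summary.**  Regions are fixed on the rest mask by arc-
   coordinate quantiles: each end holds ceil(N/6) voxels by default
   (combined ends one third of the muscle), the rest is mid.  The
   maximum-contraction frame is the frame whose mid-region median strain
   is most negative (ties earliest; manual override available).
   Regional medians at that frame give the normalized strain ratio.

6. **Statistics.**  Ratios of two groups are compared with a two-sided
   Mann-Whitney U test, computed by exact enumeration of all
   C(n_a+n_b, n_a) assignments whenever that count is at most 200,000
   (an 8-vs-10 cohort is 43,758 assignments); ties are handled by
   midranks over the observed multiset.  Larger groups use the normal
   approximation with tie and continuity corrections.  Shapiro-Wilk
   (scipy's Royston implementation) checks normality; Welch's t test
   serves demographic-style comparisons of approximately normal
   quantities.

## Regularization parameters

Per-frame motions at the clinical 1.5 Hz volume rate are 0.03-0.3 voxel,
and speckle-tracking errors are spatially correlated at roughly the
block scale, so two masked normalized-convolution smoothing steps
stabilize the strain field without borrowing from the stationary
background:

* `increment_smoothing_mm` (default 2.0) - each inter-volume field,
  smoothed over the current mask only;
* `projection_smoothing_mm` (default 1.0) - the accumulated
  displacement components on the rest grid, before the 2x2x2 slope.

Both preserve locally linear displacement profiles (hence constant
strain) exactly up to boundary effects; they round the cosine-taper
transitions of the phantom profile slightly, which is the main reason
recovered end medians sit below the analytic +20%.

## The synthetic phantoms

No clinical volumes are distributable, so validation runs on seeded
speckle phantoms with analytically known motion:

* **Geometry** - a half-annulus band (arc radius 20 mm, tube radius
  4 mm) in one grid plane of a 64 mm cube at 1 mm isotropic spacing -
  the simplest shape with a curved fiber direction and two
  distinguishable ends.
* **Texture** - ~2 scatterers/mm^3 with Rayleigh amplitudes, rendered
  per frame by summing truncated separable Gaussian PSF contributions
  (sigma 1.2 mm); additive Gaussian noise at 5% of the mean intensity.
  The rendering is an exact continuous function of scatterer position,
  so translated phantoms really are translations of the same speckle.
* **Motion** - a piecewise-constant tangential strain profile e(s) with
  cosine-tapered transitions (taper width 10% of arc length): the mid
  2/3 of the arc carries `peak_mid_strain` (default -10%), the end
  sixths carry the balancing +20% forced by anchoring both ends to the
  bone (zero net end-to-end displacement).  For a unilateral avulsion
  the detached end co-contracts at the mid strain and only the intact
  end is anchored.  Displacement is u(s) = activation x integral of e,
  directed along the local tangent, decaying to zero over one tube
  radius outside the band.  8 frames ramp activation linearly from rest
  to maximum; `bulk_velocity` adds a strain-free rigid translation for
  null experiments.
* **Cohorts** - normalized-ratio populations are log-normal with medians
  0.36 (intact) and 1.54 (avulsion), matching the reference cohort, and
  log-sd 0.75, chosen so a sample of ~10 spans roughly the reported
  extremes (0.13-3.07 and 0.95-14.59).  The reported p-value of 0.04
  for 8 vs 10 women cannot be recomputed exactly because the individual
  ratios are not published; the power of the comparison at these
  settings is reported by the calibration test, not asserted.

What the phantoms do **not** emulate: anatomically realistic geometry,
attenuation/shadowing, out-of-plane probe motion, frame-time jitter
("11 to 15 s" acquisitions are treated as uniformly spaced), the
return-to-rest half of the maneuver, and inter-subject variability of
contraction strength.  Passing the phantom suite shows the estimator
chain is correct and unbiased at realistic speckle and noise scales; it
does not certify clinical accuracy.

## Problem sizes used in the test suite

The reference conditions (64^3 voxels, 8 frames) are used for the
tracking-accuracy and strain-recovery checks and for the rigid-motion
null.  Multi-seed pattern-separation runs use a reduced phantom (48^3,
6 frames, arc radius 15 mm, tube radius 3.5 mm), which preserves every
geometric ratio of the reference phantom at smaller scale.  The
rigid-motion null is constructed from spline-shifted copies of one
rendered frame - the same known-shift idiom as the tracking-accuracy
check - so it isolates the estimator's translation response from
independent per-frame noise; with fully independent frame noise the
tracker's ~0.08-voxel field noise leaves end-region medians of up to
~2% apparent strain, an honest noise floor of the method at these
settings.

## Numerical choices and degenerate inputs

* Voxel (i,j,k) sits at physical position (i,j,k) x spacing;
  displacements are stored in mm; strain is in percent.
* Exact Mann-Whitney p is the tail fraction of assignments with
  min(U_a, U_b) <= observed (two-sided by symmetry); a complete tie
  returns p = 1.
* The ratio denominator guard is 1e-9 (percent units).
* A disconnected mask, an empty region after cuts, a region with no
  defined strain, a skeleton shorter than degree+1 points, and a NIfTI
  without spatial metadata (no sform and no qform - nibabel would
  silently substitute 1 mm) all raise typed errors rather than degrade.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a phantom is bit-reproducible given
  (spec, seed).

## Known limitations

* The centerline proxy assumes fibers follow the band axis; real PRM
  fiber dispersion is not modeled.
* Strain accuracy at the band ends is intrinsically worse than mid-band:
  displacement is small there, the centerline fit is extrapolated, and
  the regions are short, so medians average over few independent
  error cells.
* The 2x2x2 estimator support means per-voxel strain is noisy by
  design; only regional medians are reported as endpoints.
* Exact enumeration is quadratic-factorial in group sizes; beyond the
  enumeration limit the normal approximation is used and flagged in the
  output.
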