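# Methods

## Overview

The package reconstructs a stress-inference chain for multicellular
spheroids carrying embedded elastic microbead sensors:

1. **Calibration** — fit the sensor stress–strain law from
   osmotic-compression data and invert it.
2. **Imaging** — segment each bead's equatorial cross-section before and
   after a pressure step, convert areas to volumetric strain, locate the
   bead in 3D, and apply quality control.
3. **Profile** — bin strain/pressure against normalized radius and fit
   the stress power law.
4. **Mechanics** — map the fitted exponent to a cell stiffness anisotropy
   with a transversely anisotropic elastic-sphere model.
5. **Anisotropy** — quantify cell shape elongation along the radius and
   locate the high→low transition.

A seeded generator produces calibration tables, bead scenes with ground
truth, and cell fields, so every stage is validated against known truth.

## Constitutive law of the bead sensor

Compressive stress is positive throughout; strain is the unsigned
relative volume change `s = |V(P) − V0| / V0`.  The law is a
zero-intercept polynomial `P(s) = K s + c2 s² + … + cd s^d` (default
degree 3).  The bulk modulus `K` is fitted first as the zero-intercept
least-squares slope of `P` on `s` restricted to the linear regime
(`s ≤ 0.15` by default, 15 kPa for the shipped PAA 5/0.225 preset); the
higher coefficients are then fitted with `c1` pinned to `K`, and the
result is rejected (`NonMonotoneFitError`) unless `P'(s) > 0` on the
whole observed strain range, checked on a 2001-point grid.  Inversion
uses Brent bracketing on `[0, s_max]` (xtol 1e-12); strains or pressures
outside the calibrated range raise `OutOfRangeError` rather than
extrapolating.  Exact recovery of polynomial coefficients requires the
linear-regime subset to be effectively linear; when the underlying law
already curves below the linear limit, the pinned `K` absorbs a small
bias that the higher terms then compensate.

## Anisotropic elastic-sphere model

Spherically symmetric equilibrium `dσ_rr/dr + (2/r)(σ_rr − σ_θθ) = 0`
closed with a constant stress ratio `σ_θθ = σ_rr/ρ`, `ρ = E_r/E_t`, gives
`σ_rr = P_s (r/R0)^β` with `β = 2(1/ρ − 1)`.  This minimal closure is a
reconstruction of the published anisotropic-sphere argument, chosen
because it reproduces the printed correspondence β = −0.21 ↔ ρ = 1.12
exactly; it is not a full anisotropic elasticity solution with
displacement fields.  `radial_stress_numeric` integrates the same ODE
with RK45 (rtol 1e-10, atol 1e-14) inward from `σ(R0) = P_s` and serves
as an independent oracle; closed form and integration agree to better
than 1e-6 relative error on `r/R0 ∈ [0.05, 1]` for ρ ∈ [0.8, 1.5].
Ratios within 1e-9 of 1 are classified isotropic.  The observed pressure
drops at the spheroid surface and centre are deliberately *not* part of
this model; they live in the generator as the transmission factor η and
the optional core-drop flag.

## Synthetic scenes

`SceneConfig` defaults are the study conditions: spheroid radius
120 ± 10 μm (normal, clipped at half the mean), 3–4 beads per spheroid
(uniform), bead radius 8–18 μm (uniform, < 20 μm), applied osmotic step
ΔP0 = 5 kPa, surface transmission η = 0.2 (reproducing the ~1 kPa
surface stress), stiffness ratio ρ = 1.12, pixel size 1 μm, Gaussian PSF
σ = 2 px, background 100 and bead intensity 1000 with additive Gaussian
noise of sd 20 (2% of bead intensity).  Local stress is
`σ(r) = η ΔP0 (r/R0)^β`; the after-image radius is shrunk so each bead's
volumetric strain equals the constitutive law at its local stress.

Bead centres are uniform in the spheroid volume (density ∝ r²); by
default placement keeps the bead surface at least one bead radius from
the spheroid surface, which also means the generated cohorts rarely
trigger the 10 μm surface-margin QC rule (that rule is exercised in unit
tests and matters for real data).  An optional core-drop flag tapers the
stress linearly to zero inside `r/R0 < 0.25`, emulating the reduced core
pressure seen experimentally; it is off by default.

Rendering: each bead appears in its own image pair at its own equatorial
focal plane (other beads are out of focus and omitted), as an
anti-aliased disk (8×8 subpixel coverage sampling), Gaussian-blurred and
noised; the stage z of each bead is recorded in the metadata, as in the
original acquisition.  The generator emulates neither Poisson shot
noise, cell-scale texture, bead–bead optical interference, nor 3D PSFs —
passing tests therefore demonstrate correctness of the measurement chain
under idealized epifluorescence, not robustness to every real-world
artefact.

Cell fields place non-overlapping rasterized ellipses (pixel-exact
random sequential placement, equivalent radius 5 μm) uniformly over the
equatorial section: outside the transition radius (default R0/3) cells
are tangential with aspect ratio 2.25; inside they are randomly oriented
with aspect ratio 1.5.

## Imaging choices

* **IsoData threshold**: iterated intermeans on the ROI, starting from
  the ROI mean, converged when the update falls below half of a 256-bin
  histogram width over the ROI min–max; pixels equal to the threshold
  count as background.  This follows the classic iterative-intermeans
  family as implemented in common image-analysis software.
* **ROI**: bounding box of the brightest blob dilated by 50% per side
  (stand-in for the original hand-drawn ROIs), or a fixed square around
  the metadata position.
* **Segmentation**: largest 8-connected component above threshold; area
  is the raw pixel count; ellipticity is the major/minor axis ratio of
  the second-moment ellipse.
* **Geometry**: sphere volume from equatorial area,
  `V = 4/(3√π) A^{3/2}`; spheroid radius `R0 = √(area/π)` from the
  contour mask; bead radial position from image (x, y) plus stage z.
* **QC**: reject beads within 10 μm of the surface and beads whose
  before-image ellipticity exceeds 1.15 (the published exclusion of
  pre-deformed beads is qualitative, ~1/100; the numeric cut is ours).
  Every rejection carries a machine-readable reason; per-bead failures
  never abort a run.

Accuracy: pixel counting quantizes areas.  For generic subpixel bead
positions the segmented area is within ~1% of truth for radii ≥ 8 px
(within 2% in essentially all cases); highly symmetric alignments of the
smallest beads can reach ~3%, and at PSF σ = 2 px the threshold sits
below half-maximum so small-bead areas are over-estimated by a few
percent.  These biases largely cancel in the before/after ratio; the
residual per-bead strain error under the default study conditions is
~0.01–0.02, small against the strain range and absorbed by the
power-law fit, whose exponent stays within the published ±0.1 band on
50-spheroid cohorts.  The noiseless accuracy checks in the test suite
use finer sampling (0.25 μm/px) where strain errors fall below 0.01.

## Profiles and fitting

Binning is equal-count with 7 bins by default (configurable, also
fixed-width); each bin reports the mean position, mean value, s.e.m.
(n−1 sd over √n; single-point bins carry NaN rather than a fabricated
error) and count.  Strain converts to pressure per observation *before*
re-binning, since the law may be nonlinear.  The power law is fitted by
weighted least squares of log P on log r with bin counts as weights —
exact on clean power-law data, with a closed-form slope standard error.
Bin exclusion (e.g. a contaminated core bin) is an explicit user choice,
never automatic.  The raw-strain linear trend is an OLS slope with a
one-sided sign test.

## Anisotropy measurement

Ellipse descriptors come from second central moments (with the 1/12
pixel-integration term), axis lengths 4√eigenvalue, orientation from the
principal direction measured counter-clockwise from the +x (column)
axis in [−π/2, π/2); the alignment angle is the acute angle to the local
tangential direction.  Only single-component masks are accepted.  The
change point of the binned aspect-ratio profile is the exhaustive
two-segment piecewise-constant least-squares split, reported as the
midpoint between adjacent bin centres; splits that reduce variance by
less than 10% report "no transition".

## Problem sizes

Default analyses use 50 spheroids (~175 beads), 100 calibration points,
180-cell fields and 9 radial bins; recovery-rate checks run 200
calibration simulations and 100 cell-field seeds.  All generators take
explicit seeds and are bit-reproducible; the pipeline itself is
deterministic.

## Known limitations

* The anisotropic closure is the minimal one consistent with the printed
  exponent↔ratio correspondence; other constitutive assumptions could
  yield different mappings.
* Strain accuracy is pixel-quantization-limited for the smallest beads
  at 1 μm/px.
* The surface screening η is a scalar stand-in for unmodelled surface
  mechanics; the core pressure drop is emulated, not explained.
* No 3D segmentation, autofocus, drift correction, or actin-image cell
  segmentation: cell masks and spheroid contours are inputs.
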