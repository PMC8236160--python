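# Methods

This note records the models, conventions and numerical choices behind
`radfilm`, and what the synthetic validation does and does not establish
about real film.

## Scan model and netOD

Film response is read from 48-bit (3×16-bit) transmission scans.  Four
scans per film are taken with the film rotated between scans; because each
rotation is one of the four axis flips, undoing it is deterministic given
the orientation tag, and default "registration" is exact flip inversion.
An optional integer-pixel refinement (exhaustive ±5 px SSD search on the
green channel) absorbs mechanical repositioning error; guide strips on the
scanner bed keep residual drift below a pixel in practice, so the
refinement is off by default.

Net optical density uses the standard radiochromic convention
netOD = log₁₀(PV_before/PV_after) on the averaged pixel values.  Pixel
values are floored at 1 before the ratio so dead pixels cannot produce
infinities; floored pixels are counted and logged rather than silently
accepted.  No scanner-uniformity correction map is applied; the lateral
response artifact is instead available in the synthetic scanner model and
acknowledged as the dominant uncontrolled uncertainty for wide fields.
The unexposed reference may be a companion film or an unirradiated margin
of the exposed film; neither is canonical and both are supported.

## Calibration

The nine-level grid spans 3–21 Gy.  Block means are taken after shrinking
each block by `margin_fraction` (default 0.25) per side, so penumbra and
edge blur never contaminate the samples; for internally uniform blocks the
result is margin-invariant (tested).  The fit is an unweighted
least-squares cubic netOD → dose with a free intercept — with nine points
and four coefficients, noiseless data are reproduced to machine precision.
Monotonicity of the fitted cubic is checked numerically at 1000 samples
over the point span; a non-monotone curve is flagged, not rejected, since
the downstream conversion only needs the fitted values.

The direction of the polynomial (netOD → dose rather than dose → netOD) is
chosen because the coefficients are used to compute dose from scanned
optical density.  Curve comparison samples both cubics at 200 uniform
netODs over their common span (the result is insensitive beyond ~50
samples) and reports the Pearson correlation of the sampled dose vectors.

Channel policy: red for plan maxima ≤ 10 Gy (steepest sensitometric slope
at low dose), green above; blue is carried through but never auto-selected.

## Dose conversion

The cubic is evaluated per pixel.  Outside the calibrated netOD span the
cubic is not extrapolated: above the span the netOD is clamped to the
largest fitted point (saturation) and the pixel flagged; negative fitted
doses are floored to 0 Gy and flagged separately.  Clamping was chosen
over extrapolation because cubic extrapolation diverges quickly beyond the
data.

## Plane geometry and registration

Planes live on pixel centers with x right, y up, and the isocenter at
(0, 0); row 0 is the top of the plane.  The plain-text dialect stores
unit, spacing and origin in comment headers and round-trips within
10⁻⁶ Gy; the raw binary container with a JSON sidecar is lossless.  DICOM
RT Dose values are scaled to Gy via `DoseGridScaling`; grids above 4096²
are refused.

Registration of film to plan is fiducial-driven: the user supplies the
film pixel marked at the room-laser crosshair, a rotation, and an optional
left-right flip; the film is then resampled bilinearly onto the plan grid.
Automatic dose-based registration is deliberately absent — it would absorb
exactly the spatial delivery errors the gamma analysis exists to detect.
Resampling uses bilinear interpolation on pixel centers (it reproduces
constants and affine ramps exactly, the basis of its tests); target pixels
outside the source support are NaN and excluded downstream.

## Gamma analysis

The implementation follows the standard dose-difference /
distance-to-agreement construction with **global** normalization: the dose
denominator is Δ% of the reference-plane maximum (D_global).  The plan is
the reference (it defines D_global, the 10% evaluation threshold, and the
evaluation pixels — keeping the denominator and the evaluated set
independent of film noise); the film is the evaluated distribution.

The search minimizes over candidates on a square lattice of step
min(Δd/10, native evaluated spacing) within radius `gamma_cap`·Δd
(cap 2.0 — a gamma above the cap can never change pass/fail), with the
evaluated dose interpolated bilinearly.  γ ≤ 1 passes, boundary inclusive;
the comparison allows 10⁻⁹ of float slack so a dose difference exactly at
the criterion passes, as the analytic uniform-plane case requires.

In relative mode the evaluated plane is first rescaled by
max(reference)/max(evaluated).  A plain maximum is fragile on noisy film,
so the default "maximum" is the mean of the top 0.5% of pixels; the exact
maximum is available via `use_robust_max=False`.  Note that on noisy film
even the robust maximum is biased high (the top pixels are the noise
peaks), which biases the scaling factor low and can fail gradient-region
points that absolute mode passes — visible in the README example and
consistent with clinical experience of relative analysis.

`brute_force_gamma` is an independent oracle: an explicit per-pixel loop,
its own offset lattice (Δd/`subgrid_factor`), its own bilinear formula, no
pruning and no shared code path with `compute_gamma`.  On matched lattices
the two agree to ~10⁻¹⁴.

Two discretization facts shape the tests:

- **Criteria dominance.** Componentwise-looser criteria give pointwise
  smaller gamma — exactly — when all criteria are evaluated on a shared
  candidate lattice (the looser radius is then a superset and its
  integrand pointwise smaller).  With per-criteria default steps (Δd/10)
  the lattices differ and dominance holds only up to discretization.
  `compute_gamma(..., subgrid_step_mm=...)` exposes the shared-lattice
  mode; dominance checks use it at 0.1 mm.
- **Convergence.** Near a dose-crossing minimum the lattice error is first
  order in step × (dose gradient / dose denominator).  Self-convergence of
  the oracle under lattice refinement is therefore demonstrated on gently
  modulated fields; steep-penumbra fields are instead validated by
  oracle-vs-implementation agreement on matched lattices.

## Profiles

Profiles are sampled bilinearly along the central axes at native spacing,
normalized to the mean over |position| ≤ 2.5 mm (the central 5 mm), and
resampled by linear interpolation to detector positions (5 mm chamber
pitch or 0.5 mm diode steps; extrapolation is refused).  Percentage
differences are 100·(D_meas·SF − D_ref)/D_global with SF the max-ratio
scaling factor (same robust-max policy as gamma) or 1 in absolute mode.
Summary statistics are the mean and maximum of the **absolute** per-point
differences (signed values are retained in the comparison object, since
conventions differ between clinics).  FWHM is the distance between the 50%
crossings of the central-axis value with linear interpolation; penumbra is
the 20–80% width per edge, the usual medical-physics convention; the
"penumbra region" for reporting maxima is bounded by the 10% and 90%
crossings.

## Synthetic data

The generator emulates the study conditions rather than a beam model:

- **Open fields**: D(x, y) = D_max·E(x; w)·E(y; w) with
  E(t; w) = ½[erf((t+w/2)/(σ√2)) − erf((t−w/2)/(σ√2))], σ default 1.5 mm.
  Default plane pitch 0.5 mm, extent field + 50 mm.  For w ≫ σ the central
  value equals D_max; FWHM equals the nominal field size to well under a
  pixel for every size in the standard list (0.83–19.92 cm).
- **Calibration grid**: nine erf-edged blocks (default 40 mm blocks at
  60 mm pitch on a 20.3×25.4 cm film canvas) carrying the standard dose
  list; block separation must exceed 6σ so cross-talk is below 10⁻⁶.
- **Film response**: per-channel monotone cubics chosen for plausible
  magnitudes (netOD ≈ 0.45 at 10 Gy red, ≈ 0.55 at 21 Gy green,
  unexposed PV 42–46 k) — synthetic, not a measured film lot.  Exposure
  inverts the cubic through a 4097-knot tabulated inverse (linear
  interpolation; the tabulation error is orders of magnitude below the
  0.1% round-trip budget).  Pixel values are rounded to 16 bits, which
  sets the actual round-trip floor: ±0.5 PV ≈ 10⁻⁵ netOD ≈ 3×10⁻⁴ Gy —
  hence the < 10⁻³ Gy residual bound on the noiseless grid-film loop
  rather than an exact-recovery claim.
- **Scanner**: the four orientations are the tagged flips of the noiseless
  geometry, each with an independent multiplicative Gaussian PV noise draw
  (the unexposed companion scan gets its own); the optional lateral
  artifact multiplies netOD by 1 + A·(2d/W)², peaking at the film's
  left/right edges (default A = 0, opt-in).
- **PSQA patterns**: two-level boost, wedge, and offset-hotspot plans with
  injectable delivery errors (global scaling, translation, additive blob)
  to exercise gamma sensitivity in known directions.

Every generator is a pure function of (spec, seed).

### What the synthetic validation shows — and does not

Passing tests establish that the processing chain is self-consistent
(simulated film is recovered to the quantization floor), that the gamma
implementation matches an exhaustive oracle, and that the statistical
behavior under noise (replicate-calibration correlation, pass-rate
degradation with jitter) is as expected.  They do **not** validate
physical film behavior: real films add lot-to-lot response variation,
scanner warm-up drift, lateral-response artifacts larger than the
parabolic model, Newton rings and dust.  Clinical pass-rate magnitudes
should not be inferred from the synthetic cases.

## Problem sizes

Validation runs use planes between 28×28 (1 mm) for oracle and dominance
studies — the brute-force oracle is O(pixels × candidates) — and
301×301 (0.5 mm) for the end-to-end open-field loop; the replicate
correlation study uses 100 seed pairs.  These sizes put every statistic
deep in its asymptotic behavior while keeping a full validation run under
a minute.

## Known limitations

- Single-channel dosimetry only; no triple-channel correction model.
- No automatic film-edge or grid detection; geometry is configuration.
- Rigid registration only (translation, rotation, flip).
- The lateral artifact model is a symmetric parabola; real scanner
  profiles are channel- and OD-dependent.
- Gamma is 2-D planar; no 3-D or local-normalization variants (global
  normalization is the clinical convention implemented here).
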