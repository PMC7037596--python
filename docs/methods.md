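# Methods

This note documents the models, conventions and numerical choices behind
valvescan: what the synthetic phantom emulates, how each analysis stage is
defined, and where design latitude was resolved by a declared convention.

## The phantom

A `TissuePhantom` is an ordered chain of regions along one coordinate
`x` (mm, 0 at the PM end): PM, PM–CT, CT, CT–LL, LL for the mitral (`mv`)
and tricuspid (`tv`) presets, and an aortic-wall→cusp chain for the `av`
preset (which carries no reference values and exists only as a geometry).
Each region has a length, cross-sectional area, thickness, relative muscle
fraction, resting fiber-orientation spread and a constitutive law.

**Composition.** `f_m(x)` is a plateau per pure region (PM 0.95, CT 0, LL 0
relative muscle content) with linear ramps across the transition regions;
the PM–CT ramp width defaults to 3 mm, matching the few-millimetre diffuse
transition seen in composition scans.  `f_m = 0` in pure CT by construction
("no muscle detected").

**Molecular-strain coupling.** The local collagen molecular strain under an
overall engineering strain `ε` is modelled as `ε_mol(x) = c(x)·ε` with
`c(x)` a baseline (0.10) plus Gaussian bumps — a large one (amplitude 0.30,
σ 1.2 mm) centred on the PM–CT transition and a small one (0.04–0.05) at
CT–LL.  The measurements report the phenomenon (strain localization at the
junctions) but no functional form; the Gaussian-bump-over-baseline is this
package's choice.  The rendered D-period is `D(x, ε) = D₀·(1 + c(x)·ε)`
with `D₀ = 67.0 nm`.

**Muscle (1,1).** The resting d-spacing is 21.5 nm and shrinks linearly
with strain (`d₁₁ = d₁₁,₀·(1 − 0.3·ε)`).  The relation between (1,1)
spacing and sarcomere length is only a relative, approximate measure, so
the gain is a free linear parameter and the analysis flags the output as a
relative measure.

**Orientation.** The azimuthal spread is a per-region resting value
(CT 7°, PM 16°, LL 24°, transitions intermediate) scaled by
`max(0.2, 1 − 1.5·ε)`: fibers align under stretch, so the spread is
non-increasing in strain.  A second collagen population rotated 90° to the
strip axis is rendered near the CT–LL junction (fraction up to 0.7 over
σ 0.8 mm); it is the orientation signature the CT–LL transition call
requires.

**Constitutive law.** Per region,

    σ(ε) = (E_t/k)(e^{kε} − 1)      ε < ε_toe
    σ(ε) = σ_toe + E (ε − ε_toe)    up to σ_ult

with `ε_toe = ln(E/E_t)/k` chosen so the tangent modulus is continuous at
the toe/linear junction.  Moduli are plausible for the tissue types
(compliant muscle E ≈ 0.05–0.5 MPa, stiff chordae E ≈ 40–120 MPa,
intermediate leaflet) and put the ultimate strains in the observed ordering
(CT fails near 5 % strain, PM near 27 %).  Past `σ_ult` the region tears;
it retains a small residual fraction (0.05) of its strength.

**Strength-consistent areas.** In a series pull all regions carry the same
force, so per-region ultimate stresses measured from a single tear satisfy
`σ_ult,i = F_tear/A_i` identically — the published per-region values from
one pull are mutually consistent in exactly this way.  Presets invert the
relation: `A_i = F₀/σ_ult,i`, with `F₀` fixed by giving the reference
region (PM) a realistic 10 mm² cross-section.  The designated failure site
(PM–CT) gets a 0.5 % area deficit so that it reaches its ultimate first;
every region's recorded peak stress then sits within 0.5 % of its nominal
strength while failure deterministically localizes at the junction.

**Series solver.** For a grip displacement Δ the equilibrium force solves
`Σ_i ε_i(F)·L₀,i = Δ` with `ε_i(F) = σ_i⁻¹(F/A_i)` (piecewise-analytic
inverse), by Brent root finding on the monotone loading branch
(`xtol 1e-15`; the residual force imbalance is at machine precision and
displacement closes to < 1e-9 mm).  Past the tear point a gentle descending
branch would have to extend over >100 % strain to avoid snap-back given
these compliances, which is unphysical; the tear is therefore modelled as a
force decay from the peak to the residual level over a 2 s propagation
time, with intact regions unloading elastically along their own curves and
the torn region absorbing the freed displacement.  The pull starts from a
0.1 g pre-tension (the resting reference state); the load stays within the
455 g load-cell range.

**Rendering.** Diffraction frames are phenomenological: Gaussian arcs
(radial σ 1.5 px) at the exact geometric radii of collagen meridional
orders 1–9 and the muscle (1,0)/(1,1) equatorial reflections, an azimuthal
two-lobed Gaussian of the local spread, and a smooth power-law background;
no structure factors or wide-angle corrections.  Composition is encoded in
integrated intensities: the 5th order carries total counts ∝ (1 − f_m) and
the (1,1) ∝ f_m on a common scale.  Orders of the rotated (90°) population
that would radially collide with a muscle reflection (notably order 3,
D/3 = 22.3 nm vs d₁₁ = 21.5 nm) are omitted — reflections stay radially
separated because multi-peak deconvolution is out of scope.  Poisson noise
is applied only when a seed is given; `peak_snr` rescales the arcs so the
brightest 5th-order pixel has `s/√(s+b)` equal to the requested SNR.
Default geometry: λ = 1.033 Å, 2500 mm, 0.172 mm pixels, 512², beam center
(255.5, 255.5) — chosen so orders 1–9 of a 67 nm D-period land on-detector.
Video frames are light fields with dark Gaussian blobs (σ 2 px) at the
marker positions advected by the per-region strain truth, 12 px/mm,
5 fps; markers sit on the strip midline (a lateral offset would introduce
a cosine error in pair distances), two per region, 0.5 mm inside each
region boundary, so every transition has a marker on each side.

## Reduction and fitting conventions

- Fiber axis vertical on the detector: meridional = vertical wedges,
  equatorial = horizontal wedges, ±15° half-angle by default.  Pixel
  coordinates are 0-based (col, row); q = (4π/λ)sin θ with
  2θ = atan(r·pixel/distance).
- Sector profiles use pixel-center assignment into 1-px annular bins and
  report the mean counts per pixel plus the bin populations; empty bins are
  dropped, not zero-filled; a central 6 px disc stands in for the beamstop.
  Pixel-center assignment makes the counts-conservation check exact.
- Background: 1-D grey opening (rolling minimum/maximum, window 31 bins)
  with light smoothing, or linear interpolation between local minima;
  residuals are clipped non-negative and the method is recorded in
  provenance.
- Peak fits are least-squares Gaussian (optionally pseudo-Voigt) plus a
  linear baseline; areas are analytic in the fitted parameters;
  non-convergent or machine-amplitude fits return a flagged null, never a
  silent zero.  Windows are seeded at the expected position (±5 % local
  maximum search) — the measurement protocol this emulates does not state a
  windowing rule, so this is a declared convention.
- The D-period uses the 5th meridional order only (`D = 5·2π/q₅`); other
  orders serve the internal consistency check (n·d_n constant to 0.3 %).
  A fitted (1,1) whose spacing falls more than 6 % from the expected value
  is rejected as "no muscle reflection" (this also rejects any residual
  collagen contamination on the equator).
- Integrated arc intensities for composition are reconstructed from the
  sector fit as (fitted peak per bin) × (bin population) / (wedge azimuthal
  capture), the capture being `erf(half_angle/(√2·σ_χ))` with the spread
  from the azimuthal fit.  Muscle and collagen arcs share σ_χ in the
  generator, so the composition ratio is insensitive to capture errors.
- Orientation: two-lobed (180°-periodic) circular Gaussian fit on the 1°
  azimuthal profile.  The peak–trough modulation that decides isotropy
  (threshold 0.1) is read off a circularly smoothed copy (9° window):
  at 1° bins the per-bin pixel-assignment jitter of a ring is several
  percent and would otherwise dominate the statistic; the parameter fit
  itself uses the raw profile.  The ellipse minor axis is
  `b = a·min(1, κ/spread)` with κ = 5°, making b exactly inversely
  proportional to the spread for spreads ≥ 5° (dots for isotropic points,
  `b = 0.12·a`).
- Composition calibration weight `w` defaults to 1.0 (the upstream
  normalization it stands in for is unspecified); transition thresholds are
  declared conventions: PM–CT is the interval where %muscle crosses from
  ≥ 80 down to ≤ 5 (linearly interpolated crossings), CT–LL additionally
  requires the rotated-orientation signature (fitted angle > 45° off axis)
  and is only attempted when orientation data are present.
- Scan positions are reported in resting-state coordinates; tracked-point
  advection between strain levels uses the regional strains (generator
  truth in tests), recorded in provenance.

## Mechanics conventions

- g₀ = 9.80665 m/s²; stress in MPa from grams-force over mm².  Frame 0 is
  the strain reference.  5 fps frame extraction.
- Tracking: single-scale LoG detection at the known blob scale with
  intensity-centroid refinement over a ±2.5σ window (the window is kept
  tight so neighbouring markers do not bias the centroid); nearest-
  neighbour linking with a displacement gate (10 px/frame default; the
  pipeline widens it to cover tear-propagation recoil), ambiguous links
  resolved by smaller displacement and logged, lost tracks terminated and
  flagged rather than interpolated.  A detection whose second moment is
  ≥1.3× the blob scale warns of a merged pair (two blobs closer than ~2σ
  are unresolvable).
- Failure rule: stress below (1 − 0.10)× the running maximum for 3
  consecutive samples *while the strain exceeds the strain at that
  maximum*.  The strain condition is essential with a single shared load
  cell: every region's stress is the same force over a constant area, so
  all traces drop proportionally at the tear; what distinguishes the torn
  region is that it keeps elongating while intact regions recoil
  elastically.  Intact regions report their observed maximum with
  `failure_detected = False`.  The failure locus is the earliest failure
  frame, ties broken by the lower ultimate stress.
- Toe/linear moduli are least-squares slopes (MPa per unit strain): toe
  over the initial 10 % window, linear over the steepest sustained 15 %
  window before failure; low-slope plateaus before the linear region are
  reported as (possibly multiple) toe intervals.
- The 10 %-drop/3-sample failure rule is a declared convention (failure was
  identified visually in the source experiments), as are the window
  fractions.

## Problem sizes and what the tests show

The validation suite runs the full pipelines at desk scale: 512² frames,
10 scan positions × 6 strain levels, pulls of roughly 550 video frames at
5 fps (0.04 mm/s ramp), 50-seed repetitions for the localization
statistics (with ±3 % strength jitter, ±10 % thickness jitter, coupling-
bump jitter and Poisson/sensor noise), and 100-seed repetitions for the
noisy D-period metrology at SNR 20.  Faster ramps (0.2 mm/s) are used where
only localization, not 2 %-level stress recovery, is at stake; peak-force
sampling at 5 fps costs about 0.2 % at 0.04 mm/s and about 1 % at
0.2 mm/s.

The phantom emulates arc geometry, composition ratios, strain coupling and
marker kinematics, but not detector artefacts (polarization, flat field,
geometric distortion), sample hydration drift, marker smearing, or
constitutive viscoelasticity/hysteresis.  Passing recovery tests therefore
demonstrate that the analysis chain is internally correct and unbiased on
idealized data at realistic magnitudes — not that these tolerances hold on
beamline data.  The strength-consistent preset areas mean the per-region
ultimate-stress recovery exercises the pipeline's measurement chain, not an
independent re-derivation of tissue strength.

## Known limitations

- The series model treats regions as homogeneous 1-D elements; no strain
  gradients within a region and no lateral contraction.
- Only one tear per pull: after the weak region fails, the force stays at
  its residual level, so other regions never reach their own ultimate in
  the same simulation (consistent with a real tear terminating the pull).
- The orientation fit assumes a single dominant population plus an optional
  90°-rotated one; arbitrary multi-modal distributions are out of scope.
- Absolute composition is deliberately not computed — the ratio is relative
  muscle vs collagen signal, not a mass fraction.
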