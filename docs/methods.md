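# Methods

`vsxscan` models the task a refractionist faces: given one eye, which
sphere/cylinder/axis combination - out of the whole dioptric space a
phoropter can dial - gives the best retinal image quality, and how is that
quality distributed over the space?  The pipeline is: synthesize eye
biometry, apply a parametric spectacle or scleral-lens correction, ray
trace to the exit-pupil wavefront, score it with the visual Strehl (VSX)
metric, search the correction space with a coarse-to-fine ladder, and
characterize the topography of the resulting VSX cloud (one focus vs
several).

## Eye model

Each eye is a four-surface schematic eye (anterior/posterior cornea,
crystalline lens front/back) of conic sections, with indices at 555 nm
(cornea 1.376, aqueous 1.3374, lens 1.420, vitreous 1.336), a 5-mm physical
pupil at the lens front vertex, and a retinal plane.  The template values
are Navarro-style: posterior cornea 6.50 mm, corneal thickness 0.55 mm,
anterior chamber 3.05 mm, lens radii 10.20/-6.00 mm, lens thickness
4.00 mm.  Two conic constants were calibrated rather than copied from any
schematic eye: the anterior corneal asphericity (mean Q = -0.45) and an
oblate lens back surface (Q = +1.0).  Together they set the balance of
corneal versus internal spherical aberration so that a spherocylindrically
best-corrected eye at a 5-mm pupil retains the image quality of typical
adult eyes (VSX about 0.33 with spectacles and about 0.39 with scleral
lenses, which mask most of the corneal contribution).  Those two numbers
are the only "tuned" template constants; all per-eye quantities are solved
from sampled targets (below).

Anterior corneal astigmatism is a biconic (two apical radii, shared conic);
the keratoconic cone is a Gaussian elevation bump subtracted from the
anterior sag:

    sag'(x, y) = sag(x, y) - a * exp(-((x-cx)^2 + (y-cy)^2) / (2 sigma^2))

with amplitude `a` (um), width `sigma` (mm) and centre (cx, cy) (mm,
+y superior).  Amplitude 0 encodes "no cone"; posterior-surface and
thickness changes are not modelled - the anterior surface dominates the
aberration signature this pipeline studies.

## Synthetic cohorts

The generator is a stand-in for a full multivariate statistical eye model.
Rather than sampling correlated raw biometry, it samples each eye's
clinically meaningful *targets* from the published cohort distributions -

| quantity            | normal        | keratoconic   |
|---------------------|---------------|---------------|
| Kmax (D)            | 43.00 +/- 1.00| 53.69 +/- 4.85|
| Seidel sphere (D)   | -0.74 +/- 3.10| -2.84 +/- 5.72|
| Seidel cylinder (D) | -0.78 +/- 0.40| -4.27 +/- 2.45|

- and then *solves* the free biometric parameters so the traced eye
reproduces them exactly: the anterior radius carries the Kmax target
(normals), the cone amplitude is solved by bisection against the simulated
keratometry (keratoconus), the anterior toricity is solved so the traced
astigmatic power vector matches the cylinder target, and the vitreous depth
is solved so the traced Seidel sphere matches the sphere target.  Normal
eyes are additionally gated to |sphere| <= 10 D.  Distributions are
truncated to physiologic brackets with the location parameter re-centred so
the *truncated* mean equals the published mean; cohort draws use stratified
inverse-CDF sampling over independently permuted strata, which pins cohort
means at the configured values without narrowing per-eye dispersion.

Cone shape parameters are not fixed by the printed summary statistics and
were calibrated once against the cohort-level outcomes (best-corrected VSX
level of the keratoconic cohort and the prevalence and separation of double
foci): sigma 1.8 +/- 0.2 mm with a severity coupling of +0.12 mm per
diopter of Kmax above the cohort mean (advanced cones are broader, which is
what makes the steep zone uniform enough to act as a second focus),
decentration radius 1.6 +/- 0.3 mm at -90 +/- 25 degrees (inferior).  The
keratoconic base cornea steepens with the myopia target (slope
-0.45 x 0.5 D/D) so extreme myopes remain inside the axial-length bracket,
reflecting that keratoconic myopia is corneal, not axial.

What the generator does *not* emulate: real covariance structure between
biometric quantities, corneal thickness maps, posterior corneal ectasia,
irregular (non-Gaussian) cone shapes, and age or progression effects.
Passing cohort tests therefore show that the *pipeline* reproduces the
study's statistics under these study conditions, not that the generator is
a population model.

## Corrections

Both modalities use a fixed geometry and a variable anterior surface:
spectacles (n = 1.510, posterior radius 100 mm, centre thickness 2.000 mm,
vertex distance 12.000 mm in air) and scleral lenses (n = 1.415, posterior
radius 7.20 mm, centre thickness 0.300 mm, corneal vault 0.325 mm filled
with tears of n = 1.3368).  Anterior conic is -(1/n), posterior conic
-(n/n_following).  For a prescription (S, C, axis) the anterior surface is
a biconic whose meridian at the axis carries the radius solved for S and
the perpendicular meridian the radius for S + C; the radius comes from the
closed-form inversion of the thick-lens back-vertex relation.

Spectacle powers are air back-vertex powers (lensmeter convention).
Scleral powers are labelled *in situ*, as over-refraction relative to the
neutral diagnostic lens: the label-to-air-power offset (-4.325 D) is frozen
as the air back-vertex power of the scleral that leaves the emmetropic
template eye emmetropic through its tear layer.  This mirrors how scleral
prescriptions are ordered clinically and keeps the plano-anchored scleral
scan centred near its optimum.  (Defining scleral power as back-vertex
power in the tear medium was implemented and rejected: a "plano" lens then
contributes no vergence in tears, leaving the tear-masked eye tens of
diopters underpowered and the scan degenerate.)

## Ray tracing and the wavefront

A bundle of 121 parallel rays (object at infinity) is aimed so it fills the
5-mm physical pupil: hexapolar rings of 1+8+16+24+32+40 rays at radii
proportional to the ring index, launch heights scaled by the paraxial
front-magnification of each configuration.  Surfaces are intersected in
closed form (rotationally symmetric conics) or by damped Newton iteration
on the sag function (toric or cone-perturbed surfaces, |error| < 1e-9 mm);
refraction is the vector Snell law; rays that miss an aperture or suffer
total internal reflection are excluded and counted (more than 20% lost
raises an error).

The optical path difference of each ray is evaluated against the chief ray
on the reference sphere centred at the chief ray's retinal intersection and
passing through the exit pupil (the paraxial image of the physical pupil
through the crystalline lens).  The sign convention `OPD = OPL_chief -
OPL_ray` makes a myopic eye yield a positive defocus coefficient and hence
a minus-sphere prescription.

The OPD samples are fitted with an eighth-order normalized (OSA/ANSI)
Zernike series by least squares at the achieved pupil coordinates.  The
fitted coefficients carry two pupil-radius labels:

* the **physical** label (2.5 mm) for the image-quality chain, so PSFs are
  computed for the 5-mm aperture;
* the **dioptric** label for the refraction formulas.  The wavefront is
  sampled over the exit pupil, which is magnified relative to the physical
  pupil, and a spectacle's power reaches it through the eye's front optics
  with a further vergence magnification.  Both factors are folded into one
  equivalent radius, measured per eye with two +/-1 D probe traces (a
  paraxial computation of the same quantity serves as cross-check), so that
  second-order coefficients read directly in spectacle-plane diopters and
  prescribing the Zernike refraction nulls the residual c2 terms in one
  step on template-scale ametropias.

Objective refractions: the Zernike refraction uses second-order terms only
(M = -4*sqrt(3) c20 / r^2 etc.); the Seidel refraction matches the paraxial
(r^2) content of the wavefront and mixes in the radially symmetric and
astigmatic chains of orders 4 and 6 with factors 12*sqrt(5), -24*sqrt(7)
(m = 0) and 6*sqrt(10), -12*sqrt(14) (m = +/-2).  Whether the astigmatic
chains are included is a switch, default on.  Conversions between
(S, C, axis) and power vectors (M, J0, J45) follow the standard Fourier
form; minus-cylinder convention with axis in [0, 180) throughout.

## VSX

The PSF is |FFT of exp(i 2 pi W / lambda)|^2 over the circular 5-mm
aperture, pupil sampled on a 256x256 grid (192x192 in the scaled-down
cohort settings) and zero-padded 2x, giving an angular pixel of
lambda/(2D) = 0.19 arcmin.  Piston and tilt are zeroed before the
transform.  The neural weighting is the closed-form spatial kernel of an
exponential photopic neural contrast sensitivity function
N(f) = exp(-f/f0), f0 = 7 cycles/degree:

    NW(r) = (1 + (2 pi f0 r)^2)^(-3/2),  peak 1 at the origin,

positive and radially decreasing.  VSX is the inner product of the PSF with
the weighting *centred on the PSF peak*, normalized by the same quantity
for the diffraction-limited PSF; VSX(aberration-free) = 1 exactly.  Peak
centring (rather than centroid) was chosen because the weighting acts in
the space domain and the metric should reward the best-registered image
patch; for rotationally asymmetric eyes the centroid can sit far from any
image detail.  The choice of f0 fixes the absolute VSX scale; the template
calibration (above) was performed with this kernel frozen.

Far from focus the finite pupil grid undersamples the wavefront and the
FFT aliases; the aliased VSX values stay below ~0.006, comfortably under
every scan threshold, so they can never seed refinement (tested).  No
shortcut based on the residual Seidel blur is used: in keratoconic eyes the
best corrections can sit many diopters from the Seidel refraction - that is
precisely the multifocal phenomenon under study - and an early version of
the evaluator that skipped "hopelessly blurred" points suppressed the
distant foci entirely.

## The scan ladder

* spherical scan: 0.25-D steps over +/-10 D around the uncorrected Seidel
  sphere (spectacles) or plano (sclerals); 81 evaluations.
* stage A: coarse grid, 1-D sphere and cylinder steps, 10-degree axis
  steps, sphere within +/-7 D (spectacles) or +/-3 D (sclerals) of the best
  sphere, cylinder down to -16 D (configurable; the default is wide enough
  for the largest keratoconic foci).
* stage B: +/-0.5 D and +/-5 degrees around every stage-A point with
  VSX > 0.03, at half steps.
* stage C: +/-0.25 D and +/-2.5 degrees around every stage-B point with
  VSX > 0.01, at the final phoropter steps (0.25 D / 0.25 D / 2.5 deg).

All stage grids are integer multiples of the final lattice; duplicate
points are evaluated once (cache keyed on the canonical prescription; a
zero cylinder collapses the axis).  Ties at equal VSX break toward smaller
|sphere|, then smaller |cylinder|, then smaller axis.  The +/-7 D bound is
applied to the stage-A sphere range only; stages B and C are
neighbourhood-bounded.  If no stage-A point exceeds 0.03 the cloud is
returned with a warning flag rather than an error.  An exhaustive full-grid
search over the same bounds is retained purely as a test oracle.

Completeness condition: the ladder finds the global optimum provided every
relevant peak lifts some coarse-grid point above the stage thresholds,
i.e. peaks wider than the coarse step; the stub-surface tests exercise
exactly this condition.

## Foci

A focus is a connected component of the superlevel set
{VSX >= (2/3) max VSX} under 26-neighbourhood adjacency on the scan lattice
with the axis wrapping at 180 degrees; its peak is the component argmax.
When the superlevel set contains coarse-stage points (low-ceiling scans),
adjacency widens to the coarse lattice so isolated coarse samples of one
region are not miscounted as separate foci.  Note the *number* of
components is not monotone in the threshold (a ridge can split before its
branches vanish); the monotone property is refinement of the partition, and
that is what the tests assert.  Inter-focus separation is the Euclidean
distance between the two peak prescriptions in (M, J0, J45); axis
differences are reported in both conventions - unfolded |a1 - a2| in
[0, 180) and folded (<= 90 degrees) - with the unfolded value primary,
since reported mean axis differences near 96 degrees exceed the folded
maximum of 90.

The I-S (inferior-superior) index follows the Rabinowitz convention: mean
keratometric power (keratometric index 1.3375, meridional curvature by
central differences on a 0.05-mm grid) at five inferior points minus five
mirrored superior points on the 3-mm-radius circle at 30-degree spacing.
In this cone model the sign at the 3-mm ring depends on where the Gaussian
skirt crosses it: cones centred near the ring raise I-S, compact central
cones locally flatten the ring and can drive I-S slightly negative - which
is why the keratoconic cohort's I-S sits near zero here.

## Problem sizes and numerical choices

Default settings trace 121 rays per evaluation and evaluate a full PSF for
every scan point.  Cohort-scale runs (the acceptance script, the cohort
CLI default) use scaled-down settings chosen as a deliberate
accuracy/throughput trade-off: a 192x192 pupil grid (VSX changes by < 1%
versus 256), a coarsened scan lattice (0.5-1 D and 5-10 degree final
steps), and a final local hill-climb at the full phoropter resolution
(0.25 D / 2.5 deg) around every reported peak so best-correction values are
still quoted at clinical resolution.  Degenerate inputs are handled
explicitly: zero cylinder collapses the axis to 0; rejection sampling and
solver failures in the generator trigger a redraw up to a configured
attempt cap; empty survivor sets flag the scan rather than aborting it.

## Known limitations

- The cone is a single Gaussian bump on the anterior cornea; real cones are
  asymmetric, have a broader steep plateau, and involve the posterior
  surface and thickness.  The bump reproduces the shell-shaped correction
  clouds and genuine double foci, but the secondary (cone-region) focus
  clears the two-thirds-of-maximum criterion less often and at somewhat
  smaller separations than a full topographic cone model would give;
  widening the cone to raise the double-focus prevalence trades directly
  against the best-corrected VSX level and the separations.
- Lenses are rigid, centred and on-axis; no flexure, decentration or tilt.
- Monochromatic 555 nm only; indices are treated as valid at 555 nm.
- VSX on its own does not predict absolute acuity; the simulated charts are
  qualitative.
- The neural-CSF constants are a frozen, documented parametrization, not a
  fit to any individual observer.
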