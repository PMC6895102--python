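# Methods

This note records the models the package implements, the parameters
that matter, the choices made where the design was genuinely open, and
what the simulations do and do not establish.

## Geometry and frames

The global origin sits at the centre of the field of view, +z towards
the detector. The pinhole plate centre is at z = 45.2 mm; the septa
walls span z ∈ [50, 55) mm and the bottom crystal z ∈ [55, 58) mm.
This 3.8 mm gap between the plate exit face and the wall tops is a load
bearing feature: the steepest ray a knife-edge aperture can pass makes
tan α = d′/h = 1.84 (α ≈ 61.5°, hence the 28.5° minimum incidence angle
onto a wall, l/cos 28.5° ≈ 2.3 mm effective thickness), and with this
gap such a ray still meets a wall before reaching a neighbouring cell.
A much larger plate-to-wall distance would let oblique rays fly over
the walls and re-introduce multiplexing — which is measurable with this
package (`tests/test_transport.py::test_septa_block_cross_cell_rays`).

Each module's local frame has its origin at that module's pinhole
centre. All element boxes are half-open `[lo, hi)`, making
point-in-element lookup unique on shared faces. The knife-edge aperture
is a double cone built from (h, d, d′) as given constants; the printed
40° opening equals the cone half-angle implied by them
(tan 40° = (d′ − d)/h).

The 4 × 4 camera abuts modules at 12 mm pitch. An optional
`inter_septa_plate_mm` inserts thin tungsten sheets on the module
boundary planes from the plate exit down to the septa bottom; this
removes most of the residual cross-cell leakage (photons crossing a
wall at ~33% transmission or jumping the plate-to-wall gap). The
240-module SPECT ring places 24 modules per 15° step on a 40 mm
pinhole radius, 10 axial rings of 12 mm; every module is a proper rigid
copy of the reference module with its axis through the cylinder axis.

No housing or side shielding is modelled: a broad source that wraps
around the camera laterally can strike the side faces of the detector
stack directly. This matters for the large-sphere experiment (below)
and is stated there.

## Photon transport

140 keV monoenergetic photons (Tc-99m photopeak). Linear attenuation
coefficients are frozen constants from standard attenuation tables:
GaGG (Gd₃Al₂Ga₃O₁₂, ρ = 6.63 g/cm³): μ_PE = 0.398 mm⁻¹,
μ_C = 0.089 mm⁻¹; tungsten: μ = 3.38 mm⁻¹. Coherent scattering is
neglected; the photoelectric share μ_PE/(μ_PE + μ_C) ≈ 0.82. These
values reproduce the three device-level closure figures (~80% of first
interactions within 3 mm; ~67% stopping over 2.28 mm; photoelectric
share ~85%) within a few percentage points — the three printed figures
are not exactly mutually consistent, and the frozen constants sit
inside all three bands.

The tracer computes the exact tungsten chord of each ray through the
plate (slab minus the analytic double-cone void, quadratic roots per
half-plate) and treats tungsten as a pure absorber (collimator scatter
back into the crystals is a sub-percent effect at this energy and
thickness). Scintillator traversal uses exact ray–box chord
decomposition over all element boxes, a single exponential optical
depth draw per flight, photoelectric termination, and Klein–Nishina
sampled Compton continuation (rejection sampling; deposited energy
E − E′). Coefficients are kept at their 140 keV values for scattered
photons (90–140 keV); scattered photons are predominantly absorbed
within a few mm, so the induced bias is small. Each Monte Carlo
experiment derives all randomness from one seed.

Emission sampling can restrict directions to the cone subtending the
camera, either carrying the solid-angle weight Ω/4π per decay or
Bernoulli-thinning by it; both leave detected-event statistics unbiased
and the thinned form is what the reconstruction chain consumes.

### Characterization experiments

* *Depth statistics*: ≥10⁵ photons at central normal incidence on a
  300 mm GaGG block; reports the first-interaction fraction within 3 mm
  (≈ 0.77) and the photoelectric share of all interactions (≈ 0.82).
* *Septa share*: a uniform 10 cm-radius sphere centred 10.5 cm from the
  plate illuminates the 4 × 4 camera; among all interactions in the
  five detector elements per module, ≈ 62% occur in the walls — the
  sensitivity gained by making the septa active. With no housing
  modelled, side-entry photons contribute to this number; the result is
  insensitive to that detail at the ±few-percent level.

## Readout model

The physical device reads the light of both the bottom crystal and the
walls with one 4 × 4 array of 3 × 3 mm² pixels (50% quantum efficiency)
under the bottom crystal. The optical surface treatments (specular
reflector on the wall faces, black paint, retro-reflector) are **not**
ray-traced; they are abstracted into a parametric charge-spread kernel,
and this abstraction is the package's main fidelity gap:

* expected pixel charge = E · yield(46 ph/keV) · collection(0.6) ·
  QE(0.5) · (2-D Gaussian integral over the pixel), Poisson-realized;
* the spread width grows with stand-off from the photodetector plane,
  σ(z) = σ₀ + k·(z_pd − z), which is what carries depth information
  (walls sit 3–8 mm above the plane, the bottom crystal 0–3 mm);
* inside a wall the spread is anisotropic: the reflective wall faces
  confine light transversely (constant σ_wall) while it spreads freely
  along the wall. This is what makes the transverse wall coordinate
  resolve *better* than the along-wall one — with any isotropic kernel
  that ordering is unreachable.

The three free parameters are frozen at σ₀ = 0.5 mm, k = 0.8,
σ_wall = 2.4 mm, chosen once on calibration-style simulations to
balance septa/bottom discrimination against the resolution ordering.
With them the pipeline delivers σ_transverse ≈ 1.2 mm <
σ_along ≈ 1.4 mm for wall events, DOI residual σ ≈ 1.3 mm, bottom
centroid σ ≈ 0.2 mm, and ≈ 92–93% discrimination efficiency. The
device-level study reports finer wall coordinates (0.3/0.8 mm) and a
coarser bottom (1.2 mm FWHM); matching those exactly would require the
full optical simulation, so they are treated as qualitative targets
while the *ordering* and the discrimination efficiency are the
properties this package asserts.

The pixel array is centred under the crystal. A rigid lateral offset
(to put two pixel rows under each wall) was considered and rejected:
with 16 pixels per module any offset breaks the ±x/±y wall symmetry and
starves two of the four walls of coverage; the compressed transverse
scale of the centred layout is exactly what the [a′,b′] → [a, b]
interval renormalization undoes.

### Estimators and discrimination

Wall events use the centre of mass of the N = 4 largest pixel charges
(ties broken deterministically by pixel index); the transverse
coordinate is affinely renormalized from the calibrated raw interval
[a′, b′] (0.5th/99.5th percentiles on calibration data) onto the
physical wall cross-section, with clamping. Bottom events use the RTP2
centroid and a fixed depth equal to the mean of an exponential
truncated to the 3 mm crystal (1.15 mm below the entry face) — the
statistically correct single depth when no DOI is estimated.

Depth is estimated from the ratio Q_tot/Q₁ᵐᵃˣ ∈ [1, 16] through a
monotone isotonic calibration fitted on an isotropic point source at
the pinhole centre. The septa/bottom decision ("DOI in the septa band
and Anger centroid close to a wall centre") is operationalized as a
linear discriminant in the (ratio, centroid magnitude) plane, fitted
during the same calibration; fixed hand thresholds on either quantity
alone are measurably worse. The wall identity comes from the centroid
azimuth with sector boundaries at the pinwheel corner directions
(a naive dominant-component rule misassigns the corners each wall
owns). Efficiency is scored on the binary septa-versus-bottom
assignment — the decision the rule exists for — with wall-identity
accuracy reported separately (≈ 100% with the anisotropic kernel).

## Reconstruction

Each accepted event becomes a LOR through its estimated impact point
(global frame) and its module's pinhole centre; events are assigned to
the module that received the most energy. Voxel traversal uses the
Siddon parametric formulation (sorted plane crossings; exact chords;
half-open voxel convention). System elements are the chords weighted by
the inverse squared distance of the chord midpoint to the pinhole — the
solid-angle factor of the aperture. The bare-length kernel is available
as a switch, but at FOV depths spanning 5–85 mm it is badly
inconsistent along each line (a uniform ball then reconstructs as a
hollow shell), so the weighted form is the default.

The sensitivity Σᵢ pᵢⱼ is estimated by Monte Carlo: a uniform virtual
source filling the FOV box is *acquired through the same transport and
readout chain*, and each resulting LOR's system row is accumulated
after normalization by its own forward projection of the uniform image.
Both points matter: sampling uniform point pairs with only an aperture
test drops the detection weighting, and skipping the normalization
squares the measure (virtual events are drawn with intensity
proportional to that forward projection) — either error redistributes
intensity visibly. A cheap geometric pair-sampling estimator is kept as
a primitive for studying Monte Carlo error scaling.

LM-OSEM hyperparameters (unstated in the device study) default to 10
subsets, 5 iterations, Gaussian smoothing of 1 voxel after each
sub-iteration, 2 mm voxels at desk scale; voxels whose sensitivity
falls below 1% of its maximum are frozen at zero (their 1/sensitivity
factor is noise-dominated). Subsets are formed by striding, so results
are independent of event order within a subset.

### Phantoms and experiments

Phantom presets follow the study: the 4 cm-radius background sphere
(3.7 MBq, A_V ≈ 0.373 µCi/cm³) centred on the FOV centre; three 1 cm
hot spheres at 2 cm spacing in a plane parallel to the collimator at
distance d, at 2:1 specific activity (hot volumes *replace* background
activity in their extent); the tetrahedral four-sphere variant; and the
SPECT cylinder (5 cm ⌀ × 5 cm, 3 MBq) with two 2 mm rods at 10:1 (the
rod lateral positions, unstated in the study, are fixed at (12, 0) and
(−8, −8) mm). Decay times are uniform over the acquisition; radioactive
decay during ≤60 s acquisitions is neglected. Phantom self-attenuation
is not modelled (sources emit into vacuum).

Full-chain runs are desk-scaled: tests use activity scales of
0.05–0.5 relative to the nominal 3.7 MBq so that single runs finish in
tens of seconds to a few minutes on one CPU; the structural metrics
below are computed at those sizes. SPECT acquisitions pool five ring
rotations of 3° (covering the 15° pinhole spacing together with the
ring symmetry).

Image quality is quantified structurally, since the study's figures are
qualitative: smoothed local maxima above 50% of the slice maximum in
the phantom plane, truth-matched within 5 mm, and peak-to-valley ratios
along the lines joining true sphere centres ("resolved" = all maxima
matched and every peak-to-valley > 1).

## Known limitations

* The charge-spread kernel replaces the optical simulation; absolute
  resolution numbers are approximate (ordering and discrimination
  efficiency are the validated properties).
* Limited-angle artifacts: with a single planar camera, list-mode OSEM
  with Monte Carlo sensitivity reproduces point sources and separated
  hot spheres at their true positions, but a *low-contrast* (2:1)
  structure inside the full 8 cm background sphere is not recovered as
  matched maxima at any statistics tried (up to the nominal
  3.7 MBq × 10 s): structured background inhomogeneity tied to the
  support edge and the aperture pattern exceeds the 2:1 contrast. The
  spheres do remain visible as structure (peak-to-valley > 1 along all
  centre pairs), which is what the tests assert. The device study's
  reconstruction (10⁸ virtual LORs, unstated hyperparameters) evidently
  controlled this better; closing that gap would need a substantially
  larger sensitivity computation than a desk-scale run affords.
* No detector electronics, energy resolution, dead time, or phantom
  attenuation/scatter; no housing or side shielding.
* Monotone image-quality degradation with phantom distance (d = 2→4 cm)
  is too noise-dominated at desk scale to assert as a test.
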