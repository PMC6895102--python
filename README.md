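# activesepta

Monte Carlo simulation and list-mode reconstruction toolkit for a
multi-pinhole gamma camera with **active septa**: the collimating walls
between pinhole cells are themselves position-sensitive GaGG
scintillators. Because every photon that would otherwise land in the
overlap region of a conventional multi-pinhole camera is either stopped
*and measured* by a wall or confined to its own cell, the pinhole each
detected photon traversed is identified unambiguously — high sensitivity
without multiplexing artifacts.

The package is aimed at detector physicists and image-scientists who
want to study this design computationally: it models the device
geometry exactly, transports 140 keV (Tc-99m) photons through it,
simulates the pixel readout and the impact-coordinate estimators, and
reconstructs activity distributions with list-mode OSEM.

## The device

One module is a knife-edge tungsten pinhole (thickness h = 2 mm, inner
diameter d = 2 mm, outer diameter d′ ≈ 3.68 mm) looking at a
12 × 12 × 3 mm³ GaGG bottom crystal, with four 2 × 10 × 5 mm³ GaGG
septa walls standing pinwheel-fashion on its perimeter (walls span
z ∈ [50, 55) mm, bottom z ∈ [55, 58) mm, pinhole plate at z = 45.2 mm;
the global origin is the FOV centre). The camera is a 4 × 4 array of
modules; a proposed preclinical SPECT ring stacks 240 modules
(24 per ring × 10 rings, pinholes every 15°) on an 8 cm-bore cylinder.

## Models and estimators

* **Transport** — exponential free paths with frozen 140 keV linear
  attenuation coefficients (GaGG: μ_PE = 0.398, μ_C = 0.089 mm⁻¹;
  W: μ = 3.38 mm⁻¹), photoelectric termination, Klein–Nishina Compton
  continuation, exact ray–box chords through all elements and exact
  double-cone tungsten paths through the collimator.
* **Readout** — a 4 × 4 array of 3 × 3 mm² pixels (50% QE) with a
  parametric charge-spread kernel; impact coordinates via the N-maxima
  centroid  x̄ = Σᴺ xᵢQᵢᵐᵃˣ / ΣᴺQᵢᵐᵃˣ (N = 4) for wall events (with
  [a′,b′] → [a,b] interval renormalization of the transverse
  coordinate) and the RTP2 centroid for the bottom crystal; depth of
  interaction via the ratio 𝒩/ℐ = Q_tot/Q₁ᵐᵃˣ with a monotone
  calibration; septa/bottom discrimination by a calibrated DOI + Anger
  rule.
* **Reconstruction** — each event yields a LOR through its estimated
  impact point and its module's pinhole centre; system elements are
  Siddon voxel chords (optionally 1/r² solid-angle weighted); the
  per-voxel sensitivity Σᵢ pᵢⱼ is estimated by Monte Carlo from a
  uniform virtual source acquired through the same chain; images are
  iterated with list-mode OSEM
  λⱼ ← λⱼ/Σᵢpᵢⱼ · Σ_{k∈Sₗ} p_{i_k j} / Σ_b p_{i_k b} λ_b
  over ordered subsets with optional Gaussian inter-iteration smoothing.

## Worked example

```python
>>> import activesepta as A
>>> A.effective_path_length(2.0, 28.5)          # wall at minimum incidence
2.2757863623546606
>>> A.specific_volume_activity(3.7, "sphere", [4.0])   # uCi/cm^3
0.3730193978716298
>>> r = A.depth_stats_experiment(n_photons=50_000, seed=1)
>>> round(r["fraction_first_within_3mm"], 3), round(r["photoelectric_fraction"], 3)
(0.768, 0.816)
```

The first number is the effective wall thickness (mm) seen by the
steepest ray a knife-edge aperture passes; the second the specific
volume activity of the 3.7 MBq background sphere; the last two say that
~77% of first interactions happen within 3 mm of GaGG and ~82% of all
interactions are photoelectric — the properties that make a 3 mm
crystal and 2 mm walls efficient at 140 keV.

A full camera acquisition and reconstruction:

```python
from activesepta import experiments as E
image, metrics = E.run_derenzo(d_cm=2.0, seed=1)
image.save_nifti("derenzo.nii.gz")
```

or from the shell:

```
activesepta experiment fig4 --seed 1 --out out/fig4
activesepta experiment derenzo --seed 1 --scale 0.05 --out out/derenzo
```

Every run writes a config snapshot with its seed, so any output can be
regenerated exactly.

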