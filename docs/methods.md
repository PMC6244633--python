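# Methods

## RBED mathematics

Survival of an irradiated cell population is modelled as
SF(D) = exp(−αD − βD²) with α (Gy⁻¹) and β (Gy⁻²) fitted LQ
coefficients. Equating the survival of a nanoparticle-doped system A and
its undoped reference B yields a quadratic in the reference dose whose
positive root is the RBED:

    D_B = ( sqrt(α_B² + 4β_B(α_A D_A + β_A D_A²)) − α_B ) / (2β_B).

When the reference response is purely linear (β_B = 0) the degenerate
branch D_B = (α_A D_A + β_A D_A²)/α_B is used; it is the analytic limit
of the quadratic branch (verified numerically at β_B = 1e-8). A reference
with α_B = β_B = 0 is rejected.

**Concentration interpolation.** Radiosensitisation datasets typically
provide only a control and a single doped concentration C_M. Doped
coefficients at intermediate C are interpolated linearly,
α_A(C) = α_B + (C/C_M)Δα (β likewise). We define
Δα ≡ α(C_M, doped) − α(0, undoped): with this convention the
interpolation reproduces both measured endpoints exactly (bit-exact in
the tests) and reproduces the published worked-example RBED values. An
alternative reading of the deltas that references the *interpolated*
doped coefficient is self-referential and cannot recover the doped
endpoint, so it was rejected. Concentrations above C_M extrapolate and
are logged as warnings rather than rejected, since tumour-wall uptake
equals C_M and user scenarios may exceed it.

**Scenario registry** (`data/scenarios.json`): minimum / mean / maximum
radiosensitisation of MDA-MB-231 breast-cancer cells with 1.9 nm AuNPs
under 6 MV irradiation, measured at C_M = 500 μg/ml:

| scenario | α(0) | β(0) | α(500) | β(500) |
|----------|------|------|--------|--------|
| minimum  | 0.024 | 0.086 | 0.064 | 0.087 |
| mean     | 0.002 | 0.079 | 0.104 | 0.098 |
| maximum  | 0.000 | 0.072 | 0.144 | 0.109 |

The "conventional" entry carries identical doped/undoped parameters so
every code path treats it uniformly; its RBED map is the identity by
construction. Only breast tissue (breast + both tumour compartments)
responds; heart, lung, soft tissue and bone are mapped as identity —
equivalent to C = 0 but without requiring LQ parameters that were never
measured for those tissues.

**Equivalent exposure.** The scale factor f such that undoped tissue at
doses f·D(x) matches the doped region's cell kill is found by Brent
root-finding on f ∈ [1, 100] to relative tolerance 1e-8. The matching
criterion is *region-mean survival fraction*; other defensible criteria
(mean-RBED ratio, isoeffect on the minimum) give different numbers, so
published exposure-increase percentages from other matching rules are not
expected to be reproduced exactly.

## Phantom

The phantom is deliberately geometric, not anatomical. Stated study
quantities: two-compartment tumour of 20 mm outer / 16 mm inner diameter,
tumour centre 20 mm anterior of the left-breast centre along the breast
axis, breasts rotated 20° from the sternum, 1 mm³ default voxelisation,
AuNP uptake 500/250 μg/ml in the tumour wall/inner, 25 μg/ml in soft
tissues and organs, 0 in bone. Everything else (torso semi-axes
150 × 90 mm, breast fused cylinder-ellipsoid of radius 55 mm, seven
vertebrae and rib rings, sternum bar, lung ellipsoids, skewed heart
ellipsoid) is a configurable plausible default; no test or result depends
on these choices. Ribs are modelled as full elliptical-tube rings — a
simplification, as their true shape is not specified. The "lung wall"
component is modelled as a solid inflated-lung-tissue ellipsoid pair.

Voxelisation is by centre inclusion with integer priorities resolving
overlaps (tumour > breast > lungs > heart > bone > torso bulk).
Left/right organ pairs are built by reflecting one shape through the
sagittal plane, which makes the mirror symmetry of the label grid exact
in floating point (asserted in the tests, tumour excluded). Voxelised
volumes converge to the analytic solid volumes as spacing decreases;
note that lattice-symmetric shape centres align the surface with voxel
centres and carry the largest surface bias (≈1.5% for the 16 mm sphere
at 1 mm), while generic centres — as in the default phantom — land well
inside 1%.

Materials are ICRU-style elemental compositions (soft tissue, breast,
inflated lung ρ = 0.26 g/cm³, skeletal muscle, compact bone ρ = 1.85).
Gold doping adds Au at mass fraction (C·10⁻⁶ g/cm³)/ρ and renormalises;
the bulk density is kept (the perturbation is ≤ 5×10⁻⁴).

## Dose engine

The engine is a deterministic desk-scale surrogate for condensed-history
Monte Carlo transport, adequate for *relative* dosimetry and for the
doped/undoped perturbation claim, not for absolute dose maps:

* **Primary kerma raytrace.** Parallel rays on a voxel-pitch lattice fill
  the 30 mm circular aperture; each ray accumulates per-spectral-bin
  optical depth through the upstream voxel materials (midpoint rule) and
  deposits collision kerma Σ fluence·E·(μ_en/ρ)·exp(−τ) at each sample
  (charged-particle equilibrium assumed). Voxels outside the beam
  cylinder receive no primary dose. A monoenergetic run in uniform water
  reproduces the Beer–Lambert slope to 0.1% (R² > 0.999).
* **Scatter.** Lateral spread is a separable Gaussian with per-axis width
  σ·sqrt(1 − u_i²) (exact perpendicular smearing for grid-aligned beams,
  a small-angle approximation at the 20° obliquity). Reflective
  boundaries conserve integral dose to machine precision. Default
  σ = 6 mm — a tunable chosen for a qualitative broad-beam penumbra
  roll-off beyond ±15 mm, not a fitted claim.
* **Plan and calibration.** The default plan is two equal-weight opposed
  sub-fraction beams along the breast axis focused at the tumour centre.
  Absolute normalisation replaces the original absolute photon count by
  scaling the grid so the whole-tumour minimum equals the 2 Gy
  prescription exactly; calibration is idempotent.
* **Spectrum.** The bundled 6 MV spectrum CSV
  (`data/spectrum_6mv_synthetic.csv`) is an analytic gamma-shaped
  approximation (Φ ∝ E^0.45·e^(−E/1.2), 0.25–6 MeV, mean ≈ 1.7 MeV) to
  the published curve, which exists only graphically; it is
  user-replaceable via the documented CSV interface.

**Interaction coefficients.** No photon cross-section library is bundled
with the runtime environment, so the per-element μ/ρ and μ_en/ρ tables in
`data/attenuation_synthetic/` are *synthetic*: generated by the analytic
model in `rbedplan.physics` (exact Klein–Nishina scattering with a
numerically integrated energy-transfer fraction; a Z^4.5/E³
photoelectric parameterisation with a crude K-edge jump for high-Z
elements; a Z²-scaled pair-production term). In the 0.2–6 MeV range the
model is Compton-dominated and matches reference water values to well
under 1% (0.0494/0.0262 cm²/g at 2 MeV vs the standard 0.0494/0.0260);
below ~0.1 MeV and for gold it is qualitative only, which is immaterial
here because gold enters at mass fractions ≤ 5×10⁻⁴. Coherent scattering
and radiative losses of secondaries are neglected.

## DVH/RVH statistics

Cumulative histograms use a 0.01 Gy default bin width; V(d) is the
fraction of region voxels with value ≥ d, so the curve starts at 100%
and is non-increasing. Region statistics are exact voxel moments;
volume-weighted means of any region partition recompose the whole-region
mean to machine precision. Line profiles are trilinear at 0.5 mm
sampling. "Whole tumour" means inner ∪ wall.

Because RBED is concave in dose near 2 Gy, the RBED of a region's mean
dose slightly exceeds the mean of its voxel RBEDs; at the worked-example
doses the difference is ≲ 0.5%, which is why volume-weighting the
compartment worked examples reproduces the whole-tumour enhanced mean to
about 1% rather than exactly.

## Problem sizes and determinism

The default phantom voxelises at 1 mm (18.3 M voxels). The test suite and
the acceptance script run the same geometry at 2 mm (2.3 M voxels), where
a full doped + undoped calibrated fraction simulates in about a second;
this choice trades spatial resolution for fast, exactly reproducible
desk-scale runs and does not affect any quantity the tests assert, all of
which are resolution-robust (worked-example RBED values are closed-form;
engine claims are relative). Every stage is deterministic: identical
configurations produce bit-identical CSV/JSON outputs, and the pipeline
report embeds a hash of the scientific configuration (output paths
excluded), the package version and the seed.

## What the synthetic exemplar does and does not show

The generator-and-engine combination emulates the study conditions — the
uptake pattern, beam plan, prescription and response scenarios — but not
real patient anatomy, heterogeneous intra-tumour uptake, spectral
details, or electron-transport effects (build-up, disequilibrium at
interfaces). Passing tests therefore demonstrate the correctness of the
RBED mathematics, the interpolation, the histogram statistics and the
engine's stated physics properties; they do not validate absolute dose
distributions against Monte Carlo, and published values that depend on
the original MC dose maps (profile peak RBEDs, breast mean RBEDs,
exposure-increase percentages under an unstated matching criterion) are
covered by property invariants rather than numeric reproduction.

## Known limitations

* Collision-kerma transport: no electron disequilibrium, no beam
  divergence, no spectral hardening off-axis beyond the line integral.
* Synthetic cross sections: qualitative below 0.1 MeV and for high-Z
  photoelectric/pair detail.
* Linear concentration interpolation of LQ coefficients is an empirical
  device, not a mechanistic uptake model.
* The oblique-beam scatter kernel is separable, slightly anisotropic at
  20° obliquity.
* The phantom's unstated dimensions are conventions, not anatomy.
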