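# Methods

## Scope and intent

`oofdose` implements the complete out-of-field dose chain for PBS proton
therapy at desk scale: commissioning, plan/CT ingestion, component-resolved
transport, detector calibration chains, organ-dose and risk reporting, and
gamma-index QA. The transport engine is an explicit physics *surrogate*: it
reproduces the structure, interfaces and qualitative behaviour of a
general-purpose Monte Carlo study (component-resolved maps, log-binned
neutron spectra, batch uncertainties, seeded determinism) with simplified
interaction models that run in seconds on one CPU. Absolute out-of-field
magnitudes from a full Monte Carlo with a modelled treatment room are not
reproduction targets; the deterministic calibration arithmetic, the
commissioning tolerances and the qualitative mixed-field behaviour are.

## Stopping power and ranges (`oofdose.stopping`)

Electronic mass stopping powers use the Bethe formula with the exact
maximum energy transfer and no shell/density corrections (adequate above
~1 MeV for the 10–250 MeV regime used here). Materials carry mass
fractions, density and a mean excitation energy I; Z/A follows Bragg
additivity. CSDA ranges integrate 1/S on a 2000-point geometric energy
grid and are cached as cubic splines together with their inverse.

Two water I-value conventions coexist deliberately: `WATER` uses I = 75 eV
(the PSTAR convention), which reproduces the printed water-equivalent
thickness of the lucite range shifter (4.44 cm → 5.14 cm at 150 MeV);
`WATER_I_EV_GEANT4 = 78 eV` is kept as a named constant for users matching
condensed-history codes tuned to that value (it yields ≈ 5.17 cm and is
not used in the WET chain).

WET is computed by slowing-down, not by a single-energy ratio: the energy
lost through the slab is obtained from the material's CSDA range spline
and converted to the water path with the same entry energy. The air-path
mean-energy correction inverts a log–log cubic-spline fit of the air CSDA
range table (60 nodes, 1–300 MeV): ΔE is the source-side increment such
that the proton arrives at the nominal energy after the given track length
(0.29 MeV for 50 cm at 150 MeV).

## Analytical Bragg model and commissioning (`oofdose.bragg`)

The forward depth-dose model is the classic closed form obtained from a
power-law range–energy relation R = αE^p (α, p fitted once to the internal
CSDA curve over 60–250 MeV; α ≈ 2.31·10⁻³, p ≈ 1.76) with a linear
fluence-depletion term (β = 0.012 cm⁻¹, local-deposit fraction γ = 0.6)
convolved analytically with a Gaussian range spread, giving parabolic
cylinder functions D_v. The total range spread combines intrinsic
straggling σ_mono = 0.012·R^0.935 with the energy spread mapped through
dR/dE. Numerically, the plateau (>10σ upstream of R) uses the unconvolved
form and the peak region the D_v form; the seam is continuous to <2%.
The distal tail-buildup parameter ε defaults to 0 because the engine
tallies secondary protons separately.

`fit_energy_spread` is a bounded least squares on the normalized curve with
multi-start over σ_E (0.3/0.8/1.5 MeV) and the energy start implied by the
measured R80; afterwards a few Newton steps on dR/dE anchor the model's
R80 to the measured one, guaranteeing the ±0.01 cm commissioning
tolerance by construction. On 100 synthetic curves with 0.5%
multiplicative noise, |ΔE| ≤ 0.1 MeV in ≥95 cases (acceptance suite).
Curves without a distal falloff or without a peak-to-entrance contrast of
at least 1.2 are rejected.

## Machine model (`oofdose.machine`)

The commissioning grid runs from the lowest available energy upward in
fixed steps, appending the maximum energy when the stepped sequence misses
it (100.0 … 226.7 MeV in 5 MeV steps → 27 records). Records carry
(E, σ_E), Fermi–Eyges moments (A0, A1, A2) = (⟨θ²⟩, ⟨xθ⟩, ⟨x²⟩) per
transverse axis *at the nozzle-exit plane* (50 cm upstream of the
isocenter), and protons per MU; queries between nodes are linearly
interpolated. Spot back-projection treats each transverse axis
independently with its own scanning-magnet focus (defaults 220/180 cm
upstream of the isocenter — machine configuration, recorded explicitly in
the machine file since real focus distances are facility-specific). The
MU/ion calibration is the ratio of the prescribed dose per MU to the dose
per source proton scored in the reference geometry (41×41 spots at
0.25 cm, cylindrical tally ⌀1 cm × 0.5 cm at 3 cm depth in water).

Whether a machine's stated energy spread is absolute (MeV) or relative is
not standardized; this package uses absolute MeV throughout, and the
synthetic machine database uses σ_E = 0.6% of E.

## Plans and phantoms (`oofdose.plan`, `oofdose.phantom`)

Plans are field → energy-layer → spot hierarchies with spot positions at
the isocenter plane (cm) and MU weights; DICOM RT Ion files round-trip
through pydicom (positions mm→cm; the range-shifter thickness is encoded
in the accessory ID), and a YAML format carries the same information for
fixture-free tests. History allocation is largest-remainder proportional
to spot MU, deviating from exact proportionality by less than one history
per spot (<0.01% of any realistic total).

The coordinate system is right-handed, voxel-center addressed, distances
in cm, isocenter at the origin; gantry angles rotate the beam in the x–y
plane and the table about the longitudinal z axis.

The CT calibration is a Schneider-style piecewise lookup covering
[−1024, 3000] HU with 25 tissues + air: one lung bin, eight soft-tissue
bins interpolating adipose→muscle composition, sixteen bone bins
interpolating red marrow→cortical bone, with I-values ramping 63→106 eV.
Mass density follows a piecewise-linear ramp (air 0.00121; soft
1 + HU/1000; bone 1.1 + 5.65·10⁻⁴·(HU−100), capped at 2.8), and
per-structure density overrides are applied after the lookup — mirroring
the clinical practice of overwriting phantom-slab densities with datasheet
values. The table is a package-versioned construction in the style of the
published stoichiometric calibrations, not a reprint of any specific one.
Device-specific HU corrections are the caller's responsibility (apply them
to the HU grid before `load_geometry`).

## Transport engine (`oofdose.transport`)

**Primaries.** Condensed-history transport with a fixed geometric step
(default 0.1 cm): per step the residual *water-equivalent* range falls by
step × RSP(voxel), the deposit is the exact CSDA energy difference over
that decrement (energy-conserving by construction), and dose is
water-referenced (deposit / water mass of the voxel). Each history samples
its energy from N(E + ΔE_air, σ_E) and an additional Gaussian range
perturbation σ_mono, so the scored depth dose converges to the analytical
model; the scored R80 agrees with the analytical R80 to ≤0.03 cm on the
0.2 cm grid (tolerance 0.05 cm; the small residual is genuine
multiple-scattering path detour, which the 1-D analytic model ignores).
Two numerical details matter: deposits are attributed at segment
*midpoints*, and each history starts with a random sub-step lead —
without these, a step size commensurate with the voxel pitch aliases into
±20% even/odd slice artifacts. Lateral transport adds Highland
multiple-scattering kicks per step (X0 = 36.08 g/cm² everywhere; bone is
approximated as water-like for scattering) on top of the sampled
Fermi–Eyges phase space; the in-field dose passes a 3%/3 mm global gamma
test at >95% against an independent pencil-beam convolution oracle.

**Range shifter and air.** The range shifter is not voxelized: it
subtracts its WET from the residual range and adds a Highland angular kick
at its exit plane (default 20 cm upstream of the isocenter). The air path
from there to the phantom surface subtracts its (tiny) WET, and the
source-side mean-energy correction ΔE_air compensates it, as in the
commissioning procedure. With `world_medium="vacuum"` both vanish.

**Nonelastic events and secondaries** (`SecondarySourceModel` defaults):
events are sampled at 0.012 per cm of water-equivalent path above a
20 MeV threshold (the same β as the analytic depletion term). Each event
emits Poisson(1.6) neutrons — 65% Maxwellian evaporation at T = 2 MeV
(isotropic), 35% cascade (energy 0.1–0.6 of the primary's, direction
∝ exp(2.5·cosθ) about the field axis) — plus, with probability 0.6, one
secondary proton carrying 20–50% of the event energy (forward-peaked,
k = 6), 4 MeV of prompt gammas, and a local deposit of 35% of the
remaining energy standing in for heavy fragments and recoils. Sampled
energies never exceed the event energy, so total deposition is bounded by
the beam energy. These are documented surrogate defaults chosen for
physical plausibility, not fitted claims.

**Neutrons.** Analog ray-tracing (no variance reduction): exponential
removal with a log-interpolated water removal coefficient (3 cm⁻¹ thermal
→ 0.035 cm⁻¹ at 1 GeV, density-scaled), one isotropic scatter with energy
degradation U(0.05, 0.5), then either thermalization (30%, one thermal
flight) or absorption with a 2.2 MeV capture gamma (80%). Track lengths
are scored per voxel into a log-energy fluence spectrum (1 meV–1 GeV, 10
bins/decade), and simultaneously into the neutron dose-equivalent map via
h(E) and into the secondary-proton dose map via the tissue kerma factor
k(E) — the kerma approximation for neutron-induced recoil protons. The
derived quality factor H/D_recoil is therefore the fluence-kerma-weighted
Q(E), landing at ≈8–9 for the brain-plan field (acceptance band [5, 15]).
Neutrons leaking the grid feed a uniform room-return thermal fluence
(albedo 0.08 of the leakage per grid surface area) standing in for the
treatment room; its magnitude is a calibration knob unconstrained by
printed data. At desk-scale history counts the analog estimator is sparse
far out-of-field: beyond ~40 cm the scored field is dominated by the
uniform room-return term, which is why monotonicity checks use
median-filtered, detector-volume-averaged profiles and why far positions
are excluded from thermal-share point checks (the volume-integrated
thermal share stays ≪5%).

**Gammas.** Straight-line kerma estimator: energy fluence attenuates with
μ_att/ρ = 0.045 cm²/g and deposits with μ_en/ρ = 0.026 cm²/g (2–4 MeV
photons).

**Uncertainty.** Histories are split into 10 batches; per-voxel relative
uncertainty is the k = 1 standard error of the batch mean. Fixed seed and
single-threaded numpy give bit-identical maps.

## Detector chains (`oofdose.detectors`)

MTS-7: D_W = K_air × 1.12 (mass energy-absorption ratio water/air at
Co-60), normalized per physical target dose; uncertainty is the quadrature
of the enabled budget components (dosimeter 1.8%, batch 1.9%, Co-60
calibration 2.4%, background up to 11%, proton energy response 5%, photon
energy response 1%; k = 1). MCP-6 − MCP-7: air-kerma difference (floored
at zero with a warning; the convention for negative differences is not
standardized) × 1.24·10⁻² mSv/mGy → thermal H; ×1.12 → the
"gamma-equivalent" convention; the two outputs satisfy
gamma_equivalent / 1.12 × 1.24·10⁻² = H identically, and the chain
reproduces the printed far/near endpoints (6.9 µGy/Gy → 0.08 µSv/Gy;
1846 µGy/Gy → 20.4 µSv/Gy, within 1% of the printed 20.3). The thermal
coefficient carries a factor-2-class (100%, k = 1) uncertainty. BD-PND:
H = counts / sensitivity / target dose, uncertainty max(counting
statistics, 20%); the energy response above 20 MeV is treated as flat
(flagged, since it is not fully characterized). The Cf-252 sensitivity is
per-detector calibration data and is always a caller input.

## Reporting (`oofdose.reporting`)

H_total = 1.1·D_primary-proton + 1.0·D_gamma + H_neutron voxelwise. The
secondary-proton map is *not* added: out of field it is recoil dose
already counted inside H_neutron (adding it would double-count the same
physical dose with and without its quality factor). Organ doses are ROI
voxel means of H per target dose; course totals multiply by the physical
course dose and round to two significant figures; risks round to one
decimal in percent and physical doses to one decimal — fixed conventions
that make the worked examples exact test oracles (45.8 Gy, 120 mSv, 0.2%,
0.1%). LAR scaling is linear no-threshold, Sv≈Gy, with the embedded
age-5 incidence coefficients (breast 914 ♀, lung 608/261, thyroid 419/76
per 10⁵ per 0.1 Gy). The linear rule gives ≈0.5% for the women's thyroid
figure where 0.6% is sometimes quoted; the discrepancy is noted, not
emulated. A second course segment delivering a few Gy(RBE) to a
marginally reduced volume is approximated by linear scaling of the
initial beam set.

## Gamma QA (`oofdose.gamma`)

γ(voxel) = min over evaluated points within 3× the distance criterion of
√((d/dta)² + (ΔD/δ)²); δ is a percentage of the masked reference maximum
(global) or of the local reference dose (local; zero-dose voxels fall back
to the dose term alone). γ ≤ 1 passes, including the boundary. The search
runs over voxel centers by default and exactly matches a brute-force
exhaustive oracle; `subsample > 1` refines the lattice with trilinear
interpolation for sub-voxel agreement. Offsets are visited in increasing
distance, so the search terminates early once the pure distance penalty
exceeds every running minimum. The default low-dose threshold is 0%
inside the evaluation mask.

## Synthetic fixtures (`oofdose.fixtures`)

The generators emulate the study conditions: a three-field brain plan
(two ipsilateral oblique fields and one contralateral, energy layers
100–165 MeV, 4.44 cm lucite range shifter, prescription 50.4 Gy(RBE)), a
simplified 5-year-old head–torso phantom with six tissue types and 28
standard organ ROIs, TLD positions at 6.7–50 cm from the isocenter along
the inferior axis, TLD irradiation at 100.8 Gy(RBE) and bubble-detector
irradiation at a few Gy(RBE). Detector readings are produced by running
the engine and inverting the exact evaluation chains with
budget-consistent noise, so detector evaluation round-trips to the
simulated truth — a check the physical experiment cannot offer. What the
fixtures do **not** emulate: anatomical realism of a commercial
anthropomorphic phantom, CT artifacts, the treatment room geometry, and
the absolute out-of-field magnitudes of a full Monte Carlo; green tests
demonstrate the correctness of the chain and the qualitative physics, not
clinical dose accuracy.

Problem sizes are the package's own desk-scale choices: the default study
case uses a 0.5 cm grid and 4–6·10⁴ histories (seconds per run); the
commissioning and water-tank checks use the native 0.2–0.25 cm grids with
2.5·10⁴–1.2·10⁵ histories. The water-tank preset defaults to the 50 cm
reference cube; tests pass reduced shapes explicitly.

## Known limitations

* The surrogate neutron/gamma physics is parametric; energy and angular
  distributions are plausible but not benchmarked against cross-section
  data, and heavy fragments are lumped into a local deposit.
* The h(E) = k(E)·Q(E) table is a package-built compilation (hydrogen
  recoil + thermal capture kerma, standard-shaped quality factors) on 19
  log-energy nodes; it is the default and is swappable wherever a
  `ConversionTables` is accepted.
* Analog scoring is sparse far out-of-field at desk-scale history counts;
  far-field values are dominated by the uniform room-return term.
* Scattering uses the water radiation length everywhere; bone/lung
  heterogeneity affects only the stopping path exactly, the scattering
  approximately.
* No charged-particle-equilibrium corrections, no fractionation effects,
  and no full lifetable risk model (the LAR scaling is linear
  no-threshold on incidence coefficients).
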