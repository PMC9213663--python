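# oofdose

Out-of-field dosimetry for pencil-beam-scanning (PBS) proton therapy, at
desk scale.

During proton therapy, nonelastic nuclear reactions in the patient and the
beamline produce secondary neutrons, protons and gammas that deposit dose
far outside the treatment field. This out-of-field dose — 5 to 6 orders of
magnitude below the target dose — drives the risk of radiation-induced
second cancers and is particularly relevant for pediatric patients, yet no
clinical treatment-planning system computes it. `oofdose` implements the
full computational chain a medical physicist needs to estimate it:

* **Beam model commissioning** — an analytical Bragg-curve model
  parameterized by mean energy E and Gaussian energy spread σ_E, built from
  a power-law range–energy relation R = αE^p convolved with the total range
  spread σ_R² = σ_mono² + (σ_E · dR/dE)², evaluated with parabolic-cylinder
  functions; fitting recovers (E, σ_E) from measured depth-dose curves with
  the standard ±0.01 cm R80 commissioning tolerance. Lateral optics follow
  Fermi–Eyges theory: σ²(z) = A2 + 2·A1·z + A0·z² per transverse axis, with
  spots back-projected from the scanning-magnet foci to the nozzle exit.
* **Plan and CT ingestion** — DICOM RT Ion plans (or an equivalent YAML
  format), a Schneider-style piecewise HU → 25-stoichiometric-tissue
  lookup on a 0.2 cm grid, per-structure density overrides, and
  MU-proportional history allocation.
* **Surrogate transport** — condensed-history CSDA proton transport with
  Highland multiple scattering; nonelastic events spawn neutrons
  (Maxwellian evaporation + forward-peaked cascade), secondary protons and
  prompt gammas; neutrons are ray-traced with exponential removal, a single
  scatter, thermalization, and a room-return term; per-voxel neutron
  fluence is scored on logarithmic energy bins and folded with
  h(E) = k(E)·Q(E) into an ambient dose equivalent.
* **Mixed-field detector chains** — MTS-7 TLDs (Co-60 air-kerma
  calibration, D_W/K_air = 1.12), the MCP-6 − MCP-7 pair for thermal
  neutrons (1.24·10⁻² mSv/mGy), and BD-PND bubble detectors, each with its
  metrological uncertainty budget.
* **Reporting** — total dose equivalent H = 1.1·D_proton + D_gamma +
  H_neutron, 28 organ doses per target dose and per treatment course, and
  BEIR-VII-style lifetime-attributable-risk scaling.
* **QA** — a 3D gamma index (global/local normalization, exhaustive search
  within 3× the distance criterion, optional sub-voxel interpolation).

## Worked example

```python
import numpy as np
from oofdose import compute_wet, LUCITE, physical_target_dose
from oofdose.detectors import gamma_equivalent_to_h
from oofdose.fixtures import FixtureSpec, make_synthetic_case
from oofdose.reporting import (compose_total_dose_equivalent,
                               compute_organ_doses, target_dose_per_proton)

print(round(compute_wet(LUCITE, 4.44, 150.0), 2))      # 5.14 (cm)
print(physical_target_dose(50.4, 1.1))                 # 45.8 (Gy)
print(round(gamma_equivalent_to_h(6.9), 2))            # 0.08 (uSv/Gy)

spec = FixtureSpec(seed=7, histories=60_000, spacing_cm=0.5)
plan, phantom, readings, maps = make_synthetic_case(spec)
h_total = compose_total_dose_equivalent(maps)
d_t = target_dose_per_proton(maps, phantom.roi_masks["target"])
rois = {k: v for k, v in phantom.roi_masks.items()
        if k not in ("target", "body")}
print(compute_organ_doses(h_total / d_t * 1e6, rois, 45.8))
```

The first three lines verify the deterministic chain arithmetic: the
4.44 cm lucite range shifter is 5.14 cm water-equivalent (Bethe
stopping-power-ratio integration), a 50.4 Gy(RBE) prescription is 45.8 Gy
physical dose at proton RBE 1.1, and a far-field thermal-neutron reading of
6.9 µGy/Gy gamma-equivalent converts to 0.08 µSv/Gy dose equivalent. The
last block runs the full surrogate study — a three-field brain plan on a
child head–torso phantom — and prints the 28-organ report; with this seed
the thyroid receives 602 µSv per target Gy (28 mSv over the 45.8 Gy
course), the lungs ~200 µSv/Gy, the testes ~43 µSv/Gy, and the derived
out-of-field quality factor H_neutron/D_secondary-proton averages 8.7.
Absolute out-of-field magnitudes depend on the surrogate physics
parameters and the desk-scale history count; the chain arithmetic, the
component structure and the qualitative falloff are the validated outputs.

A CLI mirrors the library:

```sh
oof fixtures --preset brain3field --seed 7 --out case/
oof transport --plan case/plan.yaml --machine case/machine.tsv \
    --phantom case/phantom.h5 --histories 100000 --seed 1 --out maps.h5
oof convert-detectors case/readings.csv --out doses.csv
oof report maps.h5 --phantom case/phantom.h5 --course-dose-gy 45.8 --out organs.csv
oof gamma ref.h5 eval.h5 --dose 1 --dta 2 --mode global
```

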