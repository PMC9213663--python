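"""Seeded synthetic fixtures: machine data, phantoms, plans, readings.

Everything the framework consumes can be generated here deterministically:
a commissioned-machine database, synthetic depth-dose curves from the
analytical Bragg model, water-tank and simplified child head-torso voxel
phantoms, single-spot and three-field brain plans (100-165 MeV layers
behind a 4.44 cm lucite range shifter), and mixed-field detector reading
tables.  Detector readings are produced by running the transport engine
and inverting the exact calibration chains used for evaluation, with
noise drawn from the stated uncertainty budgets — so detector evaluation
round-trips to the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import bragg
from .conversion import ConversionConstants
from .detectors import DEFAULT_BUDGET_COMPONENTS, READINGS_COLUMNS
from .machine import (
    EnergyLayerRecord,
    MachineDatabase,
    SpotSpec,
    build_energy_grid,
)
from .phantom import VoxelPhantom, build_tissue_table
from .plan import (
    DEFAULT_RANGE_SHIFTER,
    EnergyLayer,
    FieldSpec,
    TreatmentPlan,
)
from .stopping import WATER
from .transport import (
    ComponentDoseMaps,
    SecondarySourceModel,
    TransportConfig,
    run_transport,
)

#: TLD/BD positions: distances from the isocenter [cm] along the
#: inferior body axis, spanning the near-field to far out-of-field range.
DETECTOR_DISTANCES_CM = (
    6.7, 7.8, 9.0, 11.0, 13.0, 16.0, 19.0, 23.0, 28.0, 33.0, 38.0, 43.0, 50.0
)
BD_DISTANCES_CM = (6.7, 11.0, 19.0, 28.0, 38.0, 43.0)

#: 28 organ ROI centers (cm) in the child phantom, isocenter at the
#: cerebellar target.  z runs superior (+) to inferior (-).
ORGAN_CENTERS: Dict[str, tuple[float, float, float]] = {
    "brain": (0.0, 3.0, 4.0),
    "pituitary": (0.0, 2.0, 1.0),
    "eye_left": (-2.5, 6.0, 1.0),
    "eye_right": (2.5, 6.0, 1.0),
    "salivary_glands": (0.0, 3.0, -4.0),
    "oral_cavity": (0.0, 4.0, -5.0),
    "thyroid": (0.0, 3.0, -8.5),
    "esophagus": (0.0, 1.0, -12.0),
    "thymus": (0.0, 3.0, -13.0),
    "lung_left": (-4.0, 0.0, -15.0),
    "lung_right": (4.0, 0.0, -15.0),
    "breast_left": (-4.0, 4.5, -15.5),
    "breast_right": (4.0, 4.5, -15.5),
    "heart": (1.0, 2.0, -16.0),
    "liver": (3.0, 1.0, -21.0),
    "stomach": (-3.0, 2.0, -21.0),
    "spleen": (-4.0, -1.0, -21.0),
    "pancreas": (0.0, 0.0, -22.0),
    "adrenals": (0.0, -2.0, -23.0),
    "kidney_left": (-3.0, -2.0, -24.0),
    "kidney_right": (3.0, -2.0, -24.0),
    "small_intestine": (0.0, 1.0, -26.0),
    "colon": (0.0, 2.0, -28.0),
    "bladder": (0.0, 1.0, -31.0),
    "ovaries": (0.0, 0.0, -30.5),
    "uterus": (0.0, 0.5, -31.5),
    "prostate": (0.0, 0.0, -32.5),
    "testes": (0.0, 2.0, -34.0),
}


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic study case."""

    seed: int = 0
    phantom_preset: str = "child_head_torso"  # or "water_tank"
    plan_preset: str = "brain3field"  # or "single_spot"
    spacing_cm: float = 0.5
    tank_size_cm: float = 50.0
    histories: int = 40_000
    tld_target_dose_gy_rbe: float = 100.8
    bd_target_dose_gy_rbe: float = 6.0
    bubble_sensitivity: float = 2.0  # bubbles per uSv
    noise: bool = True


# ----------------------------------------------------------------- machine


def make_machine_database(
    spot_sigma_iso_cm: float = 0.55, divergence_rad: float = 3e-3
) -> MachineDatabase:
    """Deterministic commissioned-machine database on the 5 MeV grid.

    Energy spreads follow a ~0.6%-of-energy trend; spot sizes shrink with
    energy as real PBS nozzles do; protons per MU grow roughly linearly
    with energy.  Values are synthetic machine configuration, not a
    published beam model.
    """
    records = []
    for e in build_energy_grid(100.0, 226.7, 5.0):
        spread = 0.006 * e
        sigma_nozzle = spot_sigma_iso_cm * (150.0 / e) ** 0.5
        a0 = divergence_rad**2
        a2 = sigma_nozzle**2
        a1 = -0.3 * np.sqrt(a0 * a2)  # slightly convergent beam
        records.append(
            EnergyLayerRecord(
                mean_energy=e,
                energy_spread=spread,
                fe_moments_x=(a0, a1, a2),
                fe_moments_y=(1.1 * a0, a1, 0.9 * a2),
                protons_per_mu=1.0e8 * (e / 100.0),
            )
        )
    return MachineDatabase(records)


def make_synthetic_pdd(
    energy: float,
    spread: float,
    noise_percent: float = 0.0,
    seed: int = 0,
    depth_step: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic commissioning depth-dose curve (depth [cm], dose [a.u.]).

    Analytical Bragg model on a fine grid with multiplicative Gaussian
    noise; stands in for Bragg-peak-chamber measurements.
    """
    if noise_percent < 0:
        raise ValueError("noise must be non-negative")
    from .stopping import csda_range

    r = float(csda_range(WATER, energy))
    depth = np.arange(depth_step, r + 3.0, depth_step)
    dose = bragg.bragg_curve(depth, energy, spread)
    if noise_percent > 0:
        rng = np.random.default_rng(seed)
        dose = dose * (
            1.0 + noise_percent / 100.0 * rng.standard_normal(dose.size)
        )
    return depth, dose


# ---------------------------------------------------------------- phantoms


def make_water_tank(
    size_cm: float = 50.0, spacing: float = 0.2,
    shape: Optional[tuple[int, int, int]] = None,
    entry_face_to_iso_cm: float = 3.0,
) -> VoxelPhantom:
    """Water tank phantom; the beam (gantry 0, -y) enters the +y face.

    The isocenter sits ``entry_face_to_iso_cm`` below the entry face,
    matching the MU-calibration reference geometry.
    """
    if shape is None:
        n = int(round(size_cm / spacing))
        shape = (n, n, n)
    materials = build_tissue_table() + [WATER]
    water_id = len(materials) - 1
    ids = np.full(shape, water_id, dtype=np.int16)
    rho = np.ones(shape)
    # voxel (0,0,0) center position: grid centered on x/z, +y face at
    # entry_face_to_iso_cm above the isocenter
    origin = np.array([
        -spacing * (shape[0] - 1) / 2.0,
        entry_face_to_iso_cm - spacing / 2.0 - spacing * (shape[1] - 1),
        -spacing * (shape[2] - 1) / 2.0,
    ])
    return VoxelPhantom(
        spacing=spacing, origin=origin, material_id=ids, density=rho,
        roi_masks={}, materials=materials,
    )


def make_child_phantom(spacing: float = 0.5) -> VoxelPhantom:
    """Simplified 5-year-old head-torso phantom with 6 tissue types.

    Spherical head (brain + skull shell), neck, elliptic-cylinder torso
    with two lungs and a spine, in air.  The cerebellar target sits at
    the isocenter (origin); ROI masks cover the target, the whole body
    and the 28 standard organ positions.
    """
    x = np.arange(-10.0, 10.0 + spacing / 2, spacing)
    y = np.arange(-8.0, 11.0 + spacing / 2, spacing)
    z = np.arange(-52.0, 13.0 + spacing / 2, spacing)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    materials = build_tissue_table()
    # tissue ids in the standard table (spine uses a lighter bone bin)
    AIR_ID, LUNG_ID, SOFT_ID, BONE_ID, SPINE_ID = 0, 1, 6, 17, 13
    BRAIN_ID = 5

    ids = np.zeros(X.shape, dtype=np.int16)
    rho = np.full(X.shape, 0.00121)

    head_c = np.array([0.0, 3.0, 3.0])
    r_head = np.sqrt((X - head_c[0]) ** 2 + (Y - head_c[1]) ** 2
                     + (Z - head_c[2]) ** 2)
    skull = (r_head <= 8.5) & (r_head > 7.8)
    brain = r_head <= 7.8
    neck = (np.sqrt(X**2 + (Y - 2.0) ** 2) <= 4.0) & (Z < -4.0) & (Z >= -10.0)
    torso = (((X / 8.0) ** 2 + ((Y - 1.5) / 6.5) ** 2) <= 1.0) \
        & (Z < -10.0) & (Z >= -36.0)
    lung_l = (((X + 4.5) / 3.0) ** 2 + (Y / 2.5) ** 2
              + ((Z + 16.0) / 6.0) ** 2) <= 1.0
    lung_r = (((X - 4.5) / 3.0) ** 2 + (Y / 2.5) ** 2
              + ((Z + 16.0) / 6.0) ** 2) <= 1.0
    spine = (np.sqrt(X**2 + (Y + 4.0) ** 2) <= 1.5) & (Z < -10.0) \
        & (Z >= -36.0)

    for sel, mid, dens in (
        (torso, SOFT_ID, 1.0),
        (neck, SOFT_ID, 1.0),
        (skull, BONE_ID, 1.45),
        (brain, BRAIN_ID, 1.04),
        ((lung_l | lung_r) & torso, LUNG_ID, 0.26),
        (spine & torso, SPINE_ID, 1.35),
    ):
        ids[sel] = mid
        rho[sel] = dens

    origin = np.array([x[0], y[0], z[0]])
    masks: Dict[str, np.ndarray] = {}
    masks["body"] = ids != AIR_ID
    target_r = np.sqrt(X**2 + (Y + 0.0) ** 2 + Z**2)
    masks["target"] = target_r <= 2.0  # cerebellar PTV at the isocenter
    for organ, c in ORGAN_CENTERS.items():
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        m = d2 <= max(1.0, spacing) ** 2
        if not m.any():  # always keep at least the nearest voxel
            m = d2 <= d2.min() + 1e-9
        masks[organ] = m
    return VoxelPhantom(
        spacing=spacing, origin=origin, material_id=ids, density=rho,
        roi_masks=masks, materials=materials,
    )


# ------------------------------------------------------------------- plans


def make_single_spot_plan(energy: float = 150.0, mu: float = 100.0
                          ) -> TreatmentPlan:
    layer = EnergyLayer(energy, [SpotSpec((0.0, 0.0), mu)])
    f = FieldSpec(gantry_angle=0.0, table_angle=0.0, layers=[layer],
                  range_shifter=None, name="single")
    return TreatmentPlan([f], name="single_spot")


def make_brain_plan(
    energies: tuple[float, ...] = (100.0, 115.0, 130.0, 145.0, 165.0),
    spots_per_side: int = 3,
    spot_spacing: float = 0.6,
    mu_per_spot: float = 10.0,
) -> TreatmentPlan:
    """Three-field PBS brain plan behind a 4.44 cm lucite range shifter.

    Two ipsilateral oblique fields and one contralateral oblique field,
    energy layers spanning 100-165 MeV, square spot grids per layer.
    """
    half = (spots_per_side - 1) / 2.0
    offs = (np.arange(spots_per_side) - half) * spot_spacing
    fields = []
    for name, gantry in (("ipsi_1", 45.0), ("ipsi_2", 100.0),
                         ("contra", 290.0)):
        layers = []
        for li, e in enumerate(energies):
            spots = [
                SpotSpec((float(ox), float(oy)),
                         mu_per_spot * (1.0 + 0.2 * ((ox + oy) > 0)),
                         layer_index=li)
                for ox in offs
                for oy in offs
            ]
            layers.append(EnergyLayer(e, spots))
        fields.append(
            FieldSpec(gantry_angle=gantry, table_angle=0.0, layers=layers,
                      range_shifter=DEFAULT_RANGE_SHIFTER, name=name)
        )
    return TreatmentPlan(fields, prescribed_dose_gy_rbe=50.4,
                         name="brain3field")


# ------------------------------------------------------- full study cases


def _grid_value(
    grid: np.ndarray, ph: VoxelPhantom, pos: np.ndarray,
    radius_cm: float = 1.5,
) -> float:
    """Mean of a grid over a small ball (detector-insert averaging)."""
    pos = np.asarray(pos, dtype=float)
    idx = np.round((pos - ph.origin) / ph.spacing).astype(int)
    r_vox = max(int(np.ceil(radius_cm / ph.spacing)), 0)
    lo = np.maximum(idx - r_vox, 0)
    hi = np.minimum(idx + r_vox + 1, np.array(grid.shape))
    if np.any(lo >= hi):
        idx = np.clip(idx, 0, np.array(grid.shape) - 1)
        return float(grid[tuple(idx)])
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ax = [ph.origin[a] + ph.spacing * np.arange(lo[a], hi[a]) - pos[a]
          for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    ball = X**2 + Y**2 + Z**2 <= radius_cm**2
    if not ball.any():
        idx = np.clip(idx, 0, np.array(grid.shape) - 1)
        return float(grid[tuple(idx)])
    return float(sub[ball].mean())


def make_synthetic_case(
    spec: FixtureSpec,
    machine: Optional[MachineDatabase] = None,
    source: Optional[SecondarySourceModel] = None,
) -> tuple[TreatmentPlan, VoxelPhantom, pd.DataFrame, ComponentDoseMaps]:
    """Generate (plan, phantom, detector readings, dose maps) for a preset.

    The detector readings are produced from the engine's own dose maps by
    inverting the evaluation chains (MTS-7: divide by D_W/K_air; MCP pair:
    thermal H back through the thermal coefficient; BD-PND: multiply by
    the bubble sensitivity) and adding budget-consistent noise, so that
    detector evaluation recovers the simulated truth within the stated
    uncertainties.
    """
    if spec.phantom_preset == "water_tank":
        ph = make_water_tank(spec.tank_size_cm, spec.spacing_cm)
    elif spec.phantom_preset == "child_head_torso":
        ph = make_child_phantom(spec.spacing_cm)
    else:
        raise ValueError(f"unknown phantom preset {spec.phantom_preset!r}")
    if spec.plan_preset == "single_spot":
        plan = make_single_spot_plan()
    elif spec.plan_preset == "brain3field":
        plan = make_brain_plan()
    else:
        raise ValueError(f"unknown plan preset {spec.plan_preset!r}")
    machine = machine or make_machine_database()

    cfg = TransportConfig(histories=spec.histories, seed=spec.seed)
    maps = run_transport(plan, machine, ph, cfg, source=source)

    target_mask = ph.roi_masks.get("target")
    if target_mask is None or not target_mask.any():
        raise ValueError("phantom preset lacks a target ROI")
    d_phys = (
        maps.dose_primary_proton + maps.dose_secondary_proton
        + maps.dose_gamma
    )
    d_target = float(d_phys[target_mask].mean())  # Gy per proton

    consts = ConversionConstants()
    rng = np.random.default_rng(spec.seed + 1)
    tld_target = spec.tld_target_dose_gy_rbe / 1.1  # physical Gy
    bd_target = spec.bd_target_dose_gy_rbe / 1.1

    budget_pct = np.sqrt(
        DEFAULT_BUDGET_COMPONENTS["dosimeter_repro"] ** 2
        + DEFAULT_BUDGET_COMPONENTS["batch_repro"] ** 2
        + DEFAULT_BUDGET_COMPONENTS["co60_calibration"] ** 2
    )

    rows = []
    for dist in DETECTOR_DISTANCES_CM:
        pos = np.array([0.0, 0.0, -dist])
        pg = _grid_value(d_phys, ph, pos) / d_target * 1e6  # uGy/Gy
        gam = _grid_value(maps.dose_gamma, ph, pos) / d_target * 1e6
        h_th = _grid_value(maps.neutron_H_thermal, ph, pos) / d_target * 1e6
        noise = (
            1.0 + budget_pct / 100.0 * rng.standard_normal()
            if spec.noise else 1.0
        )
        # MTS-7: proton+gamma dose, inverted through D_W/K_air
        kair = pg / consts.dw_over_kair * tld_target * noise
        rows.append(("MTS-7", *pos, dist, max(kair, 0.0), tld_target))
        # MCP pair: MCP-7 sees the gamma dose, MCP-6 adds thermal capture
        kair7 = gam / consts.dw_over_kair * tld_target
        dkair = h_th / consts.thermal_coeff * tld_target
        n7 = 1.0 + 0.05 * rng.standard_normal() if spec.noise else 1.0
        n6 = 1.0 + 0.05 * rng.standard_normal() if spec.noise else 1.0
        rows.append(("MCP-7", *pos, dist, max(kair7 * n7, 0.0), tld_target))
        rows.append(
            ("MCP-6", *pos, dist, max((kair7 + dkair) * n6, 0.0), tld_target)
        )
    for dist in BD_DISTANCES_CM:
        pos = np.array([0.0, 0.0, -dist])
        h_fast = (
            _grid_value(maps.neutron_H, ph, pos)
            - _grid_value(maps.neutron_H_thermal, ph, pos)
        ) / d_target * 1e6  # uSv/Gy
        mean_bubbles = max(h_fast * bd_target * spec.bubble_sensitivity, 0.0)
        count = (
            int(rng.poisson(mean_bubbles)) if spec.noise
            else int(round(mean_bubbles))
        )
        rows.append(("BD-PND", *pos, dist, count, bd_target))

    readings = pd.DataFrame(rows, columns=READINGS_COLUMNS)
    return plan, ph, readings, maps
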