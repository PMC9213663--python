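"""Voxel phantom and Schneider-style CT calibration.

CT Hounsfield units are converted to a fixed table of 25 stoichiometric
tissues plus air by a piecewise-linear lookup: one lung bin, eight soft
tissue bins interpolating adipose -> muscle composition, and sixteen bone
bins interpolating red marrow -> cortical bone.  Mass density follows a
piecewise-linear HU -> density ramp with per-structure overrides applied
after the lookup, mirroring the planning practice of overwriting phantom
slab densities with datasheet values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Dict

import numpy as np
from scipy import ndimage

from .stopping import AIR, MaterialSpec, mass_stopping_power, WATER

HU_MIN = -1024.0
HU_MAX = 3000.0

# Base compositions (mass fractions) used to build the tissue table.
_LUNG = {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "P": 0.002,
         "K": 0.002, "S": 0.003, "Na": 0.002, "Cl": 0.003}
_ADIPOSE = {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "S": 0.001,
            "Na": 0.001, "Cl": 0.001}
_MUSCLE = {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710, "P": 0.002,
           "K": 0.004, "S": 0.003, "Na": 0.001, "Cl": 0.001}
_MARROW = {"H": 0.115, "C": 0.644, "N": 0.007, "O": 0.231, "S": 0.002,
           "Na": 0.001}
_CORTICAL = {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Mg": 0.002,
             "P": 0.103, "S": 0.003, "Ca": 0.226}


def _mix(a: Dict[str, float], b: Dict[str, float], t: float) -> Dict[str, float]:
    els = sorted(set(a) | set(b))
    w = {el: (1 - t) * a.get(el, 0.0) + t * b.get(el, 0.0) for el in els}
    s = sum(w.values())
    return {el: v / s for el, v in w.items()}


def _norm(a: Dict[str, float]) -> Dict[str, float]:
    s = sum(a.values())
    return {el: v / s for el, v in a.items()}


def _density_from_hu(hu: np.ndarray) -> np.ndarray:
    """Piecewise-linear HU -> mass density [g/cm^3]."""
    hu = np.asarray(hu, dtype=float)
    rho = np.empty_like(hu)
    lo = hu < -950.0
    soft = (~lo) & (hu <= 100.0)
    bone = hu > 100.0
    rho[lo] = 0.00121
    rho[soft] = np.maximum(1.0 + hu[soft] / 1000.0, 0.05)
    rho[bone] = np.minimum(1.1 + (hu[bone] - 100.0) * 5.65e-4, 2.8)
    return rho


def build_tissue_table() -> list[MaterialSpec]:
    """The fixed 26-entry material table: air plus 25 tissues.

    Index 0 is air; 1 lung; 2-9 soft tissues; 10-25 bone.  I-values ramp
    from 75 eV for soft tissue to 106 eV for the densest bone bin.
    """
    table = [AIR]
    table.append(MaterialSpec("lung", _norm(_LUNG), 0.26, 75.3))
    for i in range(8):
        t = i / 7.0
        table.append(
            MaterialSpec(
                f"soft_{i+1}", _mix(_ADIPOSE, _MUSCLE, t), 0.95 + 0.0143 * i,
                63.0 + 12.0 * t,
            )
        )
    for i in range(16):
        t = i / 15.0
        table.append(
            MaterialSpec(
                f"bone_{i+1}", _mix(_MARROW, _CORTICAL, t), 1.12 + 0.053 * i,
                70.0 + 36.0 * t,
            )
        )
    return table


#: HU bin edges: material id i covers [edges[i], edges[i+1]).
def tissue_bin_edges() -> np.ndarray:
    soft_edges = np.linspace(-120.0, 120.0, 9)
    bone_edges = np.linspace(120.0, HU_MAX, 17)[1:]
    return np.concatenate(
        [[HU_MIN, -950.0], soft_edges, bone_edges]
    )


def material_id_from_hu(hu: np.ndarray) -> np.ndarray:
    """Total piecewise lookup HU -> material id over [-1024, 3000]."""
    hu = np.asarray(hu, dtype=float)
    if np.any(hu < HU_MIN - 1e-9) or np.any(hu > HU_MAX + 1e-9):
        raise ValueError(f"HU outside lookup domain [{HU_MIN}, {HU_MAX}]")
    edges = tissue_bin_edges()
    ids = np.searchsorted(edges, hu, side="right") - 1
    return np.clip(ids, 0, len(edges) - 2).astype(np.int16)


@dataclass
class VoxelPhantom:
    """Isotropic voxel grid of material ids and densities, with ROI masks.

    ``origin`` is the position of the voxel center (0, 0, 0) in the
    patient coordinate system (cm, isocenter at the origin).
    """

    spacing: float  # cm, isotropic
    origin: np.ndarray  # (3,) cm
    material_id: np.ndarray  # (nx, ny, nz) int16
    density: np.ndarray  # g/cm^3
    roi_masks: Dict[str, np.ndarray] = field(default_factory=dict)
    materials: list[MaterialSpec] = field(default_factory=build_tissue_table)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.material_id.shape != self.density.shape:
            raise ValueError("material and density grids must match")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        for name, mask in self.roi_masks.items():
            if mask.shape != self.material_id.shape:
                raise ValueError(f"ROI mask {name!r} does not match grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_id.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def relative_stopping_power(self) -> np.ndarray:
        """Per-voxel stopping power relative to water (at 100 MeV).

        The mass-stopping ratio varies by <1% over therapeutic energies,
        so a single reference energy is used; density carries the rest.
        """
        s_w = float(mass_stopping_power(WATER, 100.0))
        ratios = np.array(
            [float(mass_stopping_power(m, 100.0)) / s_w for m in self.materials]
        )
        return ratios[self.material_id] * self.density

    def hydrogen_fraction(self) -> np.ndarray:
        fr = np.array([m.hydrogen_fraction for m in self.materials])
        return fr[self.material_id]

    def in_body(self) -> np.ndarray:
        """Voxels occupied by tissue (anything but air)."""
        return self.material_id > 0


def load_geometry(
    hu: np.ndarray,
    spacing: float,
    origin: np.ndarray | None = None,
    structures: Dict[str, np.ndarray] | None = None,
    density_overrides: Dict[str, float] | None = None,
    grid_spacing: float = 0.2,
) -> VoxelPhantom:
    """Build a voxel phantom from a CT HU grid.

    HU values are binned into the 25-tissue table, densities follow the
    piecewise-linear ramp, per-structure density overrides are applied
    after the lookup, and the grid is resampled to ``grid_spacing`` cm
    (nearest neighbour for ids/masks, linear for density).
    """
    hu = np.asarray(hu, dtype=float)
    ids = material_id_from_hu(hu)
    rho = _density_from_hu(hu)
    masks = {k: np.asarray(v, dtype=bool) for k, v in (structures or {}).items()}
    for name, value in (density_overrides or {}).items():
        if name not in masks:
            raise ValueError(f"density override for unknown structure {name!r}")
        rho = np.where(masks[name], value, rho)

    if origin is None:
        origin = -spacing * (np.array(hu.shape) - 1) / 2.0
    origin = np.asarray(origin, dtype=float)

    if abs(grid_spacing - spacing) > 1e-9:
        zoom = spacing / grid_spacing
        rho = ndimage.zoom(rho, zoom, order=1, mode="nearest")
        ids = ndimage.zoom(ids, zoom, order=0, mode="nearest")
        masks = {
            k: ndimage.zoom(v, zoom, order=0, mode="nearest") for k, v in masks.items()
        }
        # keep the voxel-center position of index (0,0,0)
        origin = origin.copy()
        spacing = grid_spacing

    return VoxelPhantom(
        spacing=spacing,
        origin=origin,
        material_id=ids,
        density=rho.astype(np.float64),
        roi_masks=masks,
    )


def save_phantom(ph: VoxelPhantom, path) -> None:
    """Persist a voxel phantom (grids, masks, material table) to HDF5."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["spacing_cm"] = ph.spacing
        f.attrs["origin_cm"] = ph.origin
        f.create_dataset("material_id", data=ph.material_id,
                         compression="gzip")
        f.create_dataset("density", data=ph.density, compression="gzip")
        g = f.create_group("roi_masks")
        for name, mask in ph.roi_masks.items():
            g.create_dataset(name, data=mask.astype(np.uint8),
                             compression="gzip")
        mats = [
            {
                "name": m.name,
                "mass_fractions": m.mass_fractions,
                "density": m.density,
                "mean_excitation_energy": m.mean_excitation_energy,
            }
            for m in ph.materials
        ]
        f.attrs["materials_json"] = json.dumps(mats)


def load_phantom(path) -> VoxelPhantom:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        mats = [
            MaterialSpec(m["name"], m["mass_fractions"], m["density"],
                         m["mean_excitation_energy"])
            for m in json.loads(f.attrs["materials_json"])
        ]
        return VoxelPhantom(
            spacing=float(f.attrs["spacing_cm"]),
            origin=np.asarray(f.attrs["origin_cm"]),
            material_id=f["material_id"][...],
            density=f["density"][...],
            roi_masks={k: v[...].astype(bool)
                       for k, v in f["roi_masks"].items()},
            materials=mats,
        )
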