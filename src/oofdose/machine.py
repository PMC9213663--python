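"""Machine beam-parameter database and pencil-beam optics.

A commissioned PBS machine is described by an ordered list of per-energy
records: mean kinetic energy and Gaussian spread of the layer, the
Fermi-Eyges phase-space moments per transverse axis at the nozzle-exit
plane, and the number of protons delivered per monitor unit.  Queries
between grid energies are linearly interpolated.

Moment convention: (A0, A1, A2) = (<theta^2> [rad^2], <x theta> [cm rad],
<x^2> [cm^2]) at the nozzle exit, z measured downstream from that plane,
so the vacuum envelope is sigma^2(z) = A2 + 2 A1 z + A0 z^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np

ENERGY_MIN = 100.0
ENERGY_MAX = 226.7

#: Default scanning-magnet focus distances upstream of the isocenter [cm],
#: per transverse axis (x, y).  Machine configuration, deliberately unequal.
DEFAULT_FOCI = (220.0, 180.0)
#: Nozzle-exit plane, upstream of the isocenter [cm].
NOZZLE_EXIT = 50.0


def build_energy_grid(e_min: float, e_max: float, step: float) -> list[float]:
    """Commissioning energy grid: e_min upward in fixed steps, capped at e_max.

    When the stepped sequence does not land on e_max it is appended, so
    (100.0, 226.7, 5) yields the 27-point grid 100, 105, ..., 225, 226.7.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if e_min > e_max:
        raise ValueError("e_min must not exceed e_max")
    n = int(np.floor((e_max - e_min) / step + 1e-9))
    grid = [e_min + i * step for i in range(n + 1)]
    if abs(grid[-1] - e_max) > 1e-9:
        grid.append(e_max)
    return grid


@dataclass(frozen=True)
class EnergyLayerRecord:
    """One commissioned energy layer of the machine database."""

    mean_energy: float  # MeV
    energy_spread: float  # MeV, Gaussian sigma
    fe_moments_x: tuple[float, float, float]  # (A0 rad^2, A1 cm rad, A2 cm^2)
    fe_moments_y: tuple[float, float, float]
    protons_per_mu: float

    def __post_init__(self) -> None:
        if not (ENERGY_MIN - 1e-9 <= self.mean_energy <= ENERGY_MAX + 1e-9):
            raise ValueError(
                f"mean energy {self.mean_energy} outside "
                f"[{ENERGY_MIN}, {ENERGY_MAX}] MeV"
            )
        if self.energy_spread < 0:
            raise ValueError("energy spread must be >= 0")
        if self.protons_per_mu <= 0:
            raise ValueError("protons per MU must be positive")
        for a0, a1, a2 in (self.fe_moments_x, self.fe_moments_y):
            if a0 < 0 or a2 < 0 or a1 * a1 > a0 * a2 + 1e-15:
                raise ValueError(
                    "Fermi-Eyges moments must form a positive-semidefinite "
                    "covariance (A0 >= 0, A2 >= 0, A1^2 <= A0*A2)"
                )


def lateral_spot_sigma(
    record: EnergyLayerRecord, z: float | np.ndarray, axis: str = "x"
) -> np.ndarray:
    """Vacuum beam envelope sigma(z) [cm] downstream of the nozzle exit."""
    a0, a1, a2 = record.fe_moments_x if axis == "x" else record.fe_moments_y
    z = np.asarray(z, dtype=float)
    var = a2 + 2.0 * a1 * z + a0 * z * z
    if np.any(var < -1e-12):
        raise ValueError("phase-space covariance not positive-semidefinite")
    return np.sqrt(np.maximum(var, 0.0))


@dataclass(frozen=True)
class SpotSpec:
    """A scan spot as specified by the plan, at the isocenter plane."""

    isocenter_xy: tuple[float, float]  # cm
    mu: float
    layer_index: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("spot MU must be positive")


@dataclass(frozen=True)
class NozzleSpot:
    """A spot back-projected to the nozzle-exit plane."""

    exit_position: tuple[float, float]  # cm, at the nozzle-exit plane
    direction: tuple[float, float, float]  # unit vector, +z downstream

    def __post_init__(self) -> None:
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-12:
            raise ValueError("direction must be normalized")


def back_project_spot(
    spot: SpotSpec,
    foci: tuple[float, float] = DEFAULT_FOCI,
    exit_plane_z: float = NOZZLE_EXIT,
) -> NozzleSpot:
    """Trace a spot from the scanning-magnet foci back to the nozzle exit.

    Each transverse axis is deflected at its own focus (distance upstream
    of the isocenter); straight-line vacuum optics gives the exit-plane
    intercept by similar triangles and the direction as the normalized
    focus-to-isocenter ray.
    """
    fx, fy = foci
    if fx <= exit_plane_z or fy <= exit_plane_z:
        raise ValueError("foci must lie upstream of the nozzle-exit plane")
    xi, yi = spot.isocenter_xy
    x_exit = xi * (fx - exit_plane_z) / fx
    y_exit = yi * (fy - exit_plane_z) / fy
    # direction: per-axis slope towards the isocenter over the drift
    dx = xi / fx
    dy = yi / fy
    v = np.array([dx, dy, 1.0])
    v /= np.linalg.norm(v)
    return NozzleSpot((x_exit, y_exit), tuple(v))


def forward_project(nozzle: NozzleSpot, exit_plane_z: float = NOZZLE_EXIT
                    ) -> tuple[float, float]:
    """Project a nozzle spot forward to the isocenter plane (z=0)."""
    x0, y0 = nozzle.exit_position
    dx, dy, dz = nozzle.direction
    t = exit_plane_z / dz
    return (x0 + dx * t, y0 + dy * t)


def calibrate_protons_per_mu(
    dose_per_proton_at_tally: float, prescribed_dose_per_mu: float
) -> float:
    """MU/ion calibration: protons per MU from the reference-field tally.

    ``dose_per_proton_at_tally`` is the dose scored per source proton in
    the reference geometry (symmetric square grid of 1681 spots at 0.25 cm
    spacing, cylindrical tally 1 cm diameter x 0.5 cm at the isocenter at
    3 cm depth in a water tank); ``prescribed_dose_per_mu`` is the dose
    meter reading per MU in the same geometry.
    """
    if dose_per_proton_at_tally <= 0 or prescribed_dose_per_mu <= 0:
        raise ValueError("calibration inputs must be positive")
    return prescribed_dose_per_mu / dose_per_proton_at_tally


#: Spot layout of the MU/ion reference field: 41 x 41 = 1681 spots, 0.25 cm.
REFERENCE_FIELD_SPOTS = 1681
REFERENCE_FIELD_SPACING = 0.25


def reference_field_positions() -> np.ndarray:
    """(1681, 2) spot positions of the symmetric square reference field."""
    n = int(round(np.sqrt(REFERENCE_FIELD_SPOTS)))
    half = (n - 1) / 2.0
    axis = (np.arange(n) - half) * REFERENCE_FIELD_SPACING
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class MachineDatabase:
    """Ordered per-energy machine records with linear interpolation."""

    records: list[EnergyLayerRecord]
    foci: tuple[float, float] = DEFAULT_FOCI

    def __post_init__(self) -> None:
        e = [r.mean_energy for r in self.records]
        if len(e) < 1:
            raise ValueError("machine database must contain records")
        if np.any(np.diff(e) <= 0):
            raise ValueError("records must be strictly increasing in energy")

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.mean_energy for r in self.records])

    def span(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def interpolate(self, energy: float) -> EnergyLayerRecord:
        """Record at an arbitrary energy, linear between grid nodes."""
        e = self.energies
        if not (e[0] - 1e-9 <= energy <= e[-1] + 1e-9):
            raise ValueError(
                f"energy {energy} MeV outside database span {self.span()}"
            )
        energy = float(np.clip(energy, e[0], e[-1]))
        j = int(np.searchsorted(e, energy))
        if j < e.size and abs(e[j] - energy) < 1e-12:
            return self.records[j]
        if j > 0 and abs(e[j - 1] - energy) < 1e-12:
            return self.records[j - 1]
        lo, hi = self.records[j - 1], self.records[j]
        t = (energy - lo.mean_energy) / (hi.mean_energy - lo.mean_energy)

        def lerp(a: float, b: float) -> float:
            return (1.0 - t) * a + t * b

        return EnergyLayerRecord(
            mean_energy=energy,
            energy_spread=lerp(lo.energy_spread, hi.energy_spread),
            fe_moments_x=tuple(
                lerp(a, b) for a, b in zip(lo.fe_moments_x, hi.fe_moments_x)
            ),
            fe_moments_y=tuple(
                lerp(a, b) for a, b in zip(lo.fe_moments_y, hi.fe_moments_y)
            ),
            protons_per_mu=lerp(lo.protons_per_mu, hi.protons_per_mu),
        )


_DB_KEYS = [
    "mean_energy_MeV",
    "energy_spread_MeV",
    "A0_x",
    "A1_x",
    "A2_x",
    "A0_y",
    "A1_y",
    "A2_y",
    "protons_per_MU",
]


def save_machine_database(db: MachineDatabase, path: str | Path) -> None:
    """Write the database as delimited text, one record per energy."""
    lines = ["# foci_cm %.6g %.6g" % db.foci, "\t".join(_DB_KEYS)]
    for r in db.records:
        vals = [
            r.mean_energy,
            r.energy_spread,
            *r.fe_moments_x,
            *r.fe_moments_y,
            r.protons_per_mu,
        ]
        lines.append("\t".join("%.10g" % v for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def load_machine_database(path: str | Path) -> MachineDatabase:
    """Read a machine-parameter file written by :func:`save_machine_database`."""
    foci = DEFAULT_FOCI
    records: list[EnergyLayerRecord] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "foci_cm":
                foci = (float(parts[1]), float(parts[2]))
            continue
        if header is None:
            header = line.split("\t")
            if header != _DB_KEYS:
                raise ValueError(
                    f"unexpected machine-file header {header!r}; "
                    f"expected {_DB_KEYS!r}"
                )
            continue
        v = [float(x) for x in line.split("\t")]
        records.append(
            EnergyLayerRecord(
                mean_energy=v[0],
                energy_spread=v[1],
                fe_moments_x=(v[2], v[3], v[4]),
                fe_moments_y=(v[5], v[6], v[7]),
                protons_per_mu=v[8],
            )
        )
    return MachineDatabase(records, foci=foci)
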