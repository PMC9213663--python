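"""Proton stopping power, CSDA ranges, and water-equivalent thickness.

Electronic stopping powers are evaluated with the Bethe formula (no shell
or density-effect corrections, adequate above ~1 MeV) using each material's
elemental composition, mean excitation energy I, and density.  CSDA ranges
are obtained by numerical integration of 1/S and cached per material as
cubic splines, which also provide the range -> energy inverse used by the
transport engine and the air-path mean-energy correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

# Physical constants (MeV unless noted)
ELECTRON_MASS = 0.51099895
PROTON_MASS = 938.27208816
K_BETHE = 0.307075  # MeV cm^2 / mol

#: Z and A of the elements needed for tissue/phantom materials.
ELEMENTS: Dict[str, tuple[float, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
}


@dataclass(frozen=True)
class MaterialSpec:
    """Stoichiometric material: mass fractions, density, I-value.

    ``mean_excitation_energy`` is in eV and, when given, overrides the
    Bragg-additivity estimate from the elemental composition.
    """

    name: str
    mass_fractions: Dict[str, float]
    density: float  # g/cm^3
    mean_excitation_energy: float  # eV

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-4:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")
        unknown = set(self.mass_fractions) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements: {sorted(unknown)}")

    @property
    def z_over_a(self) -> float:
        """Mean Z/A in mol/g (Bragg additivity over mass fractions)."""
        return sum(
            w * ELEMENTS[el][0] / ELEMENTS[el][1]
            for el, w in self.mass_fractions.items()
        )

    @property
    def hydrogen_fraction(self) -> float:
        return self.mass_fractions.get("H", 0.0)


# Reference materials.  Water uses the PSTAR convention I = 75 eV; the
# Geant4-matching value of 78 eV is kept as a separate constant for users
# reproducing condensed-history depth doses tuned to that convention.
WATER_I_EV = 75.0
WATER_I_EV_GEANT4 = 78.0

WATER = MaterialSpec("water", {"H": 0.111894, "O": 0.888106}, 1.0, WATER_I_EV)

#: Lucite / PMMA range-shifter material (PSTAR composition, I = 74 eV).
LUCITE = MaterialSpec(
    "lucite", {"H": 0.0805, "C": 0.5998, "O": 0.3196}, 1.19, 74.0
)

AIR = MaterialSpec(
    "air",
    {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827},
    1.20479e-3,
    85.7,
)


def mass_stopping_power(
    material: MaterialSpec, energy: float | np.ndarray
) -> np.ndarray:
    """Electronic mass stopping power S/rho for protons [MeV cm^2/g].

    Bethe formula with the exact maximum energy transfer T_max; valid for
    kinetic energies roughly 1-250 MeV.
    """
    t = np.asarray(energy, dtype=float)
    if np.any(t <= 0):
        raise ValueError("kinetic energy must be positive")
    gamma = 1.0 + t / PROTON_MASS
    beta2 = 1.0 - 1.0 / gamma**2
    bg2 = beta2 * gamma**2
    me_over_m = ELECTRON_MASS / PROTON_MASS
    tmax = (
        2.0
        * ELECTRON_MASS
        * bg2
        / (1.0 + 2.0 * gamma * me_over_m + me_over_m**2)
    )
    i_mev = material.mean_excitation_energy * 1e-6
    arg = 2.0 * ELECTRON_MASS * bg2 * tmax / i_mev**2
    ln_term = 0.5 * np.log(np.maximum(arg, 1.0 + 1e-12)) - beta2
    return K_BETHE * material.z_over_a / beta2 * np.maximum(ln_term, 0.0)


_E_GRID = np.geomspace(0.5, 350.0, 2000)
_range_cache: Dict[str, tuple[CubicSpline, CubicSpline]] = {}


def _range_splines(material: MaterialSpec) -> tuple[CubicSpline, CubicSpline]:
    """(energy -> CSDA range [g/cm^2], range -> energy) spline pair."""
    key = f"{material.name}:{material.z_over_a:.6f}:{material.mean_excitation_energy}"
    if key not in _range_cache:
        s = mass_stopping_power(material, _E_GRID)
        r = cumulative_trapezoid(1.0 / s, _E_GRID, initial=0.0)
        # residual range below the grid floor, linear-S extrapolation
        r += _E_GRID[0] / s[0] * 0.5
        _range_cache[key] = (
            CubicSpline(_E_GRID, r),
            CubicSpline(r, _E_GRID),
        )
    return _range_cache[key]


def csda_range(material: MaterialSpec, energy: float | np.ndarray) -> np.ndarray:
    """CSDA range in g/cm^2 for protons of the given kinetic energy [MeV]."""
    fwd, _ = _range_splines(material)
    return fwd(np.asarray(energy, dtype=float))


def energy_from_range(
    material: MaterialSpec, rng_gcm2: float | np.ndarray
) -> np.ndarray:
    """Inverse of :func:`csda_range`; clips to the tabulated domain."""
    _, inv = _range_splines(material)
    fwd, _ = _range_splines(material)
    lo, hi = fwd(_E_GRID[0]), fwd(_E_GRID[-1])
    return inv(np.clip(np.asarray(rng_gcm2, dtype=float), lo, hi))


def slab_exit_energy(
    material: MaterialSpec, thickness_cm: float, energy: float
) -> float:
    """Residual kinetic energy after traversing a slab, CSDA."""
    if thickness_cm < 0:
        raise ValueError("thickness must be non-negative")
    fwd, _ = _range_splines(material)
    r_in = float(fwd(energy))
    r_out = r_in - thickness_cm * material.density
    if r_out <= 0:
        return 0.0
    return float(energy_from_range(material, r_out))


def compute_wet(
    material: MaterialSpec, thickness_cm: float, energy: float = 150.0
) -> float:
    """Water-equivalent thickness [cm] of a slab at the given beam energy.

    The energy lost through the slab is evaluated by CSDA slowing-down and
    converted to the water path length producing the same loss, i.e. the
    stopping-power ratio averaged over the slowing-down spectrum times the
    density ratio, not the single-energy ratio.
    """
    if thickness_cm < 0:
        raise ValueError("thickness must be non-negative")
    if not (10.0 <= energy <= 250.0):
        raise ValueError("energy outside supported range [10, 250] MeV")
    if thickness_cm == 0:
        return 0.0
    e_out = slab_exit_energy(material, thickness_cm, energy)
    if e_out <= 0:
        raise ValueError("slab thicker than the proton range at this energy")
    r_w = _range_splines(WATER)[0]
    return float(r_w(energy) - r_w(e_out))  # water density = 1 g/cm^3


def air_path_energy_correction(
    track_length_cm: float, energy: float, air: MaterialSpec = AIR
) -> float:
    """Mean-energy increment compensating slowing-down in an air path.

    Returns dE >= 0 such that a proton started at ``energy + dE`` arrives at
    the nominal ``energy`` after ``track_length_cm`` of air.  Uses the CSDA
    range table for air through a logarithmic cubic-spline interpolation.
    """
    if track_length_cm < 0:
        raise ValueError("track length must be non-negative")
    if track_length_cm == 0:
        return 0.0
    spline = _log_csda_spline(air)
    log_e = np.log(energy)
    if not (np.log(_E_GRID[0]) <= log_e <= np.log(_E_GRID[-1])):
        raise ValueError("energy outside the air CSDA table domain")
    r_nominal = np.exp(float(spline(log_e)))
    r_up = r_nominal + track_length_cm * air.density
    # invert the log-log spline by bisection on log-energy
    lo, hi = log_e, np.log(_E_GRID[-1])
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.exp(float(spline(mid))) < r_up:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)) - energy)


_log_cache: Dict[str, CubicSpline] = {}


def _log_csda_spline(material: MaterialSpec) -> CubicSpline:
    """ln(E) -> ln(CSDA range) cubic spline (PSTAR-style table fit)."""
    key = material.name
    if key not in _log_cache:
        nodes = np.geomspace(1.0, 300.0, 60)
        r = csda_range(material, nodes)
        _log_cache[key] = CubicSpline(np.log(nodes), np.log(r))
    return _log_cache[key]


def csda_table_nodes(material: MaterialSpec = AIR) -> tuple[np.ndarray, np.ndarray]:
    """The (energy [MeV], CSDA range [g/cm^2]) nodes behind the spline fit."""
    nodes = np.geomspace(1.0, 300.0, 60)
    return nodes, csda_range(material, nodes)
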