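"""Fluence-to-dose conversion tables and detector/risk constants.

The neutron dose-equivalent conversion follows the mixed-field practice of
factorizing h(E) = k(E) * Q(E): ICRU-tissue kerma factors k(E) [Gy cm^2]
times an effective quality factor Q(E).  The default table below is a
package-built compilation on a logarithmic energy grid: k(E) from hydrogen
elastic recoil plus the 14N(n,p) capture channel at thermal energies, Q(E)
shaped like the standard radiation-protection quality factors (peaking
near 1 MeV, falling towards thermal and relativistic energies).  It is the
default, not a claim of equivalence to any published tabulation, and can
be swapped for a user table wherever a ``ConversionTables`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

#: Air-kerma (Co-60) to dose-to-water conversion for LiF TLD chains.
DW_OVER_KAIR = 1.12
#: Thermal-neutron air-kerma-equivalent to dose-equivalent [mSv/mGy].
THERMAL_COEFF = 1.24e-2
#: Relative (k=1) uncertainty of the thermal coefficient: factor-2 class.
THERMAL_COEFF_REL_U = 1.0

# Default h(E) = k(E) Q(E) nodes, energies in MeV.
_H_NODES_E = np.array(
    [1e-9, 2.5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 5e-1,
     1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 1000.0]
)
_H_NODES_K = np.array(  # Gy cm^2; sub-thermal follows 1/v capture
    [1.35e-12, 2.7e-13, 1.4e-13, 4.5e-14, 1.6e-14, 1.4e-14, 9.5e-14,
     9.3e-13, 6.1e-12, 1.5e-11, 2.1e-11, 2.8e-11, 3.8e-11, 5.0e-11,
     6.0e-11, 6.5e-11, 7.0e-11, 7.5e-11, 8.0e-11]
)
_H_NODES_Q = np.array(
    [2.5, 2.5, 2.5, 2.5, 2.6, 2.7, 3.2, 4.7, 8.0, 14.0,
     13.5, 12.0, 9.5, 8.0, 7.0, 6.0, 5.5, 5.0, 5.0]
)


@dataclass(frozen=True)
class ConversionConstants:
    """Mixed-field TLD chain constants (immutable defaults, overridable)."""

    dw_over_kair: float = DW_OVER_KAIR
    thermal_coeff: float = THERMAL_COEFF  # mSv per mGy air kerma
    thermal_coeff_rel_uncertainty: float = THERMAL_COEFF_REL_U

    def __post_init__(self) -> None:
        if self.dw_over_kair <= 0 or self.thermal_coeff <= 0:
            raise ValueError("conversion constants must be positive")


@dataclass
class ConversionTables:
    """h(E) = k(E) Q(E) on a log-energy grid plus scalar chain constants."""

    energies_mev: np.ndarray = field(default_factory=lambda: _H_NODES_E.copy())
    kerma_gycm2: np.ndarray = field(default_factory=lambda: _H_NODES_K.copy())
    quality: np.ndarray = field(default_factory=lambda: _H_NODES_Q.copy())
    constants: ConversionConstants = field(default_factory=ConversionConstants)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_mev, dtype=float)
        if np.any(np.diff(e) <= 0) or np.any(e <= 0):
            raise ValueError("energy nodes must be positive and increasing")
        if np.any(self.kerma_gycm2 <= 0) or np.any(self.quality <= 0):
            raise ValueError("k(E) and Q(E) must be positive")

    @property
    def h_sv_cm2(self) -> np.ndarray:
        return self.kerma_gycm2 * self.quality

    def _loglog(self, table: np.ndarray, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energies_mev[0], self.energies_mev[-1]
        if np.any(e < lo * (1 - 1e-9)) or np.any(e > hi * (1 + 1e-9)):
            raise ValueError(
                f"energy outside conversion-table support [{lo}, {hi}] MeV"
            )
        return np.exp(
            np.interp(np.log(e), np.log(self.energies_mev), np.log(table))
        )

    def h_of(self, energy) -> np.ndarray:
        """h(E) [Sv cm^2], log-log interpolated between nodes."""
        return self._loglog(self.h_sv_cm2, energy)

    def kerma_of(self, energy) -> np.ndarray:
        """k(E) [Gy cm^2], log-log interpolated between nodes."""
        return self._loglog(self.kerma_gycm2, energy)


def log_energy_bins(
    e_min: float = 1e-9, e_max: float = 1e3, per_decade: int = 10
) -> np.ndarray:
    """Logarithmic neutron-energy bin edges [MeV] (default 1 meV - 1 GeV)."""
    n = int(round(np.log10(e_max / e_min) * per_decade))
    return np.geomspace(e_min, e_max, n + 1)


#: BEIR-VII style lifetime attributable risk for cancer incidence after
#: exposure at age 5, cases per 10^5 persons per 0.1 Gy, by sex.
LAR_TABLE: Dict[str, Dict[str, float]] = {
    "breast": {"female": 914.0},
    "lung": {"female": 608.0, "male": 261.0},
    "thyroid": {"female": 419.0, "male": 76.0},
}
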