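"""Mixed-field detector calibration chains and uncertainty budgets.

Implements the passive-dosimetry evaluation used for out-of-field
measurements in scanned proton beams:

* MTS-7 (7LiF:Mg,Ti) thermoluminescent detectors, calibrated in Co-60 air
  kerma, measure the non-neutron (proton + gamma) absorbed dose;
* the MCP-6/MCP-7 (LiF:Mg,Cu,P) pair isolates thermal neutrons through the
  6Li(n,alpha)3H channel: the MCP-7 reading is subtracted from MCP-6 and
  the difference is converted with a thermal air-kerma-to-dose-equivalent
  coefficient;
* BD-PND superheated-emulsion bubble detectors, Cf-252 calibrated, count
  bubbles per unit neutron dose equivalent above ~50 keV.

All results are normalized to the physical target dose: absorbed dose in
uGy/Gy, neutron dose equivalent in uSv/Gy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .conversion import ConversionConstants

#: Relative uncertainty components (k = 1, percent) of the TLD chain.
DEFAULT_BUDGET_COMPONENTS: Dict[str, float] = {
    "dosimeter_repro": 1.8,
    "batch_repro": 1.9,
    "co60_calibration": 2.4,
    "background": 11.0,  # reached only at the farthest positions
    "proton_energy_response": 5.0,
    "photon_energy_response": 1.0,
}


@dataclass
class UncertaintyBudget:
    """Quadrature combination of enabled relative uncertainty components."""

    components: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BUDGET_COMPONENTS)
    )
    enabled: Optional[list[str]] = None  # None -> all

    def combined_percent(self) -> float:
        names = self.enabled if self.enabled is not None else list(self.components)
        vals = np.array([self.components[n] for n in names], dtype=float)
        return float(np.sqrt(np.sum(vals**2)))


@dataclass(frozen=True)
class TLDReading:
    detector_type: str  # MTS-7 | MCP-6 | MCP-7
    kair_signal: float  # uGy, Co-60 air-kerma calibrated
    position: tuple[float, float, float]  # cm
    distance_to_isocenter: float  # cm
    target_dose: float  # Gy, physical

    def __post_init__(self) -> None:
        if self.detector_type not in ("MTS-7", "MCP-6", "MCP-7"):
            raise ValueError(f"unknown TLD type {self.detector_type!r}")
        if self.kair_signal < 0:
            raise ValueError("air-kerma signal must be >= 0")
        if self.target_dose <= 0:
            raise ValueError("target dose must be positive")


@dataclass(frozen=True)
class BubbleReading:
    bubble_count: int
    sensitivity: float  # bubbles per uSv (Cf-252 calibration)
    position: tuple[float, float, float]
    distance_to_isocenter: float
    target_dose: float  # Gy, physical
    rel_uncertainty: float = 0.20  # k = 1

    def __post_init__(self) -> None:
        if self.bubble_count < 0:
            raise ValueError("bubble count must be >= 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.target_dose <= 0:
            raise ValueError("target dose must be positive")


def evaluate_mts7(
    reading: TLDReading,
    budget: UncertaintyBudget | None = None,
    constants: ConversionConstants = ConversionConstants(),
) -> tuple[float, float]:
    """MTS-7 chain: (absorbed dose in water per target dose [uGy/Gy], rel u).

    D_W = K_air x (D_W/K_air); the relative uncertainty is the quadrature
    combination of the enabled budget components (fraction, k = 1).  A zero
    signal returns zero dose with the background component alone (the
    reading is background-dominated).
    """
    if reading.detector_type != "MTS-7":
        raise ValueError("evaluate_mts7 requires an MTS-7 reading")
    budget = budget or UncertaintyBudget()
    dose_w = reading.kair_signal * constants.dw_over_kair
    per_target = dose_w / reading.target_dose
    if reading.kair_signal == 0:
        return 0.0, budget.components.get("background", 11.0) / 100.0
    return per_target, budget.combined_percent() / 100.0


def evaluate_thermal_neutron(
    mcp6: TLDReading,
    mcp7: TLDReading,
    constants: ConversionConstants = ConversionConstants(),
) -> tuple[float, float]:
    """MCP-6 minus MCP-7 chain for thermal neutrons.

    Returns (thermal neutron dose equivalent per target dose [uSv/Gy],
    gamma-equivalent dose per target dose [uGy/Gy]).  The air-kerma
    difference is floored at zero; the thermal conversion coefficient in
    mSv/mGy applies identically in uSv/uGy.
    """
    if mcp6.detector_type != "MCP-6" or mcp7.detector_type != "MCP-7":
        raise ValueError("expected an (MCP-6, MCP-7) pair")
    if mcp6.position != mcp7.position:
        raise ValueError("MCP-6/MCP-7 pair must be co-located")
    if abs(mcp6.target_dose - mcp7.target_dose) > 1e-9 * mcp6.target_dose:
        raise ValueError("MCP-6/MCP-7 pair must share the target dose")
    delta_kair = mcp6.kair_signal - mcp7.kair_signal
    if delta_kair < 0:
        warnings.warn(
            "negative MCP-6 - MCP-7 difference floored at zero", stacklevel=2
        )
        delta_kair = 0.0
    h = delta_kair * constants.thermal_coeff / mcp6.target_dose
    gamma_equiv = delta_kair * constants.dw_over_kair / mcp6.target_dose
    return h, gamma_equiv


def gamma_equivalent_to_h(
    gamma_equivalent_per_target: float,
    constants: ConversionConstants = ConversionConstants(),
) -> float:
    """Convert a gamma-equivalent thermal reading [uGy/Gy] to H [uSv/Gy].

    The gamma-equivalent convention reports the MCP pair difference as
    Co-60 dose to water; dividing by D_W/K_air recovers the air kerma that
    the thermal coefficient applies to.
    """
    delta_kair = gamma_equivalent_per_target / constants.dw_over_kair
    return delta_kair * constants.thermal_coeff


def evaluate_bdpnd(reading: BubbleReading) -> tuple[float, float]:
    """BD-PND chain: (neutron H per target dose [uSv/Gy], rel uncertainty).

    H = counts / sensitivity / target dose; the relative uncertainty is
    the larger of Poisson counting statistics and the 20% (k=1) detector
    uncertainty.  The energy response above 20 MeV is treated as flat.
    """
    h = reading.bubble_count / reading.sensitivity / reading.target_dose
    if reading.bubble_count > 0:
        counting = 1.0 / np.sqrt(reading.bubble_count)
    else:
        counting = 1.0
    return h, float(max(counting, reading.rel_uncertainty))


def derive_quality_factor(
    h_neutron_usv_per_gy: float, d_secondary_proton_ugy_per_gy: float
) -> float:
    """Average quality factor Q = H_neutron / D_secondary-proton.

    Both quantities are per target dose; uSv/Gy over uGy/Gy is already
    dimensionless.  Assumes the secondary-proton absorbed dose is
    dominated by neutron-induced recoil protons.
    """
    if d_secondary_proton_ugy_per_gy <= 0:
        raise ValueError("secondary-proton dose must be positive")
    return h_neutron_usv_per_gy / d_secondary_proton_ugy_per_gy


# ------------------------------------------------------------- table I/O

READINGS_COLUMNS = [
    "detector_type", "x_cm", "y_cm", "z_cm", "distance_cm", "signal",
    "target_dose_Gy",
]


def read_detector_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(READINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detector table missing columns {sorted(missing)}")
    return df


def evaluate_detector_table(
    df: pd.DataFrame,
    budget: UncertaintyBudget | None = None,
    constants: ConversionConstants = ConversionConstants(),
    bubble_sensitivity: float = 2.0,
) -> pd.DataFrame:
    """Evaluate a mixed detector-reading table into doses per target dose.

    MTS-7 rows yield dose_w [uGy/Gy]; co-located MCP-6/MCP-7 pairs yield
    thermal-neutron H [uSv/Gy]; BD-PND rows (signal = bubble count) yield
    neutron H [uSv/Gy].  BD-PND sensitivity is per-detector calibration
    data and is supplied by the caller.
    """
    out = []
    mcp6 = df[df.detector_type == "MCP-6"]
    for _, row in df.iterrows():
        pos = (row.x_cm, row.y_cm, row.z_cm)
        if row.detector_type == "MTS-7":
            r = TLDReading("MTS-7", row.signal, pos, row.distance_cm,
                           row.target_dose_Gy)
            val, unc = evaluate_mts7(r, budget, constants)
            out.append((*pos, row.distance_cm, "proton_gamma_dose_uGy_per_Gy",
                        val, unc))
        elif row.detector_type == "MCP-7":
            mate = mcp6[
                (mcp6.x_cm == row.x_cm) & (mcp6.y_cm == row.y_cm)
                & (mcp6.z_cm == row.z_cm)
            ]
            if len(mate) != 1:
                raise ValueError("MCP-7 without a co-located MCP-6")
            r6 = TLDReading("MCP-6", float(mate.signal.iloc[0]), pos,
                            row.distance_cm, row.target_dose_Gy)
            r7 = TLDReading("MCP-7", row.signal, pos, row.distance_cm,
                            row.target_dose_Gy)
            h, _ = evaluate_thermal_neutron(r6, r7, constants)
            out.append((*pos, row.distance_cm, "thermal_H_uSv_per_Gy", h,
                        constants.thermal_coeff_rel_uncertainty))
        elif row.detector_type == "BD-PND":
            r = BubbleReading(int(row.signal), bubble_sensitivity, pos,
                              row.distance_cm, row.target_dose_Gy)
            h, unc = evaluate_bdpnd(r)
            out.append((*pos, row.distance_cm, "neutron_H_uSv_per_Gy", h, unc))
        elif row.detector_type == "MCP-6":
            continue  # consumed by its MCP-7 mate
        else:
            raise ValueError(f"unknown detector type {row.detector_type!r}")
    return pd.DataFrame(
        out,
        columns=["x_cm", "y_cm", "z_cm", "distance_cm", "quantity", "value",
                 "rel_uncertainty"],
    )
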