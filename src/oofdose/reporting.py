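"""Total dose equivalent, organ doses, course scaling, and risk estimates.

The out-of-field total dose equivalent adds the RBE-weighted direct proton
dose (generic RBE 1.1), the gamma dose (RBE 1), and the neutron dose
equivalent.  Secondary protons born of neutron interactions are already
counted inside the neutron dose equivalent (recoil kerma times Q) and are
therefore not added again.  Organ doses average the per-target-dose map
over each ROI and scale with the physical course dose; lifetime
attributable risk uses linear no-threshold scaling of per-organ LAR
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .transport import ComponentDoseMaps


@dataclass(frozen=True)
class DoseCompositionRule:
    proton_rbe: float = 1.1
    gamma_rbe: float = 1.0

    def __post_init__(self) -> None:
        if self.proton_rbe <= 0 or self.gamma_rbe <= 0:
            raise ValueError("RBE values must be positive")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def physical_target_dose(rbe_weighted_dose: float, rbe: float = 1.1) -> float:
    """Physical dose [Gy] from an RBE-weighted prescription, 1 decimal."""
    if rbe == 0:
        raise ValueError("RBE must be non-zero")
    if rbe_weighted_dose <= 0 or rbe < 0:
        raise ValueError("inputs must be positive")
    return float(np.round(rbe_weighted_dose / rbe, 1))


def compose_total_dose_equivalent(
    maps: ComponentDoseMaps, rule: DoseCompositionRule = DoseCompositionRule()
) -> np.ndarray:
    """Voxelwise H_total = 1.1 D_proton + 1.0 D_gamma + H_neutron [Sv/proton].

    The direct (primary) proton dose carries the generic proton RBE; the
    neutron term is already a dose equivalent.  The secondary-proton map is
    not added separately: out of field it is recoil dose counted inside
    H_neutron (adding it would double-count).
    """
    shapes = {
        maps.dose_primary_proton.shape,
        maps.dose_gamma.shape,
        maps.neutron_H.shape,
    }
    if len(shapes) != 1:
        raise ValueError("component grids are not co-registered")
    return (
        rule.proton_rbe * maps.dose_primary_proton
        + rule.gamma_rbe * maps.dose_gamma
        + maps.neutron_H
    )


def target_dose_per_proton(
    maps: ComponentDoseMaps, target_mask: np.ndarray
) -> float:
    """Mean physical dose in the target ROI per source proton [Gy]."""
    if not target_mask.any():
        raise ValueError("empty target mask")
    d = (
        maps.dose_primary_proton
        + maps.dose_secondary_proton
        + maps.dose_gamma
    )
    return float(d[target_mask].mean())


def compute_organ_doses(
    h_per_target: np.ndarray,
    roi_masks: Dict[str, np.ndarray],
    course_dose_gy: float,
    rel_uncertainty: np.ndarray | None = None,
) -> pd.DataFrame:
    """Organ mean dose equivalents and course totals.

    ``h_per_target`` is the total dose equivalent normalized to the
    physical target dose [uSv/Gy].  Totals are mean x course dose,
    reported in mSv at two significant figures.
    """
    if not roi_masks:
        raise ValueError("no ROI masks supplied")
    rows = []
    for organ, mask in roi_masks.items():
        if not mask.any():
            raise ValueError(f"empty ROI mask {organ!r}")
        mean_h = float(h_per_target[mask].mean())  # uSv/Gy
        total_msv = round_sig(mean_h * course_dose_gy / 1000.0, 2)
        if rel_uncertainty is not None:
            unc = float(np.sqrt(np.mean(rel_uncertainty[mask] ** 2)))
        else:
            unc = np.nan
        rows.append((organ, mean_h, total_msv, unc))
    return pd.DataFrame(
        rows,
        columns=["organ", "H_per_target_uSv_per_Gy", "total_mSv",
                 "rel_uncertainty"],
    )


def estimate_lar_risk(organ_dose_msv: float, lar_per_1e5_per_0p1gy: float
                      ) -> float:
    """Lifetime attributable risk [%] at one decimal, linear no-threshold.

    ``lar`` is cases per 10^5 persons per 0.1 Gy; Sv is treated as Gy for
    this scaling.  risk% = LAR x 1e-5 x (dose / 100 mSv) x 100.
    """
    if organ_dose_msv < 0 or lar_per_1e5_per_0p1gy < 0:
        raise ValueError("dose and LAR must be non-negative")
    risk = lar_per_1e5_per_0p1gy * 1e-5 * (organ_dose_msv / 100.0) * 100.0
    return float(np.round(risk, 1))


def profile_vs_distance(
    grid: np.ndarray,
    spacing: float,
    origin: np.ndarray,
    isocenter: np.ndarray,
    direction: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a grid along a ray from the isocenter (voxel-center values).

    Returns (distance [cm], value) pairs until the ray leaves the grid.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    isocenter = np.asarray(isocenter, dtype=float)
    origin = np.asarray(origin, dtype=float)
    dists, vals = [], []
    t = 0.0
    while True:
        p = isocenter + t * direction
        idx = np.round((p - origin) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
            break
        dists.append(t)
        vals.append(grid[tuple(idx)])
        t += spacing
    if not dists:
        raise ValueError("profile line exits the grid immediately")
    return np.asarray(dists), np.asarray(vals)
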