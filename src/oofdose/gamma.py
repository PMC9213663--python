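"""3D gamma-index comparison of dose distributions.

For every reference voxel inside the evaluation mask the gamma index is
the minimum over evaluated points within the search radius of

    gamma = sqrt( (d/dta)^2 + (dD/delta)^2 )

with d the spatial offset, dta the distance-to-agreement criterion, dD
the dose difference and delta the dose criterion — a percentage of the
masked reference maximum (global mode) or of the local reference dose
(local mode).  The search is exhaustive over all voxel centers within
3 x dta (optionally on a trilinearly interpolated sub-voxel lattice), and
gamma <= 1 counts as a pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage


@dataclass
class GammaCriteria:
    dose_percent: float  # % of reference max (global) or local dose
    distance_mm: float
    normalization: str = "global"  # "global" | "local"
    low_dose_threshold_percent: float = 0.0  # % of masked reference max
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.distance_mm <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")


def _offsets(radius_vox: float, subsample: int) -> np.ndarray:
    step = 1.0 / subsample
    r = np.arange(-np.floor(radius_vox), np.floor(radius_vox) + step / 2, step)
    ox, oy, oz = np.meshgrid(r, r, r, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    keep = np.linalg.norm(offs, axis=1) <= radius_vox + 1e-9
    offs = offs[keep]
    # evaluate the zero offset first so the running minimum starts tight
    order = np.argsort(np.linalg.norm(offs, axis=1))
    return offs[order]


def gamma_index(
    reference: np.ndarray,
    evaluated: np.ndarray,
    criteria: GammaCriteria,
    spacing_cm: float,
    subsample: int = 1,
) -> tuple[np.ndarray, float]:
    """(gamma grid, pass rate %) for two co-registered dose grids.

    ``spacing_cm`` must not exceed the distance criterion.  Voxels outside
    the mask or below the low-dose threshold hold NaN in the gamma grid
    and are excluded from the pass rate.  ``subsample > 1`` refines the
    search lattice by trilinear interpolation of the evaluated grid.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("grid shape mismatch")
    dta_cm = criteria.distance_mm / 10.0
    if spacing_cm > dta_cm + 1e-12:
        raise ValueError("grid spacing exceeds the distance criterion")
    mask = (
        np.ones(ref.shape, dtype=bool)
        if criteria.mask is None
        else criteria.mask.astype(bool)
    )
    if mask.shape != ref.shape:
        raise ValueError("mask shape mismatch")
    ref_max = ref[mask].max() if mask.any() else 0.0
    if criteria.low_dose_threshold_percent > 0:
        if ref_max <= 0:
            raise ValueError("reference has no dose above the threshold")
        mask = mask & (
            ref >= criteria.low_dose_threshold_percent / 100.0 * ref_max
        )
    if not mask.any():
        raise ValueError("evaluation mask empty after thresholding")

    if criteria.normalization == "global":
        delta = criteria.dose_percent / 100.0 * ref_max
        delta_grid = np.full(ref.shape, delta)
    else:
        delta_grid = criteria.dose_percent / 100.0 * np.abs(ref)
        delta_grid[delta_grid == 0] = np.inf  # zero-dose voxels: dose term only

    radius_vox = 3.0 * dta_cm / spacing_cm
    offs = _offsets(radius_vox, subsample)
    gamma2 = np.full(ref.shape, np.inf)
    grid_idx = None
    for off in offs:
        dist2 = float(np.sum((off * spacing_cm) ** 2)) / dta_cm**2
        # the distance term alone bounds the candidate from below: once
        # every masked voxel beats it, farther offsets cannot improve
        if dist2 >= float(np.max(gamma2[mask])):
            break
        if np.allclose(off, np.round(off)):
            io = np.round(off).astype(int)
            sl_src = tuple(
                slice(max(o, 0), n + min(o, 0))
                for o, n in zip(io, ref.shape)
            )
            sl_dst = tuple(
                slice(max(-o, 0), n + min(-o, 0))
                for o, n in zip(io, ref.shape)
            )
            shifted = np.full(ref.shape, np.nan)
            shifted[sl_dst] = ev[sl_src]
        else:
            if grid_idx is None:
                grid_idx = np.indices(ref.shape, dtype=float)
            coords = [grid_idx[a] + off[a] for a in range(3)]
            shifted = ndimage.map_coordinates(
                ev, coords, order=1, mode="constant", cval=np.nan
            )
        with np.errstate(invalid="ignore"):
            cand = dist2 + ((shifted - ref) / delta_grid) ** 2
        upd = ~np.isnan(cand) & (cand < gamma2)
        gamma2[upd] = cand[upd]

    gamma = np.sqrt(gamma2)
    gamma[~mask] = np.nan
    passed = gamma[mask] <= 1.0 + 1e-9
    pass_rate = 100.0 * float(passed.sum()) / float(mask.sum())
    return gamma, pass_rate
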