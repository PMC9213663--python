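"""Surrogate particle transport on the phantom grid.

Primaries are transported with condensed-history CSDA energy loss (dose to
water via the water-equivalent path length), Gaussian range straggling,
and Highland multiple scattering.  Nonelastic nuclear events are sampled
along the primary tracks and spawn neutrons (two-component spectrum:
Maxwellian evaporation plus a forward-peaked cascade), one generation of
secondary protons, and prompt gammas.  Neutrons are ray-traced with
exponential removal, a single isotropic scatter, a thermalization stage,
and a uniform room-return thermal component standing in for the treatment
room; their fluence is scored per voxel on logarithmic energy bins and
folded with h(E) = k(E) Q(E) into a dose-equivalent map.  Statistical
uncertainties use the batch method.

This engine is a desk-scale physics surrogate: its parameters live in
``SecondarySourceModel`` and are documented defaults, not claims of
equivalence to a general-purpose Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np

from . import bragg
from .conversion import ConversionTables, log_energy_bins
from .machine import MachineDatabase, back_project_spot, SpotSpec
from .phantom import VoxelPhantom
from .plan import TreatmentPlan, allocate_histories
from .stopping import (
    AIR,
    WATER,
    air_path_energy_correction,
    compute_wet,
    csda_range,
    mass_stopping_power,
    _range_splines,
)

MEV_TO_J = 1.602176634e-13
X0_WATER = 36.08  # radiation length of water, g/cm^2
X0_LUCITE = 40.55 / 1.19  # cm
PROTON_MASS = 938.272


@dataclass
class TransportConfig:
    histories: int = 100_000
    seed: int = 0
    max_step: float = 0.1  # cm
    production_threshold: float = 0.05  # cm (secondaries below are local)
    world_medium: str = "air"  # "air" | "vacuum"
    room_return_albedo: float = 0.08
    batches: int = 10
    spectrum_per_decade: int = 10
    rs_exit_to_iso: float = 20.0  # cm, range-shifter exit plane to isocenter

    def __post_init__(self) -> None:
        if self.histories < 1:
            raise ValueError("need at least one history")
        if self.world_medium not in ("air", "vacuum"):
            raise ValueError("world medium must be 'air' or 'vacuum'")
        if not (0.0 <= self.room_return_albedo <= 1.0):
            raise ValueError("room-return albedo must lie in [0, 1]")
        if self.batches < 2:
            raise ValueError("batch uncertainty needs at least 2 batches")


# Energy nodes for the neutron removal coefficient in water [1/cm at rho=1].
_REMOVAL_E = np.array(
    [1e-9, 1e-7, 1e-5, 1e-3, 1e-2, 0.1, 0.5, 1.0, 2.0, 5.0,
     10.0, 20.0, 50.0, 100.0, 200.0, 1000.0]
)
_REMOVAL_S = np.array(
    [3.0, 2.5, 1.8, 1.2, 1.0, 0.6, 0.35, 0.25, 0.18, 0.12,
     0.095, 0.08, 0.055, 0.045, 0.04, 0.035]
)


@dataclass
class SecondarySourceModel:
    """Parameters of the surrogate nonelastic/neutron physics."""

    nonelastic_per_cm: float = 0.012  # per cm water-equivalent path
    nonelastic_threshold_mev: float = 20.0
    neutron_yield: float = 1.6  # mean neutrons per nonelastic event
    evaporation_temperature: float = 2.0  # MeV
    cascade_fraction: float = 0.35  # of emitted neutrons
    cascade_forward_k: float = 2.5  # exp(k cos) peaking
    secondary_proton_prob: float = 0.6
    secondary_proton_forward_k: float = 6.0
    prompt_gamma_mev: float = 4.0  # total prompt gamma energy per event
    capture_gamma_mev: float = 2.2
    capture_gamma_prob: float = 0.8
    thermalization_fraction: float = 0.3
    gamma_mu_att: float = 0.045  # cm^2/g, ~2-4 MeV photons
    gamma_mu_en: float = 0.026  # cm^2/g

    def removal_coefficient(self, energy_mev: np.ndarray) -> np.ndarray:
        """Neutron removal coefficient in water [1/cm], log-log interp."""
        e = np.clip(np.asarray(energy_mev, dtype=float), _REMOVAL_E[0],
                    _REMOVAL_E[-1])
        return np.exp(
            np.interp(np.log(e), np.log(_REMOVAL_E), np.log(_REMOVAL_S))
        )


@dataclass
class ComponentDoseMaps:
    """Co-registered component dose maps per source proton."""

    spacing: float
    origin: np.ndarray
    dose_primary_proton: np.ndarray  # Gy (dose to water) per proton
    dose_secondary_proton: np.ndarray
    dose_gamma: np.ndarray
    neutron_H: np.ndarray  # Sv per proton
    neutron_H_thermal: np.ndarray  # thermal part of neutron_H
    neutron_fluence: np.ndarray  # (nbins, nx, ny, nz) cm^-2 per proton
    energy_bin_edges: np.ndarray  # MeV, len nbins+1
    rel_uncertainty: Dict[str, np.ndarray]
    histories: int

    def total_dose_components(self) -> Dict[str, np.ndarray]:
        return {
            "primary_proton": self.dose_primary_proton,
            "secondary_proton": self.dose_secondary_proton,
            "gamma": self.dose_gamma,
            "neutron_H": self.neutron_H,
        }

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["spacing_cm"] = self.spacing
            f.attrs["origin_cm"] = self.origin
            f.attrs["histories"] = self.histories
            for name in ("dose_primary_proton", "dose_secondary_proton",
                         "dose_gamma", "neutron_H", "neutron_H_thermal",
                         "neutron_fluence", "energy_bin_edges"):
                f.create_dataset(name, data=getattr(self, name))
            g = f.create_group("rel_uncertainty")
            for k, v in self.rel_uncertainty.items():
                g.create_dataset(k, data=v)

    @classmethod
    def load(cls, path: str | Path) -> "ComponentDoseMaps":
        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][...]
                for name in ("dose_primary_proton", "dose_secondary_proton",
                             "dose_gamma", "neutron_H", "neutron_H_thermal",
                             "neutron_fluence", "energy_bin_edges")
            }
            return cls(
                spacing=float(f.attrs["spacing_cm"]),
                origin=np.asarray(f.attrs["origin_cm"]),
                rel_uncertainty={k: v[...] for k, v in
                                 f["rel_uncertainty"].items()},
                histories=int(f.attrs["histories"]),
                **kw,
            )


def score_neutron_dose_equivalent(
    fluence_spectrum: np.ndarray,
    tables: ConversionTables,
    bin_edges: np.ndarray,
) -> float | np.ndarray:
    """Fold a log-binned neutron fluence spectrum with h(E).

    ``fluence_spectrum`` has the energy bins on its first axis; returns
    H = sum_bins Phi(E) h(E) with h log-log interpolated at the geometric
    bin centers.  Raises when a populated bin lies outside the h-table.
    """
    edges = np.asarray(bin_edges, dtype=float)
    phi = np.asarray(fluence_spectrum, dtype=float)
    if phi.shape[0] != edges.size - 1:
        raise ValueError("spectrum/bin-edge mismatch")
    centers = np.sqrt(edges[:-1] * edges[1:])
    populated = phi.reshape(phi.shape[0], -1).sum(axis=1) > 0
    lo, hi = tables.energies_mev[0], tables.energies_mev[-1]
    out_of_support = populated & ((centers < lo) | (centers > hi))
    if np.any(out_of_support):
        raise ValueError("populated fluence bin outside h(E) table support")
    h = np.zeros_like(centers)
    inside = (centers >= lo) & (centers <= hi)
    h[inside] = tables.h_of(centers[inside])
    return np.tensordot(h, phi, axes=(0, 0))


def estimate_statistical_uncertainty(batched: np.ndarray) -> np.ndarray:
    """Relative k=1 standard error of the batch mean, per voxel.

    ``batched`` stacks per-batch maps on axis 0 (>= 2 batches, the engine
    default is 10).  Voxels with zero mean report zero uncertainty.
    """
    b = np.asarray(batched, dtype=float)
    if b.ndim < 1 or b.shape[0] < 2:
        raise ValueError("need at least 2 batches")
    n = b.shape[0]
    mean = b.mean(axis=0)
    se = b.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean != 0, se / np.abs(mean), 0.0)
    return rel


# ------------------------------------------------------------------ engine


class _Accumulator:
    """Per-batch grids plus running sum/sumsq over batches."""

    COMPONENTS = ("primary", "secondary", "gamma", "neutron_H",
                  "neutron_H_thermal")

    def __init__(self, shape: tuple[int, int, int], nbins: int) -> None:
        self.shape = shape
        self.sums = {c: np.zeros(shape) for c in self.COMPONENTS}
        self.sumsqs = {c: np.zeros(shape) for c in self.COMPONENTS}
        self.spectrum = np.zeros((nbins, *shape), dtype=np.float32)
        self.batch: Dict[str, np.ndarray] = {}
        self.nbatches = 0

    def start_batch(self) -> None:
        self.batch = {c: np.zeros(self.shape) for c in self.COMPONENTS}

    def finish_batch(self, histories: int) -> None:
        for c in self.COMPONENTS:
            per_p = self.batch[c] / histories
            self.sums[c] += per_p
            self.sumsqs[c] += per_p**2
        self.nbatches += 1

    def mean(self, c: str) -> np.ndarray:
        return self.sums[c] / self.nbatches

    def rel_uncertainty(self, c: str) -> np.ndarray:
        n = self.nbatches
        mean = self.mean(c)
        var = np.maximum(self.sumsqs[c] / n - mean**2, 0.0) * n / (n - 1)
        se = np.sqrt(var / n)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mean != 0, se / np.abs(mean), 0.0)


def _beam_basis(gantry_deg: float, table_deg: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(direction, u, v) of a field; gantry rotates in the x-y plane,
    the table about the patient's longitudinal (z) axis."""
    g = np.deg2rad(gantry_deg)
    t = np.deg2rad(table_deg)
    d = np.array([np.sin(g), -np.cos(g), 0.0])
    rot = np.array([[np.cos(t), 0.0, np.sin(t)],
                    [0.0, 1.0, 0.0],
                    [-np.sin(t), 0.0, np.cos(t)]])
    d = rot @ d
    helper = np.array([0.0, 0.0, 1.0])
    if abs(d @ helper) > 0.99:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return d, u, v


def _entry_distance(phantom: VoxelPhantom, origin: np.ndarray,
                    direction: np.ndarray) -> float:
    """Path length from ``origin`` to the first in-body voxel (cm)."""
    body = phantom.in_body()
    t = 0.0
    step = phantom.spacing
    pos = origin.copy()
    for _ in range(int(400.0 / step)):
        idx = np.round((pos - phantom.origin) / phantom.spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < body.shape):
            if body[tuple(idx)]:
                return t
        pos = pos + direction * step
        t += step
    return t


def _pv(energy: np.ndarray) -> np.ndarray:
    return energy * (energy + 2 * PROTON_MASS) / (energy + PROTON_MASS)


def _sample_forward(rng: np.random.Generator, axis: np.ndarray, k: float,
                    n: int) -> np.ndarray:
    """Directions with cos(theta) ~ exp(k cos) around per-row axes."""
    u = rng.random(n)
    ek, emk = np.exp(k), np.exp(-k)
    mu = np.log(emk + u * (ek - emk)) / k
    phi = rng.random(n) * 2 * np.pi
    sin_t = np.sqrt(np.maximum(1 - mu**2, 0.0))
    # per-row orthonormal basis
    a = np.where(np.abs(axis[:, 2:3]) < 0.9,
                 np.tile([0.0, 0.0, 1.0], (n, 1)),
                 np.tile([1.0, 0.0, 0.0], (n, 1)))
    e1 = np.cross(a, axis)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axis, e1)
    return (axis * mu[:, None]
            + e1 * (sin_t * np.cos(phi))[:, None]
            + e2 * (sin_t * np.sin(phi))[:, None])


def _isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    mu = rng.uniform(-1, 1, n)
    phi = rng.random(n) * 2 * np.pi
    s = np.sqrt(1 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


class _Engine:
    def __init__(self, phantom: VoxelPhantom, config: TransportConfig,
                 source: SecondarySourceModel, tables: ConversionTables):
        self.ph = phantom
        self.cfg = config
        self.src = source
        self.tables = tables
        self.rsp = np.maximum(phantom.relative_stopping_power(), 1e-5)
        self.rho = np.maximum(phantom.density, 1e-5)
        self.vox_volume = phantom.spacing**3
        self.edges = log_energy_bins(per_decade=config.spectrum_per_decade)
        self.centers = np.sqrt(self.edges[:-1] * self.edges[1:])
        # clamp to the h-table support for internal scoring (sub-thermal
        # bins take the thermal-node coefficients)
        clamped = np.clip(self.centers, tables.energies_mev[0],
                          tables.energies_mev[-1])
        self.h_bins = tables.h_of(clamped)
        self.k_bins = tables.kerma_of(clamped)
        # residual-range <-> energy lookup in water
        fwd, _ = _range_splines(WATER)
        self.e_grid = np.linspace(1.0, 260.0, 1200)
        self.r_grid = fwd(self.e_grid)
        self.s_grid = mass_stopping_power(WATER, self.e_grid)
        self.air_rsp = AIR.density * float(
            mass_stopping_power(AIR, 100.0) / mass_stopping_power(WATER, 100.0)
        )
        # Gy (dose to water) deposited per MeV scored in one voxel
        self.dose_conv = MEV_TO_J / (self.vox_volume * 1e-3)

    # -- helpers ---------------------------------------------------------
    def _voxel_idx(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.round((pos - self.ph.origin) / self.ph.spacing).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(self.ph.shape)), axis=1)
        return idx, inside

    def _advance_to_box(self, pos: np.ndarray, dirs: np.ndarray
                        ) -> np.ndarray:
        """Advance rays to the grid bounding box (slab method)."""
        lo = self.ph.origin - 0.5 * self.ph.spacing
        hi = (self.ph.origin + self.ph.spacing
              * (np.array(self.ph.shape) - 0.5))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - pos) / dirs
            t2 = (hi - pos) / dirs
        tmin = np.nanmax(np.minimum(t1, t2), axis=1)
        tmin = np.clip(tmin, 0.0, None)
        # step a hair past the boundary so the entry voxel is inside
        return pos + dirs * (tmin + 1e-6)[:, None]

    # -- primary / secondary protons ------------------------------------
    def transport_protons(self, rng, pos, dirs, residual, grid,
                          spawn: bool):
        """CSDA transport; deposits into ``grid`` [MeV], returns events."""
        step = self.cfg.max_step
        ev_pos, ev_e = [], []
        pos = self._advance_to_box(pos.copy(), dirs)
        # random sub-step lead per history: de-aliases the deposit pattern
        # when the step size is commensurate with the voxel pitch
        lead = rng.random(pos.shape[0]) * step
        idx0, inside0 = self._voxel_idx(pos)
        rsp0 = np.where(
            inside0, self.rsp[tuple(np.clip(idx0, 0, np.array(self.ph.shape)
                                            - 1).T)], 0.0
        )
        pos = pos + dirs * lead[:, None]
        residual = residual - lead * rsp0
        dirs = dirs.copy()
        active = residual > 0
        lam = self.src.nonelastic_per_cm
        e_thr = self.src.nonelastic_threshold_mev
        max_iter = int(80.0 / step)
        for _ in range(max_iter):
            if not active.any():
                break
            ai = np.nonzero(active)[0]
            # deposit at the segment midpoint (unbiased attribution)
            p = pos[ai] + dirs[ai] * (step / 2.0)
            idx, inside = self._voxel_idx(p)
            # rays outside the grid are gone (they were advanced to the box)
            if not inside.all():
                active[ai[~inside]] = False
                ai = ai[inside]
                if ai.size == 0:
                    continue
                idx = idx[inside]
            flat = (idx[:, 0], idx[:, 1], idx[:, 2])
            rsp_v = self.rsp[flat]
            r = residual[ai]
            dw = step * rsp_v
            e = np.interp(r, self.r_grid, self.e_grid)
            # exact CSDA energy loss over the step (energy-conserving)
            e_next = np.interp(np.maximum(r - dw, 0.0), self.r_grid,
                               self.e_grid)
            e_next = np.where(r - dw <= self.r_grid[0], 0.0, e_next)
            dep = np.where(dw >= r, e, e - e_next)
            np.add.at(grid, flat, dep * self.dose_conv)
            stopped = dw >= r
            residual[ai] -= dw
            # nonelastic events
            if spawn:
                can = (~stopped) & (e > e_thr)
                u = rng.random(ai.size)
                hit = can & (u < lam * dw)
                if hit.any():
                    ev_pos.append(p[hit])
                    ev_e.append(e[hit])
                    active[ai[hit]] = False
            active[ai[stopped]] = False
            # multiple scattering (Highland) + advance
            pv = _pv(np.maximum(e, 5.0))
            sig_t = 14.1 / pv * np.sqrt(np.maximum(dw, 1e-12) / X0_WATER)
            g = rng.standard_normal((ai.size, 3)) * sig_t[:, None]
            d = dirs[ai]
            g -= d * np.sum(g * d, axis=1, keepdims=True)
            d = d + g
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            dirs[ai] = d
            pos[ai] += d * step
        if ev_pos:
            return np.concatenate(ev_pos), np.concatenate(ev_e)
        return np.zeros((0, 3)), np.zeros(0)

    # -- neutrons --------------------------------------------------------
    def transport_neutrons(self, rng, pos, dirs, energy, acc: _Accumulator):
        """Analog neutron transport with scatter + thermalization stages.

        Returns (capture positions, escape count).
        """
        step = self.ph.spacing
        captures = []
        escaped = 0
        bins = np.clip(
            np.searchsorted(self.edges, energy, side="right") - 1,
            0, self.centers.size - 1,
        )
        H = acc.batch["neutron_H"]
        Hth = acc.batch["neutron_H_thermal"]
        Dsec = acc.batch["secondary"]
        for stage in range(3):
            n = pos.shape[0]
            if n == 0:
                break
            eta = rng.exponential(1.0, n)
            tau = np.zeros(n)
            active = np.ones(n, dtype=bool)
            coll = np.zeros(n, dtype=bool)
            sigma_w = self.src.removal_coefficient(energy)
            h_e = self.h_bins[bins]
            k_e = self.k_bins[bins]
            thermal_like = energy < 4e-7
            max_iter = int(120.0 / step)
            pos = pos.copy()
            for _ in range(max_iter):
                if not active.any():
                    break
                ai = np.nonzero(active)[0]
                idx, inside = self._voxel_idx(pos[ai])
                out = ~inside
                if out.any():
                    active[ai[out]] = False
                    escaped += int(out.sum())
                    ai = ai[inside]
                    if ai.size == 0:
                        continue
                    idx = idx[inside]
                flat = (idx[:, 0], idx[:, 1], idx[:, 2])
                rho_v = self.rho[flat]
                # score track length -> fluence, H, recoil-proton dose
                tl = step
                np.add.at(acc.spectrum, (bins[ai],) + flat,
                          np.float32(tl))
                np.add.at(H, flat, tl * h_e[ai] / self.vox_volume)
                # neutron kerma deposited via recoil protons [Gy]
                np.add.at(Dsec, flat, tl * k_e[ai] / self.vox_volume)
                th = thermal_like[ai]
                if th.any():
                    fl_th = tuple(c[th] for c in flat)
                    np.add.at(Hth, fl_th,
                              tl * h_e[ai][th] / self.vox_volume)
                dtau = sigma_w[ai] * rho_v * tl
                tau[ai] += dtau
                now_coll = tau[ai] >= eta[ai]
                if now_coll.any():
                    coll[ai[now_coll]] = True
                    active[ai[now_coll]] = False
                pos[ai] += dirs[ai] * step
            # promote collided neutrons to the next stage
            ci = np.nonzero(coll)[0]
            if ci.size == 0:
                pos = np.zeros((0, 3))
                continue
            if stage == 0:
                # single isotropic scatter with energy degradation
                pos = pos[ci]
                energy = energy[ci] * rng.uniform(0.05, 0.5, ci.size)
                dirs = _isotropic(rng, ci.size)
            elif stage == 1:
                u = rng.random(ci.size)
                to_thermal = u < self.src.thermalization_fraction
                cap = ci[~to_thermal]
                captures.append(pos[cap])
                pos = pos[ci[to_thermal]]
                energy = np.full(pos.shape[0], 2.5e-8)
                dirs = _isotropic(rng, pos.shape[0])
            else:
                captures.append(pos[ci])
                pos = np.zeros((0, 3))
            bins = np.clip(
                np.searchsorted(self.edges, energy, side="right") - 1,
                0, self.centers.size - 1,
            ) if pos.shape[0] else bins
        cap = (np.concatenate(captures) if captures
               else np.zeros((0, 3)))
        return cap, escaped

    # -- gammas ----------------------------------------------------------
    def transport_gammas(self, rng, pos, energy, grid):
        """Kerma-style gamma deposition along one sampled direction."""
        if pos.shape[0] == 0:
            return
        step = self.ph.spacing
        dirs = _isotropic(rng, pos.shape[0])
        w = energy.copy()  # residual energy weight [MeV]
        pos = pos.copy()
        mu_att = self.src.gamma_mu_att
        mu_en = self.src.gamma_mu_en
        active = np.ones(pos.shape[0], dtype=bool)
        for _ in range(int(120.0 / step)):
            if not active.any():
                break
            ai = np.nonzero(active)[0]
            idx, inside = self._voxel_idx(pos[ai])
            if not inside.all():
                active[ai[~inside]] = False
                ai = ai[inside]
                if ai.size == 0:
                    continue
                idx = idx[inside]
            flat = (idx[:, 0], idx[:, 1], idx[:, 2])
            rho_v = self.rho[flat]
            dep = w[ai] * mu_en * rho_v * step
            np.add.at(grid, flat, dep * self.dose_conv)
            w[ai] *= np.exp(-mu_att * rho_v * step)
            active[ai[w[ai] < 1e-3]] = False
            pos[ai] += dirs[ai] * step


def run_transport(
    plan: TreatmentPlan,
    machine: MachineDatabase,
    phantom: VoxelPhantom,
    config: TransportConfig,
    source: Optional[SecondarySourceModel] = None,
    tables: Optional[ConversionTables] = None,
) -> ComponentDoseMaps:
    """Run the surrogate transport for a plan and return component maps.

    Histories are allocated to spots proportionally to their MU and split
    into ``config.batches`` batches for the statistical-uncertainty
    estimate; a fixed seed reproduces the maps bit for bit.
    """
    source = source or SecondarySourceModel()
    tables = tables or ConversionTables()
    if phantom.material_id.size == 0:
        raise ValueError("empty phantom")
    lo_e, hi_e = machine.span()
    fi, en, xy, mu = plan.spot_table()
    for e in np.unique(en):
        if not (lo_e - 1e-9 <= e <= hi_e + 1e-9):
            raise ValueError(
                f"spot energy {e} MeV outside machine database span"
            )

    rng = np.random.default_rng(config.seed)
    eng = _Engine(phantom, config, source, tables)
    acc = _Accumulator(phantom.shape, eng.centers.size)

    # per-field geometry and per-layer source terms
    field_geo = []
    for f in plan.fields:
        d, u, v = _beam_basis(f.gantry_angle, f.table_angle)
        nozzle_origin = -50.0 * d
        t_surface = _entry_distance(phantom, nozzle_origin, d)
        if f.range_shifter is not None:
            rs = f.range_shifter
            t_rs_exit = 50.0 - config.rs_exit_to_iso
            air_len = max(t_surface - t_rs_exit, 0.0)
        else:
            rs = None
            air_len = t_surface
        if config.world_medium == "vacuum":
            air_len = 0.0
        field_geo.append((d, u, v, rs, air_len))

    n_spot = allocate_histories(plan, config.histories)
    # split each spot's histories across batches (deterministic)
    per_batch = []
    for b in range(config.batches):
        nb = n_spot // config.batches
        nb = nb + ((n_spot % config.batches) > b)
        per_batch.append(nb)

    total_escaped = 0
    box_area = 2.0 * sum(
        phantom.shape[i] * phantom.shape[j]
        for i, j in ((0, 1), (1, 2), (0, 2))
    ) * phantom.spacing**2
    thermal_bin = int(
        np.clip(np.searchsorted(eng.edges, 2.5e-8, side="right") - 1,
                0, eng.centers.size - 1)
    )
    h_thermal = float(eng.h_bins[thermal_bin])

    for b in range(config.batches):
        acc.start_batch()
        nb = per_batch[b]
        if nb.sum() == 0:
            acc.finish_batch(1)
            continue
        all_ev_pos, all_ev_e, all_ev_axis = [], [], []
        # launch one vectorized bundle per (field, energy layer)
        layer_keys = np.unique(
            np.column_stack([fi, en]), axis=0
        )
        for f_idx_f, nominal in layer_keys:
            f_idx = int(f_idx_f)
            nominal = float(nominal)
            sel = np.nonzero((fi == f_idx) & (en == nominal) & (nb > 0))[0]
            if sel.size == 0:
                continue
            counts = nb[sel]
            n = int(counts.sum())
            d, u, v, rs, air_len = field_geo[f_idx]
            record = machine.interpolate(nominal)
            de_air = (
                air_path_energy_correction(air_len, nominal)
                if (config.world_medium == "air" and air_len > 0)
                else 0.0
            )
            # back-project every spot of the layer to the nozzle exit
            ex = np.empty(sel.size)
            ey = np.empty(sel.size)
            sx = np.empty(sel.size)
            sy = np.empty(sel.size)
            for j, spot_idx in enumerate(sel):
                nz = back_project_spot(
                    SpotSpec(tuple(xy[spot_idx]), float(mu[spot_idx])),
                    foci=machine.foci,
                )
                ex[j], ey[j] = nz.exit_position
                sx[j] = nz.direction[0] / nz.direction[2]
                sy[j] = nz.direction[1] / nz.direction[2]
            rep = np.repeat(np.arange(sel.size), counts)

            # sample transverse phase space (position/angle) per axis
            pos_uv = np.empty((n, 2))
            ang = np.empty((n, 2))
            for k_ax, (moms, means, slopes) in enumerate(
                ((record.fe_moments_x, ex, sx),
                 (record.fe_moments_y, ey, sy))
            ):
                a0, a1, a2 = moms
                cov = np.array([[a2, a1], [a1, a0]])
                w_eig, v_eig = np.linalg.eigh(cov)
                lchol = v_eig @ np.diag(np.sqrt(np.maximum(w_eig, 0.0)))
                sample = (lchol @ rng.standard_normal((2, n))).T
                pos_uv[:, k_ax] = means[rep] + sample[:, 0]
                ang[:, k_ax] = slopes[rep] + sample[:, 1]

            nozzle_pt = -50.0 * d
            pos = (
                nozzle_pt
                + pos_uv[:, 0:1] * u
                + pos_uv[:, 1:2] * v
            )
            dirs = d[None, :] + ang[:, 0:1] * u + ang[:, 1:2] * v
            if rs is not None:
                # multiple scattering in the range shifter
                pv = float(_pv(np.array([nominal]))[0])
                sig = (14.1 / pv) * np.sqrt(
                    rs.thickness_cm * rs.material.density / (X0_LUCITE * 1.19)
                )
                extra = rng.standard_normal((n, 2)) * sig
                dirs = dirs + extra[:, 0:1] * u + extra[:, 1:2] * v
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

            # sampled energy, air correction, straggling -> residual range
            e_samp = rng.normal(nominal + de_air, record.energy_spread, n)
            e_samp = np.clip(e_samp, 2.0, 300.0)
            r0 = np.interp(e_samp, eng.e_grid, eng.r_grid)
            if rs is not None:
                r0 = r0 - compute_wet(rs.material, rs.thickness_cm,
                                      max(nominal, 15.0))
            r0 = r0 - air_len * eng.air_rsp
            r_mean = float(csda_range(WATER, max(nominal, 15.0)))
            r0 = r0 + rng.normal(
                0.0, float(bragg.range_straggling_sigma(r_mean)), n
            )
            keep = r0 > 0
            if not keep.any():
                continue
            ev_p, ev_e = eng.transport_protons(
                rng, pos[keep], dirs[keep], r0[keep],
                acc.batch["primary"], spawn=True,
            )
            if ev_p.shape[0]:
                all_ev_pos.append(ev_p)
                all_ev_e.append(ev_e)
                all_ev_axis.append(np.tile(d, (ev_p.shape[0], 1)))

        # ---- secondaries from the collected nonelastic events
        if all_ev_pos:
            ev_pos = np.concatenate(all_ev_pos)
            ev_e = np.concatenate(all_ev_e)
            ev_axis = np.concatenate(all_ev_axis)
            m = ev_pos.shape[0]
            e_avail = ev_e.copy()

            # secondary protons (one generation, forward peaked around the
            # parent primary's field axis)
            has_sp = rng.random(m) < source.secondary_proton_prob
            e_sp = np.where(
                has_sp, rng.uniform(0.2, 0.5, m) * e_avail, 0.0
            )
            e_avail = e_avail - e_sp
            if has_sp.any():
                sp_dir = _sample_forward(
                    rng, ev_axis, source.secondary_proton_forward_k, m
                )
                idx = np.nonzero(has_sp)[0]
                r_sp = np.interp(
                    np.maximum(e_sp[idx], 2.0), eng.e_grid, eng.r_grid
                )
                eng.transport_protons(
                    rng, ev_pos[idx], sp_dir[idx], r_sp,
                    acc.batch["secondary"], spawn=False,
                )

            # neutrons: Maxwellian evaporation + forward-peaked cascade
            n_n = rng.poisson(source.neutron_yield, m)
            rep = np.repeat(np.arange(m), n_n)
            if rep.size:
                n_tot = rep.size
                casc = rng.random(n_tot) < source.cascade_fraction
                e_n = np.empty(n_tot)
                e_n[~casc] = rng.gamma(
                    2.0, source.evaporation_temperature, (~casc).sum()
                )
                e_n[casc] = rng.uniform(0.1, 0.6, casc.sum()) * ev_e[rep[casc]]
                e_n = np.minimum(e_n, 0.8 * ev_e[rep])
                e_n = np.maximum(e_n, 1e-3)
                n_dir = np.empty((n_tot, 3))
                n_dir[~casc] = _isotropic(rng, int((~casc).sum()))
                n_dir[casc] = _sample_forward(
                    rng, ev_axis[rep[casc]], source.cascade_forward_k,
                    int(casc.sum()),
                )
                cap_pos, esc = eng.transport_neutrons(
                    rng, ev_pos[rep], n_dir, e_n, acc
                )
                total_escaped += esc

                # capture gammas
                if cap_pos.shape[0]:
                    take = rng.random(cap_pos.shape[0]) < source.capture_gamma_prob
                    eng.transport_gammas(
                        rng, cap_pos[take],
                        np.full(int(take.sum()), source.capture_gamma_mev),
                        acc.batch["gamma"],
                    )

            # prompt gammas at the event sites
            eng.transport_gammas(
                rng, ev_pos, np.full(m, source.prompt_gamma_mev),
                acc.batch["gamma"],
            )

            # energy not carried by tracked secondaries deposits locally
            idxs, inside = eng._voxel_idx(ev_pos)
            loc = np.nonzero(inside)[0]
            if loc.size:
                fl = (idxs[loc, 0], idxs[loc, 1], idxs[loc, 2])
                local = np.maximum(e_avail[loc] * 0.35, 0.0)
                np.add.at(acc.batch["secondary"], fl, local * eng.dose_conv)

        acc.finish_batch(max(int(nb.sum()), 1))

    nb_total = config.histories
    rel = {
        "primary_proton": acc.rel_uncertainty("primary"),
        "secondary_proton": acc.rel_uncertainty("secondary"),
        "gamma": acc.rel_uncertainty("gamma"),
        "neutron_H": acc.rel_uncertainty("neutron_H"),
    }
    neutron_h = acc.mean("neutron_H")
    neutron_h_th = acc.mean("neutron_H_thermal")
    spectrum = acc.spectrum / np.float32(eng.vox_volume * nb_total)

    # room-return thermal component: a uniform thermal fluence fed by the
    # neutrons leaking the grid, standing in for the treatment room walls.
    phi_room = (
        config.room_return_albedo * total_escaped / box_area
    ) / max(nb_total, 1)
    if phi_room > 0:
        neutron_h = neutron_h + phi_room * h_thermal
        neutron_h_th = neutron_h_th + phi_room * h_thermal
        spectrum[thermal_bin] += np.float32(phi_room)

    return ComponentDoseMaps(
        spacing=phantom.spacing,
        origin=phantom.origin,
        dose_primary_proton=acc.mean("primary"),
        dose_secondary_proton=acc.mean("secondary"),
        dose_gamma=acc.mean("gamma"),
        neutron_H=neutron_h,
        neutron_H_thermal=neutron_h_th,
        neutron_fluence=spectrum,
        energy_bin_edges=eng.edges,
        rel_uncertainty=rel,
        histories=nb_total,
    )
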