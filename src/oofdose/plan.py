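"""Treatment plans: fields, energy layers, scan spots, and I/O.

Two on-disk representations are supported: DICOM RT Ion Plan files (read
and written through pydicom) and a simplified YAML format mirroring the
same field -> energy layer -> spot hierarchy, so that plans round-trip
losslessly without DICOM fixtures.  Spot positions are given at the
isocenter plane in cm; MU are meterset weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .machine import SpotSpec
from .stopping import LUCITE, MaterialSpec


@dataclass(frozen=True)
class RangeShifterSpec:
    material: MaterialSpec
    thickness_cm: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("range-shifter thickness must be positive")


#: The lucite range shifter of the reference brain treatment.
DEFAULT_RANGE_SHIFTER = RangeShifterSpec(LUCITE, 4.44)


@dataclass
class EnergyLayer:
    nominal_energy: float  # MeV
    spots: list[SpotSpec]

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("energy layer must contain at least one spot")

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.spots))


@dataclass
class FieldSpec:
    gantry_angle: float  # deg
    table_angle: float  # deg
    layers: list[EnergyLayer]
    range_shifter: Optional[RangeShifterSpec] = None
    name: str = ""

    @property
    def total_mu(self) -> float:
        return float(sum(l.total_mu for l in self.layers))


@dataclass
class TreatmentPlan:
    fields: list[FieldSpec]
    prescribed_dose_gy_rbe: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.total_mu <= 0:
            raise ValueError("plan must carry positive total MU")

    @property
    def total_mu(self) -> float:
        return float(sum(f.total_mu for f in self.fields))

    def spot_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (field_index, layer_energy, xy, mu) arrays over all spots."""
        fi, en, xy, mu = [], [], [], []
        for i, f in enumerate(self.fields):
            for layer in f.layers:
                for s in layer.spots:
                    fi.append(i)
                    en.append(layer.nominal_energy)
                    xy.append(s.isocenter_xy)
                    mu.append(s.mu)
        return (
            np.array(fi),
            np.array(en),
            np.array(xy),
            np.array(mu),
        )


def allocate_histories(plan: TreatmentPlan, total_histories: int) -> np.ndarray:
    """Histories per spot, proportional to spot MU (largest-remainder).

    The integer allocation deviates from exact MU proportionality by less
    than one history per spot, i.e. well under 0.01% of the total for any
    realistic history count.
    """
    if total_histories < 1:
        raise ValueError("need at least one history")
    _, _, _, mu = plan.spot_table()
    ideal = mu / mu.sum() * total_histories
    base = np.floor(ideal).astype(np.int64)
    short = total_histories - int(base.sum())
    if short > 0:
        order = np.argsort(ideal - base)[::-1]
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------- YAML I/O

def save_plan(plan: TreatmentPlan, path: str | Path) -> None:
    doc = {
        "name": plan.name,
        "prescribed_dose_gy_rbe": plan.prescribed_dose_gy_rbe,
        "fields": [
            {
                "name": f.name,
                "gantry_angle_deg": f.gantry_angle,
                "table_angle_deg": f.table_angle,
                "range_shifter": (
                    None
                    if f.range_shifter is None
                    else {
                        "material": f.range_shifter.material.name,
                        "mass_fractions": f.range_shifter.material.mass_fractions,
                        "density_g_cm3": f.range_shifter.material.density,
                        "mean_excitation_energy_eV": (
                            f.range_shifter.material.mean_excitation_energy
                        ),
                        "thickness_cm": f.range_shifter.thickness_cm,
                    }
                ),
                "layers": [
                    {
                        "nominal_energy_MeV": layer.nominal_energy,
                        "spots": [
                            [float(s.isocenter_xy[0]), float(s.isocenter_xy[1]),
                             float(s.mu)]
                            for s in layer.spots
                        ],
                    }
                    for layer in f.layers
                ],
            }
            for f in plan.fields
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _load_rs(doc: dict | None) -> Optional[RangeShifterSpec]:
    if doc is None:
        return None
    mat = MaterialSpec(
        doc["material"],
        doc["mass_fractions"],
        doc["density_g_cm3"],
        doc["mean_excitation_energy_eV"],
    )
    return RangeShifterSpec(mat, doc["thickness_cm"])


def load_plan(path: str | Path) -> TreatmentPlan:
    """Load a plan from DICOM (.dcm) or the simplified YAML format."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return load_plan_dicom(path)
    doc = yaml.safe_load(path.read_text())
    fields = []
    for fd in doc["fields"]:
        layers = []
        for li, ld in enumerate(fd["layers"]):
            spots = [
                SpotSpec((x, y), mu, layer_index=li) for x, y, mu in ld["spots"]
            ]
            layers.append(EnergyLayer(ld["nominal_energy_MeV"], spots))
        fields.append(
            FieldSpec(
                gantry_angle=fd["gantry_angle_deg"],
                table_angle=fd["table_angle_deg"],
                layers=layers,
                range_shifter=_load_rs(fd.get("range_shifter")),
                name=fd.get("name", ""),
            )
        )
    return TreatmentPlan(
        fields,
        prescribed_dose_gy_rbe=doc.get("prescribed_dose_gy_rbe", 0.0),
        name=doc.get("name", ""),
    )


# --------------------------------------------------------------- DICOM I/O

def load_plan_dicom(path: str | Path) -> TreatmentPlan:
    """Read a DICOM RT Ion Plan (modulated scan mode) into a TreatmentPlan."""
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    if "IonBeamSequence" not in ds:
        raise ValueError("not an RT Ion Plan: missing IonBeamSequence")
    fields = []
    for beam in ds.IonBeamSequence:
        if getattr(beam, "ScanMode", "MODULATED") != "MODULATED":
            raise ValueError("unsupported delivery type; expected MODULATED PBS")
        rs = None
        if getattr(beam, "NumberOfRangeShifters", 0):
            # thickness is carried in a private convention: the range
            # shifter ID encodes the lucite thickness in mm
            rsid = beam.RangeShifterSequence[0].RangeShifterID
            thickness_mm = float(str(rsid).split("_")[-1])
            rs = RangeShifterSpec(LUCITE, thickness_mm / 10.0)
        gantry = table = 0.0
        layers = []
        for cp in beam.IonControlPointSequence:
            gantry = float(getattr(cp, "GantryAngle", gantry))
            table = float(getattr(cp, "PatientSupportAngle", table))
            weights = np.asarray(
                getattr(cp, "ScanSpotMetersetWeights", []), dtype=float
            ).ravel()
            if weights.size == 0 or float(weights.sum()) == 0.0:
                continue  # paired end-of-layer control point
            if "NominalBeamEnergy" not in cp:
                raise ValueError("energy layer missing NominalBeamEnergy")
            pos = np.asarray(cp.ScanSpotPositionMap, dtype=float).reshape(-1, 2)
            spots = [
                SpotSpec((x / 10.0, y / 10.0), w)  # mm -> cm
                for (x, y), w in zip(pos, weights)
                if w > 0
            ]
            layers.append(EnergyLayer(float(cp.NominalBeamEnergy), spots))
        fields.append(
            FieldSpec(
                gantry_angle=gantry,
                table_angle=table,
                layers=layers,
                range_shifter=rs,
                name=str(getattr(beam, "BeamName", "")),
            )
        )
    return TreatmentPlan(fields, name=str(getattr(ds, "RTPlanLabel", "")))


def save_plan_dicom(plan: TreatmentPlan, path: str | Path) -> None:
    """Write a minimal DICOM RT Ion Plan carrying the full spot hierarchy."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTIonPlanStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.name or "oofdose"
    beams = []
    for f in plan.fields:
        beam = Dataset()
        beam.BeamName = f.name
        beam.ScanMode = "MODULATED"
        beam.NumberOfRangeShifters = 1 if f.range_shifter else 0
        if f.range_shifter:
            rs = Dataset()
            rs.RangeShifterID = "RS_LUCITE_%g" % (
                f.range_shifter.thickness_cm * 10.0
            )
            beam.RangeShifterSequence = [rs]
        cps = []
        for layer in f.layers:
            cp = Dataset()
            cp.GantryAngle = f.gantry_angle
            cp.PatientSupportAngle = f.table_angle
            cp.NominalBeamEnergy = layer.nominal_energy
            pos = []
            weights = []
            for s in layer.spots:
                pos.extend([s.isocenter_xy[0] * 10.0, s.isocenter_xy[1] * 10.0])
                weights.append(s.mu)
            cp.ScanSpotPositionMap = pos
            cp.ScanSpotMetersetWeights = weights
            cps.append(cp)
        beam.IonControlPointSequence = cps
        beams.append(beam)
    ds.IonBeamSequence = beams
    ds.save_as(str(path), enforce_file_format=True)
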