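"""DICOM RT Ion Plan spot-map I/O.

A pencil-beam-scanning ion plan stores, per energy layer, a flat scan-spot
position map (alternating x, y in mm at the isocenter plane) and per-spot
meterset *weights*.  Absolute MU per spot is recovered with the standard
DICOM convention::

    spot_MU = weight * BeamMeterset / FinalCumulativeMetersetWeight

where ``BeamMeterset`` lives in the fraction group's referenced-beam sequence
and ``FinalCumulativeMetersetWeight`` on the ion beam.  Layers are kept in
control-point (delivery) order; no re-sorting by energy.

Positions and weights are written with the DICOM-mandated ``FL`` (float32)
value representation, so round trips are exact at float32 precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import PlanArithmeticError, PlanFormatError, ValidationError

RT_ION_PLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.8"

#: default clinical proton energy window used for invariant checks, MeV
CLINICAL_ENERGY_RANGE = (60.0, 260.0)


@dataclass(frozen=True)
class PlannedSpot:
    """One planned beamlet: isocenter-plane position (mm) and meterset (MU)."""

    layer_index: int
    spot_index: int
    x_iso: float
    y_iso: float
    meterset: float

    def __post_init__(self):
        if self.layer_index < 0 or self.spot_index < 0:
            raise ValidationError("layer_index and spot_index must be >= 0")
        if not self.meterset > 0:
            raise ValidationError(f"spot meterset must be > 0, got {self.meterset}")


@dataclass
class EnergyLayer:
    """All spots delivered at one nominal beam energy (MeV)."""

    layer_index: int
    energy: float
    spots: list[PlannedSpot]

    def validate(self, energy_range: tuple[float, float] = CLINICAL_ENERGY_RANGE):
        lo, hi = energy_range
        if not lo <= self.energy <= hi:
            raise ValidationError(
                f"layer {self.layer_index}: energy {self.energy} MeV outside [{lo}, {hi}]"
            )
        if not self.spots:
            raise ValidationError(f"layer {self.layer_index} has no spots")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def positions(self) -> np.ndarray:
        """(n, 2) array of isocenter-plane positions in delivery order."""
        return np.array([(s.x_iso, s.y_iso) for s in self.spots], dtype=float)

    def metersets(self) -> np.ndarray:
        return np.array([s.meterset for s in self.spots], dtype=float)


@dataclass
class IonPlan:
    """One ion beam's spot map: ordered energy layers at a fixed gantry angle."""

    plan_id: str
    gantry_angle: float
    layers: list[EnergyLayer]
    total_mu: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.total_mu is None:
            self.total_mu = float(
                sum(s.meterset for layer in self.layers for s in layer.spots)
            )

    def validate(self, energy_range: tuple[float, float] = CLINICAL_ENERGY_RANGE):
        if not self.layers:
            raise ValidationError("plan has no energy layers")
        seen = set()
        for layer in self.layers:
            layer.validate(energy_range)
            for s in layer.spots:
                key = (s.layer_index, s.spot_index)
                if key in seen:
                    raise ValidationError(f"duplicate spot key {key}")
                seen.add(key)
        total = sum(s.meterset for layer in self.layers for s in layer.spots)
        if not math.isclose(total, self.total_mu, rel_tol=1e-6):
            raise ValidationError(
                f"total_mu {self.total_mu} != sum of spot metersets {total}"
            )
        return self

    @property
    def n_spots(self) -> int:
        return sum(layer.n_spots for layer in self.layers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([layer.energy for layer in self.layers], dtype=float)

    def spot_arrays(self) -> dict[str, np.ndarray]:
        """Flat per-spot arrays (layer_index, spot_index, x, y, mu, energy)
        in delivery order — the vectorised view used by the pipeline."""
        li, si, xs, ys, mus, es = [], [], [], [], [], []
        for layer in self.layers:
            for s in layer.spots:
                li.append(s.layer_index)
                si.append(s.spot_index)
                xs.append(s.x_iso)
                ys.append(s.y_iso)
                mus.append(s.meterset)
                es.append(layer.energy)
        return {
            "layer_index": np.asarray(li, dtype=np.int64),
            "spot_index": np.asarray(si, dtype=np.int64),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "mu": np.asarray(mus, dtype=float),
            "energy": np.asarray(es, dtype=float),
        }


def _require(ds, attr: str, ctx: str):
    if attr not in ds:
        raise PlanFormatError(f"{ctx}: missing required attribute {attr}")
    return ds[attr].value


def write_ion_plan(plan: IonPlan, path) -> str:
    """Write ``plan`` as a single-beam DICOM RT Ion Plan.

    Round trip through :func:`read_ion_plan` reproduces coordinates at
    float32 precision and total MU to 1e-6 relative.
    """
    plan.validate()

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RT_ION_PLAN_STORAGE
    # derive the instance UID from the plan id so writes are reproducible
    file_meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[plan.plan_id])
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RT_ION_PLAN_STORAGE
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "QA^Phantom"
    ds.PatientID = "QA"
    ds.RTPlanLabel = plan.plan_id
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    ref_beam = Dataset()
    ref_beam.ReferencedBeamNumber = 1
    ref_beam.BeamMeterset = f"{plan.total_mu:.6f}"
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfBeams = 1
    fg.ReferencedBeamSequence = [ref_beam]
    ds.FractionGroupSequence = [fg]

    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = plan.plan_id
    beam.RadiationType = "PROTON"
    beam.ScanMode = "MODULATED"
    beam.TreatmentDeliveryType = "TREATMENT"
    beam.NumberOfControlPoints = 2 * len(plan.layers)

    cps = []
    cumulative = 0.0
    for i, layer in enumerate(plan.layers):
        pos = np.asarray(layer.positions(), dtype=np.float32)
        weights = np.asarray(layer.metersets(), dtype=np.float32)

        cp_open = Dataset()
        cp_open.ControlPointIndex = 2 * i
        cp_open.NominalBeamEnergy = layer.energy
        cp_open.NumberOfScanSpotPositions = layer.n_spots
        cp_open.ScanSpotTuneID = "Standard"
        cp_open.ScanSpotPositionMap = [float(v) for v in pos.ravel()]
        cp_open.ScanSpotMetersetWeights = [float(w) for w in weights]
        cp_open.CumulativeMetersetWeight = cumulative
        if i == 0:
            cp_open.GantryAngle = plan.gantry_angle
            cp_open.GantryRotationDirection = "NONE"
        cumulative += float(np.sum(weights.astype(np.float64)))

        cp_close = Dataset()
        cp_close.ControlPointIndex = 2 * i + 1
        cp_close.NominalBeamEnergy = layer.energy
        cp_close.NumberOfScanSpotPositions = layer.n_spots
        cp_close.ScanSpotTuneID = "Standard"
        cp_close.ScanSpotPositionMap = [float(v) for v in pos.ravel()]
        cp_close.ScanSpotMetersetWeights = [0.0] * layer.n_spots
        cp_close.CumulativeMetersetWeight = cumulative
        cps.extend([cp_open, cp_close])

    # final cumulative weight = float64 sum of the float32 weights actually
    # stored, so weight -> MU conversion round-trips total_mu exactly
    beam.FinalCumulativeMetersetWeight = cumulative
    beam.IonControlPointSequence = cps
    ds.IonBeamSequence = [beam]

    ds.save_as(path, enforce_file_format=True)
    return str(path)


def _beam_metersets(ds) -> dict[int, float]:
    out = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            out[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    return out


def _read_beam(beam, beam_meterset: float, plan_id: str) -> IonPlan:
    final_cum = float(_require(beam, "FinalCumulativeMetersetWeight", "beam"))
    if final_cum == 0.0:
        raise PlanArithmeticError(
            "FinalCumulativeMetersetWeight is zero; cannot convert weights to MU"
        )
    mu_per_weight = beam_meterset / final_cum

    gantry_angle = 0.0
    layers: list[EnergyLayer] = []
    for cp in _require(beam, "IonControlPointSequence", "beam"):
        if "GantryAngle" in cp:
            gantry_angle = float(cp.GantryAngle)
        if "ScanSpotMetersetWeights" not in cp:
            continue
        weights = np.atleast_1d(np.asarray(cp.ScanSpotMetersetWeights, dtype=float))
        if not np.any(weights > 0):
            continue  # closing control point of a layer
        pos = _require(cp, "ScanSpotPositionMap", "control point")
        energy = float(_require(cp, "NominalBeamEnergy", "control point"))
        pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        if pos.shape[0] != weights.shape[0]:
            raise PlanFormatError(
                f"control point {cp.ControlPointIndex}: position map has "
                f"{pos.shape[0]} spots but {weights.shape[0]} meterset weights"
            )
        layer_index = len(layers)
        spots = [
            PlannedSpot(layer_index, j, float(x), float(y), float(w * mu_per_weight))
            for j, ((x, y), w) in enumerate(zip(pos, weights))
        ]
        layers.append(EnergyLayer(layer_index, energy, spots))

    if not layers:
        raise PlanFormatError("beam contains no control points with nonzero weights")
    return IonPlan(plan_id=plan_id, gantry_angle=gantry_angle, layers=layers)


def read_ion_plans(path) -> list[IonPlan]:
    """Read every ion beam in the file as one :class:`IonPlan` each."""
    ds = pydicom.dcmread(path)
    beams = _require(ds, "IonBeamSequence", "dataset")
    metersets = _beam_metersets(ds)
    plan_id = str(getattr(ds, "RTPlanLabel", "plan"))
    plans = []
    for beam in beams:
        number = int(_require(beam, "BeamNumber", "beam"))
        if number not in metersets:
            raise PlanFormatError(
                f"beam {number}: no BeamMeterset in any fraction group"
            )
        plans.append(_read_beam(beam, metersets[number], plan_id))
    return plans


def read_ion_plan(path, beam_number: int | None = None) -> IonPlan:
    """Read a single-beam RT Ion Plan (or select one beam of a multi-beam file)."""
    plans = read_ion_plans(path)
    if beam_number is not None:
        return plans[beam_number - 1]
    if len(plans) != 1:
        raise PlanFormatError(
            f"file contains {len(plans)} beams; pass beam_number to select one"
        )
    return plans[0]
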