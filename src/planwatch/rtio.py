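"""Readers for DICOM-RT objects and tabular cumulative-DVH exports.

Dose grids are restricted to axial, identity-oriented geometry (patient
space, mm, voxel-center convention). All doses are physical dose in Gy
after applying the file's own dose-grid scaling; no other rescaling is
performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import _dicomlite as dcm
from .exceptions import FormatError, UnsupportedOrientationError, ValidationError

log = logging.getLogger(__name__)

_IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class Technique(str, Enum):
    STATIC = "STATIC"
    DYNAMIC_MLC = "DYNAMIC_MLC"
    ARC = "ARC"


@dataclass
class DoseGrid:
    """3-D absorbed-dose array with geometry.

    ``values`` is indexed ``[z, y, x]``; ``origin`` is the patient-space
    position (x, y, z) of the first voxel center in mm; ``spacing`` is
    (dx, dy, dz) in mm.
    """

    values: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    orientation: tuple[float, ...] = _IDENTITY_ORIENTATION
    frame_of_reference: str = ""
    summation_type: str = "PLAN"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValidationError("dose grid must be a non-empty 3-D array")
        if np.any(self.values < 0):
            raise ValidationError("dose grid contains negative dose")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("dose grid spacing must be strictly positive")

    def scaled_to_plan_total(self, n_fractions: int) -> "DoseGrid":
        """Return a plan-total grid from a per-fraction one (no-op if already total)."""
        if self.summation_type != "FRACTION":
            return self
        return DoseGrid(
            self.values * n_fractions, self.origin, self.spacing,
            self.orientation, self.frame_of_reference, "PLAN",
        )


@dataclass
class Structure:
    """A named set of closed planar polygons (patient space, mm)."""

    name: str
    contours: list[np.ndarray] = field(default_factory=list)
    color: tuple[int, int, int] | None = None

    @property
    def evaluable(self) -> bool:
        return any(len(c) >= 3 for c in self.contours)

    def planes(self, decimals: int = 3) -> dict[float, list[np.ndarray]]:
        """Group contours by (rounded) z coordinate → list of (N, 2) xy arrays."""
        out: dict[float, list[np.ndarray]] = {}
        for c in self.contours:
            if len(c) < 3:
                continue
            z = round(float(np.mean(c[:, 2])), decimals)
            out.setdefault(z, []).append(np.asarray(c[:, :2], dtype=float))
        return out


@dataclass
class BeamInfo:
    id: str
    mu: float = 0.0
    dose_rate: float = 0.0
    jaw_x_width: float | None = None
    jaw_y_width: float | None = None
    isocenter: tuple[float, float, float] | None = None
    is_setup: bool = False
    couch_rotation: float = 0.0
    technique_hint: Technique = Technique.STATIC


@dataclass
class PlanInfo:
    plan_id: str
    patient_key: str = ""
    prescription_dose: float = 0.0
    n_fractions: int = 1
    beams: list[BeamInfo] = field(default_factory=list)
    is_plan_sum: bool = False

    @property
    def dose_per_fraction(self) -> float:
        return self.prescription_dose / self.n_fractions

    @property
    def treatment_beams(self) -> list[BeamInfo]:
        return [b for b in self.beams if not b.is_setup]


def _normalize_contour(points: np.ndarray) -> np.ndarray:
    """Drop a duplicated closing vertex; polygons are implicitly closed."""
    points = np.asarray(points, dtype=float)
    if len(points) > 1 and np.allclose(points[0], points[-1]):
        points = points[:-1]
    return points


def _check_modality(ds: dcm.Dataset, expected: str, path: str) -> None:
    modality = ds.get((0x0008, 0x0060), "")
    if modality != expected:
        raise FormatError(
            f"{path}: expected modality {expected}, found {modality or 'none'}"
        )


def read_rtdose(path: str) -> DoseGrid:
    """Read a DICOM RTDOSE file into a :class:`DoseGrid` (dose in Gy)."""
    ds = dcm.read_file(path)
    _check_modality(ds, "RTDOSE", path)
    scaling = ds.get((0x3004, 0x000E))
    if scaling is None:
        raise FormatError(f"{path}: RTDOSE without DoseGridScaling")
    orientation = ds.get((0x0020, 0x0037), list(_IDENTITY_ORIENTATION))
    if not np.allclose(orientation, _IDENTITY_ORIENTATION, atol=1e-6):
        raise UnsupportedOrientationError(
            f"{path}: non-axial dose grid orientation {orientation} is not supported"
        )
    rows = int(ds.require((0x0028, 0x0010), "Rows"))
    cols = int(ds.require((0x0028, 0x0011), "Columns"))
    n_frames = int(ds.get((0x0028, 0x0008), 1))
    bits = int(ds.get((0x0028, 0x0100), 32))
    if bits not in (16, 32):
        raise FormatError(f"{path}: unsupported BitsAllocated {bits}")
    raw = ds.require((0x7FE0, 0x0010), "PixelData")
    dtype = np.dtype("<u4") if bits == 32 else np.dtype("<u2")
    arr = np.frombuffer(raw, dtype=dtype, count=n_frames * rows * cols)
    values = arr.reshape(n_frames, rows, cols).astype(float) * float(scaling)

    position = ds.require((0x0020, 0x0032), "ImagePositionPatient")
    pixel_spacing = ds.require((0x0028, 0x0030), "PixelSpacing")  # [row(dy), col(dx)]
    offsets = ds.get((0x3004, 0x000C))
    if offsets is None or np.ndim(offsets) == 0 or len(offsets) < 2:
        dz = float(pixel_spacing[0])
    else:
        diffs = np.diff(np.asarray(offsets, dtype=float))
        if not np.allclose(diffs, diffs[0], atol=1e-6):
            raise FormatError(f"{path}: non-uniform GridFrameOffsetVector not supported")
        dz = float(abs(diffs[0]))
    return DoseGrid(
        values=values,
        origin=(float(position[0]), float(position[1]), float(position[2])),
        spacing=(float(pixel_spacing[1]), float(pixel_spacing[0]), dz),
        orientation=tuple(float(v) for v in orientation),
        frame_of_reference=str(ds.get((0x0020, 0x0052), "")),
        summation_type=str(ds.get((0x3004, 0x000A), "PLAN")),
    )


def read_rtstruct(path: str) -> list[Structure]:
    """Read a DICOM RTSTRUCT into a list of :class:`Structure` (names verbatim)."""
    ds = dcm.read_file(path)
    _check_modality(ds, "RTSTRUCT", path)
    names: dict[int, str] = {}
    for item in ds.get((0x3006, 0x0020), []):  # StructureSetROISequence
        number = int(item.require((0x3006, 0x0022), "ROINumber"))
        names[number] = str(item.get((0x3006, 0x0026), f"ROI_{number}"))

    structures: list[Structure] = []
    for item in ds.get((0x3006, 0x0039), []):  # ROIContourSequence
        number = int(item.require((0x3006, 0x0084), "ReferencedROINumber"))
        name = names.get(number, f"ROI_{number}")
        contours: list[np.ndarray] = []
        for contour in item.get((0x3006, 0x0040), []):  # ContourSequence
            data = contour.get((0x3006, 0x0050))
            if data is None:
                continue
            points = np.asarray(data, dtype=float).reshape(-1, 3)
            contours.append(_normalize_contour(points))
        color = item.get((0x3006, 0x002A))
        struct = Structure(
            name=name,
            contours=contours,
            color=tuple(int(c) for c in color) if color is not None else None,
        )
        if not contours:
            log.warning("ROI %r has no geometric contours", name)
        elif not struct.evaluable:
            log.warning("ROI %r has only degenerate contours (<3 points)", name)
        structures.append(struct)
    return structures


def _beam_technique(beam_type: str, rotation_direction: str) -> Technique:
    if rotation_direction and rotation_direction != "NONE":
        return Technique.ARC
    if beam_type == "DYNAMIC":
        return Technique.DYNAMIC_MLC
    return Technique.STATIC


def read_rtplan(path: str) -> PlanInfo:
    """Read a DICOM RTPLAN into a :class:`PlanInfo`.

    The total prescription dose is taken as (dose per fraction from the
    first fraction group's dose reference) x NumberOfFractionsPlanned;
    the writer stores the per-fraction target dose there.
    """
    ds = dcm.read_file(path)
    _check_modality(ds, "RTPLAN", path)
    fraction_groups = ds.get((0x300A, 0x0070), [])
    if not fraction_groups:
        raise FormatError(f"{path}: RTPLAN without a fraction group")
    fg = fraction_groups[0]
    n_fractions = int(fg.get((0x300A, 0x0078), 1))

    mu_by_beam: dict[int, float] = {}
    for ref in fg.get((0x300C, 0x0004), []):  # ReferencedBeamSequence
        number = int(ref.require((0x300C, 0x0006), "ReferencedBeamNumber"))
        mu_by_beam[number] = float(ref.get((0x300A, 0x0086), 0.0))

    dose_refs = ds.get((0x300A, 0x0010), [])
    dose_per_fraction = 0.0
    if dose_refs:
        dose_per_fraction = float(dose_refs[0].get((0x300A, 0x0026), 0.0))

    beams: list[BeamInfo] = []
    for beam in ds.get((0x300A, 0x00B0), []):  # BeamSequence
        number = int(beam.get((0x300A, 0x00C0), len(beams) + 1))
        delivery = str(beam.get((0x300A, 0x00CE), "TREATMENT"))
        beam_type = str(beam.get((0x300A, 0x00C4), "STATIC"))
        dose_rate = 0.0
        isocenter = None
        couch = 0.0
        jaw_x = jaw_y = None
        rotation_direction = "NONE"
        cps = beam.get((0x300A, 0x0111), [])  # ControlPointSequence
        if cps:
            cp = cps[0]
            dose_rate = float(cp.get((0x300A, 0x0115), 0.0))
            iso = cp.get((0x300A, 0x012C))
            if iso is not None:
                isocenter = (float(iso[0]), float(iso[1]), float(iso[2]))
            couch = float(cp.get((0x300A, 0x0122), 0.0))
            rotation_direction = str(cp.get((0x300A, 0x011F), "NONE"))
            for jaws in cp.get((0x300A, 0x011A), []):  # BeamLimitingDevicePositionSequence
                kind = str(jaws.get((0x300A, 0x00B8), ""))
                pos = jaws.get((0x300A, 0x011C))
                if pos is None or np.ndim(pos) == 0 or len(pos) < 2:
                    continue
                width = float(pos[1]) - float(pos[0])
                if kind in ("X", "ASYMX"):
                    jaw_x = width
                elif kind in ("Y", "ASYMY"):
                    jaw_y = width
        if couch > 180.0:
            couch -= 360.0
        beams.append(BeamInfo(
            id=str(beam.get((0x300A, 0x00C2), f"beam{number}")),
            mu=mu_by_beam.get(number, 0.0),
            dose_rate=dose_rate,
            jaw_x_width=jaw_x,
            jaw_y_width=jaw_y,
            isocenter=isocenter,
            is_setup=(delivery == "SETUP"),
            couch_rotation=couch,
            technique_hint=_beam_technique(beam_type, rotation_direction),
        ))

    plan = PlanInfo(
        plan_id=str(ds.get((0x300A, 0x0002), "plan")),
        patient_key=str(ds.get((0x0010, 0x0020), "")),
        prescription_dose=dose_per_fraction * n_fractions,
        n_fractions=n_fractions,
        beams=beams,
    )
    if plan.prescription_dose <= 0:
        raise FormatError(f"{path}: RTPLAN without a positive prescription dose")
    return plan


def read_dvh_table(path: str) -> list:
    """Read a long-format cumulative DVH CSV into a list of DVHCurve.

    Expected header: ``structure,dose_gy,volume_pct,volume_cc`` (volume_cc
    may be blank throughout for a structure, in which case absolute-volume
    metrics are unavailable for it).
    """
    from .dvhcore import DVHCurve  # local import to avoid cycle

    df = pd.read_csv(path)
    required = {"structure", "dose_gy", "volume_pct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_cc = "volume_cc" in df.columns

    curves = []
    for name, grp in df.groupby("structure", sort=False):
        grp = grp.sort_values("dose_gy")
        dose = grp["dose_gy"].to_numpy(dtype=float)
        vol_pct = grp["volume_pct"].to_numpy(dtype=float)
        if np.any(np.diff(vol_pct) > 1e-9):
            raise ValidationError(
                f"{path}: cumulative volume not monotone non-increasing for "
                f"structure {name!r}"
            )
        vol_cc = None
        total_cc = None
        if has_cc and grp["volume_cc"].notna().all():
            vol_cc = grp["volume_cc"].to_numpy(dtype=float)
            total_cc = float(vol_cc[0])
        bin_width = float(np.median(np.diff(dose))) if len(dose) > 1 else 0.0
        curves.append(DVHCurve(
            structure_name=str(name),
            dose_bins=dose,
            cum_volume_pct=vol_pct,
            cum_volume_cc=vol_cc,
            total_volume_cc=total_cc,
            bin_width=bin_width,
        ))
    return curves
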