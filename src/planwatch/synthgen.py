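"""Synthetic fixtures: box phantoms with analytically exact DVH metrics,
and seeded community plan libraries with specified metric distributions.

Box (axis-aligned) geometry keeps every DVH metric analytically exact,
which matters more for testing than anatomical realism. All randomness is
driven by a single seed per spec; outputs are byte-identical across runs.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from . import _dicomlite as dcm
from .dvhcore import MetricKind, parse_metric
from .exceptions import ValidationError
from .planlib import PlanRecord, write_library

Extent = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

SOP_RTDOSE = "1.2.840.10008.5.1.4.1.1.481.2"
SOP_RTSTRUCT = "1.2.840.10008.5.1.4.1.1.481.3"
SOP_RTPLAN = "1.2.840.10008.5.1.4.1.1.481.5"


def _uid(*parts) -> str:
    digest = hashlib.sha256("/".join(str(p) for p in parts).encode()).hexdigest()
    return "2.25." + str(int(digest[:30], 16))


@dataclass
class BeamSpec:
    name: str = "beam"
    mu: float = 200.0
    dose_rate: float = 600.0
    jaw_x: tuple[float, float] = (-50.0, 50.0)
    jaw_y: tuple[float, float] = (-50.0, 50.0)
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_setup: bool = False
    couch_rotation: float = 0.0
    beam_type: str = "STATIC"          # STATIC | DYNAMIC
    gantry_direction: str = "NONE"     # NONE | CW | CC


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (10, 20, 20)          # (nz, ny, nx)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # (dx, dy, dz) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    regions: list[tuple[Extent, float]] = field(default_factory=list)
    structures: list[tuple[str, Extent]] = field(default_factory=list)
    prescription_per_fraction: float = 5.2
    n_fractions: int = 5
    beams: list[BeamSpec] = field(default_factory=lambda: [BeamSpec()])
    patient_id: str = "PHANTOM"
    plan_id: str = "synth_plan"
    metrics: list[str] = field(default_factory=lambda: ["Dmean[Gy]", "Dmax[Gy]"])
    seed: int = 0


def _voxel_centers(n: int, origin: float, pitch: float) -> np.ndarray:
    return origin + pitch * np.arange(n)


def _dose_values(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    x0, y0, z0 = spec.origin
    xs = _voxel_centers(nx, x0, dx)
    ys = _voxel_centers(ny, y0, dy)
    zs = _voxel_centers(nz, z0, dz)
    values = np.zeros((nz, ny, nx))
    for (xr, yr, zr), dose in spec.regions:  # later region wins
        mx = (xs >= xr[0]) & (xs <= xr[1])
        my = (ys >= yr[0]) & (ys <= yr[1])
        mz = (zs >= zr[0]) & (zs <= zr[1])
        values[np.ix_(mz, my, mx)] = dose
    return values


# ---------------------------------------------------------------------------
# analytic oracle: exact piecewise-constant dose over a box partition

def _analytic_fractions(spec: PhantomSpec, extent: Extent) -> list[tuple[float, float]]:
    """Exact (dose, volume fraction) pairs for a box structure."""

    def cuts(axis: int) -> np.ndarray:
        lo, hi = extent[axis]
        points = {lo, hi}
        for (region, _dose) in spec.regions:
            for v in region[axis]:
                if lo < v < hi:
                    points.add(v)
        return np.array(sorted(points))

    xs, ys, zs = cuts(0), cuts(1), cuts(2)
    total = (extent[0][1] - extent[0][0]) * (extent[1][1] - extent[1][0]) * \
            (extent[2][1] - extent[2][0])
    if total <= 0:
        raise ValidationError("structure extent has zero volume")
    frac_by_dose: dict[float, float] = {}
    for i in range(len(xs) - 1):
        for j in range(len(ys) - 1):
            for k in range(len(zs) - 1):
                cx = (xs[i] + xs[i + 1]) / 2
                cy = (ys[j] + ys[j + 1]) / 2
                cz = (zs[k] + zs[k + 1]) / 2
                dose = 0.0
                for (xr, yr, zr), d in spec.regions:  # later region wins
                    if xr[0] <= cx <= xr[1] and yr[0] <= cy <= yr[1] \
                            and zr[0] <= cz <= zr[1]:
                        dose = d
                vol = (xs[i + 1] - xs[i]) * (ys[j + 1] - ys[j]) * (zs[k + 1] - zs[k])
                frac_by_dose[dose] = frac_by_dose.get(dose, 0.0) + vol / total
    return sorted(frac_by_dose.items())


def analytic_metric(spec: PhantomSpec, extent: Extent, metric: str) -> float:
    """Exact metric value for a box structure under the piecewise-constant dose."""
    fractions = _analytic_fractions(spec, extent)
    m = parse_metric(metric)
    doses = np.array([d for d, _ in fractions])
    fracs = np.array([f for _, f in fractions])
    if m.kind == MetricKind.V_DOSE:
        pct = float(100.0 * fracs[doses >= m.threshold].sum())
        if m.unit_out.value == "cc":
            total_cc = (
                (extent[0][1] - extent[0][0]) * (extent[1][1] - extent[1][0])
                * (extent[2][1] - extent[2][0]) / 1000.0
            )
            return pct / 100.0 * total_cc
        return pct
    if m.kind == MetricKind.DMEAN:
        return float(np.sum(doses * fracs))
    if m.kind == MetricKind.DMAX:
        return float(doses.max())
    if m.kind == MetricKind.DMIN:
        return float(doses.min())
    if m.kind == MetricKind.D_VOLPCT:
        # lowest dose achieving the volume (matches the tie rule of the DVH
        # engine's inverse lookup): smallest dose level d such that the
        # volume strictly above d is <= the requested volume
        order = np.argsort(doses)
        for dose in doses[order]:
            above = float(fracs[doses > dose].sum()) * 100.0
            if above <= m.threshold + 1e-12:
                return float(dose)
        return float(doses.max())
    raise ValidationError(f"analytic oracle does not support metric {metric!r}")


# ---------------------------------------------------------------------------
# DICOM writers

def _common(ds: dcm.Dataset, spec: PhantomSpec, modality: str) -> None:
    ds.set((0x0008, 0x0060), "CS", modality)
    ds.set((0x0010, 0x0010), "PN", spec.patient_id)
    ds.set((0x0010, 0x0020), "LO", spec.patient_id)
    ds.set((0x0020, 0x0052), "UI", _uid(spec.seed, "frame"))


def _write_rtdose(spec: PhantomSpec, path: str) -> None:
    values = _dose_values(spec)
    nz, ny, nx = values.shape
    dmax = float(values.max())
    scaling = (dmax / (2 ** 31 - 1)) if dmax > 0 else 1e-6
    stored = np.round(values / scaling).astype("<u4")

    ds = dcm.Dataset()
    _common(ds, spec, "RTDOSE")
    ds.set((0x0008, 0x0016), "UI", SOP_RTDOSE)
    ds.set((0x0008, 0x0018), "UI", _uid(spec.seed, "dose"))
    ds.set((0x0028, 0x0002), "US", 1)
    ds.set((0x0028, 0x0008), "IS", nz)
    ds.set((0x0028, 0x0010), "US", ny)
    ds.set((0x0028, 0x0011), "US", nx)
    ds.set((0x0028, 0x0030), "DS", [spec.spacing[1], spec.spacing[0]])  # [dy, dx]
    ds.set((0x0028, 0x0100), "US", 32)
    ds.set((0x0028, 0x0101), "US", 32)
    ds.set((0x0028, 0x0103), "US", 0)
    ds.set((0x0020, 0x0032), "DS", list(spec.origin))
    ds.set((0x0020, 0x0037), "DS", [1, 0, 0, 0, 1, 0])
    ds.set((0x3004, 0x0002), "CS", "GY")
    ds.set((0x3004, 0x0004), "CS", "PHYSICAL")
    ds.set((0x3004, 0x000A), "CS", "PLAN")
    ds.set((0x3004, 0x000C), "DS", [spec.spacing[2] * k for k in range(nz)])
    ds.set((0x3004, 0x000E), "DS", scaling)
    ds.set((0x7FE0, 0x0010), "OW", stored.tobytes())
    dcm.write_file(path, ds, SOP_RTDOSE, _uid(spec.seed, "dose"))


def _box_contours(spec: PhantomSpec, extent: Extent) -> list[list[float]]:
    (x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi) = extent
    dz = spec.spacing[2]
    z0 = spec.origin[2]
    nz = spec.shape[0]
    contours = []
    for k in range(nz):
        z = z0 + k * dz
        if z_lo - 1e-9 <= z <= z_hi + 1e-9:
            contours.append([
                x_lo, y_lo, z, x_hi, y_lo, z, x_hi, y_hi, z, x_lo, y_hi, z,
            ])
    if not contours:
        raise ValidationError("structure extent spans no dose-grid plane")
    return contours


def _write_rtstruct(spec: PhantomSpec, path: str) -> None:
    ds = dcm.Dataset()
    _common(ds, spec, "RTSTRUCT")
    ds.set((0x0008, 0x0016), "UI", SOP_RTSTRUCT)
    ds.set((0x0008, 0x0018), "UI", _uid(spec.seed, "struct"))
    roi_seq, contour_seq = [], []
    for i, (name, extent) in enumerate(spec.structures, start=1):
        roi = dcm.Dataset()
        roi.set((0x3006, 0x0022), "IS", i)
        roi.set((0x3006, 0x0026), "LO", name)
        roi_seq.append(roi)
        rc = dcm.Dataset()
        rc.set((0x3006, 0x0084), "IS", i)
        rc.set((0x3006, 0x002A), "IS", [255, 0, 0])
        items = []
        for data in _box_contours(spec, extent):
            c = dcm.Dataset()
            c.set((0x3006, 0x0042), "CS", "CLOSED_PLANAR")
            c.set((0x3006, 0x0046), "IS", len(data) // 3)
            c.set((0x3006, 0x0050), "DS", data)
            items.append(c)
        rc.set((0x3006, 0x0040), "SQ", items)
        contour_seq.append(rc)
    ds.set((0x3006, 0x0020), "SQ", roi_seq)
    ds.set((0x3006, 0x0039), "SQ", contour_seq)
    dcm.write_file(path, ds, SOP_RTSTRUCT, _uid(spec.seed, "struct"))


def _write_rtplan(spec: PhantomSpec, path: str) -> None:
    ds = dcm.Dataset()
    _common(ds, spec, "RTPLAN")
    ds.set((0x0008, 0x0016), "UI", SOP_RTPLAN)
    ds.set((0x0008, 0x0018), "UI", _uid(spec.seed, "plan"))
    ds.set((0x300A, 0x0002), "SH", spec.plan_id)

    dose_ref = dcm.Dataset()
    dose_ref.set((0x300A, 0x0026), "DS", spec.prescription_per_fraction)
    ds.set((0x300A, 0x0010), "SQ", [dose_ref])

    beam_items, ref_items = [], []
    for number, b in enumerate(spec.beams, start=1):
        beam = dcm.Dataset()
        beam.set((0x300A, 0x00C0), "IS", number)
        beam.set((0x300A, 0x00C2), "LO", b.name)
        beam.set((0x300A, 0x00C4), "CS", b.beam_type)
        beam.set((0x300A, 0x00CE), "CS", "SETUP" if b.is_setup else "TREATMENT")
        cp = dcm.Dataset()
        cp.set((0x300A, 0x0115), "DS", b.dose_rate)
        cp.set((0x300A, 0x0122), "DS", b.couch_rotation % 360.0)
        cp.set((0x300A, 0x011F), "CS", b.gantry_direction)
        cp.set((0x300A, 0x012C), "DS", list(b.isocenter))
        jx = dcm.Dataset()
        jx.set((0x300A, 0x00B8), "CS", "ASYMX")
        jx.set((0x300A, 0x011C), "DS", list(b.jaw_x))
        jy = dcm.Dataset()
        jy.set((0x300A, 0x00B8), "CS", "ASYMY")
        jy.set((0x300A, 0x011C), "DS", list(b.jaw_y))
        cp.set((0x300A, 0x011A), "SQ", [jx, jy])
        beam.set((0x300A, 0x0110), "IS", 2)
        beam.set((0x300A, 0x0111), "SQ", [cp])
        beam_items.append(beam)
        if not b.is_setup:
            ref = dcm.Dataset()
            ref.set((0x300C, 0x0006), "IS", number)
            ref.set((0x300A, 0x0086), "DS", b.mu)
            ref_items.append(ref)
    fg = dcm.Dataset()
    fg.set((0x300A, 0x0078), "IS", spec.n_fractions)
    fg.set((0x300C, 0x0004), "SQ", ref_items)
    ds.set((0x300A, 0x0070), "SQ", [fg])
    ds.set((0x300A, 0x00B0), "SQ", beam_items)
    dcm.write_file(path, ds, SOP_RTPLAN, _uid(spec.seed, "plan"))


def make_phantom(spec: PhantomSpec, out_dir) -> dict[str, str]:
    """Write RTDOSE/RTSTRUCT/RTPLAN + the analytic metric table.

    Returns a dict of paths: rtdose, rtstruct, rtplan, analytic. The table
    (``structure,metric,value`` CSV) holds the exact geometric values and
    is the oracle for the DVH engine's tests.
    """
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "rtdose": os.path.join(out_dir, "rtdose.dcm"),
        "rtstruct": os.path.join(out_dir, "rtstruct.dcm"),
        "rtplan": os.path.join(out_dir, "rtplan.dcm"),
        "analytic": os.path.join(out_dir, "analytic.csv"),
    }
    _write_rtdose(spec, paths["rtdose"])
    _write_rtstruct(spec, paths["rtstruct"])
    _write_rtplan(spec, paths["rtplan"])
    with open(paths["analytic"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure", "metric", "value"])
        for name, extent in spec.structures:
            for metric in spec.metrics:
                writer.writerow([name, metric, repr(analytic_metric(spec, extent, metric))])
    return paths


def read_analytic_table(path: str) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out[(row["structure"], row["metric"])] = float(row["value"])
    return out


# ---------------------------------------------------------------------------
# community library generation

@dataclass
class MetricDist:
    """One metric column: normal / lognormal / uniform draws.

    ``force_above`` = (cut, count) adjusts the draws so that exactly
    *count* values are strictly greater than *cut* (the rest are clamped
    to at most *cut*). ``shift_at`` = (index, delta) adds *delta* to all
    values from *index* on (change-detection harness).
    """

    dist: str = "normal"
    mu: float = 0.0
    sigma: float = 1.0
    lo: float = 0.0
    hi: float = 1.0
    force_above: tuple[float, int] | None = None
    shift_at: tuple[int, float] | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            values = rng.normal(self.mu, self.sigma, n)
        elif self.dist == "lognormal":
            values = rng.lognormal(self.mu, self.sigma, n)
        elif self.dist == "uniform":
            values = rng.uniform(self.lo, self.hi, n)
        else:
            raise ValidationError(f"unknown distribution {self.dist!r}")
        if self.shift_at is not None:
            index, delta = self.shift_at
            values[index:] += delta
        if self.force_above is not None:
            cut, count = self.force_above
            if count > n:
                raise ValidationError("force_above count exceeds record count")
            spread = abs(self.sigma) or 1.0
            values = np.minimum(values, cut)
            chosen = rng.choice(n, size=count, replace=False)
            values[chosen] = cut + spread * (0.1 + rng.random(count))
        return values


@dataclass
class LibrarySpec:
    n: int = 50
    seed: int = 0
    protocol: str = "FAST_FORWARD"
    users: list[tuple[str, float]] = field(default_factory=lambda: [("userA", 1.0)])
    laterality_mix: dict[str, float] = field(default_factory=lambda: {"RIGHT": 1.0})
    technique_mix: dict[str, float] = field(default_factory=lambda: {"VMAT": 1.0})
    boost_fraction: float = 0.0
    nodes_fraction: float = 0.0
    bh_fraction: float = 0.0
    metrics: dict[str, MetricDist] = field(default_factory=dict)
    mu_sum: MetricDist = field(
        default_factory=lambda: MetricDist("normal", mu=400.0, sigma=40.0)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("library needs at least one record")


def _categorical(rng: np.random.Generator, mix: dict[str, float], n: int) -> list[str]:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return [keys[i] for i in rng.choice(len(keys), size=n, p=probs)]


def make_records(spec: LibrarySpec) -> list[PlanRecord]:
    """Generate the records of a synthetic library (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    users = _categorical(rng, dict(spec.users), n)
    lats = _categorical(rng, spec.laterality_mix, n)
    techs = _categorical(rng, spec.technique_mix, n)
    boost = rng.random(n) < spec.boost_fraction
    nodes = rng.random(n) < spec.nodes_fraction
    bh = rng.random(n) < spec.bh_fraction
    metric_values = {name: d.draw(rng, n) for name, d in spec.metrics.items()}
    mu_sums = spec.mu_sum.draw(rng, n)
    base = datetime(2024, 1, 1, 8, 0, 0)

    for name, d in spec.metrics.items():
        if d.dist == "normal" and d.force_above is None and d.shift_at is None and n >= 2:
            err = abs(float(metric_values[name].mean()) - d.mu)
            if err > 4.0 * d.sigma / np.sqrt(n):
                raise ValidationError(
                    f"self-check failed: {name} sample mean off by {err:g}"
                )

    records = []
    for i in range(n):
        records.append(PlanRecord(
            timestamp=(base + timedelta(minutes=10 * i)).isoformat(),
            user=users[i],
            patient_key=f"pk{spec.seed:04d}{i:04d}",
            plan_id=f"plan{i:04d}",
            protocol=spec.protocol,
            laterality=lats[i],
            has_boost=bool(boost[i]),
            has_nodes=bool(nodes[i]),
            breast_modifier="NONE",
            technique=techs[i],
            technique_modifiers=frozenset({"BH"}) if bh[i] else frozenset(),
            bolus="NONE",
            mu_sum=float(np.round(mu_sums[i], 1)),
            bw_score=int(rng.integers(60, 101)),
            metrics={k: float(np.round(v[i], 4)) for k, v in metric_values.items()},
        ))
    return records


def make_library(spec: LibrarySpec, out_path: str) -> str:
    """Write a schema-valid library CSV for *spec*; returns the path."""
    write_library(out_path, make_records(spec))
    return out_path
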