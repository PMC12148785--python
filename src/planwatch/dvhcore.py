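"""Cumulative DVH computation and dose-metric evaluation.

The DVH is built by classifying (optionally supersampled) voxel centers
with an even-odd point-in-polygon test against the structure's contours
on the nearest contour plane (plane-assignment tolerance dz/2). Inner
contours therefore subtract (holes), matching standard RTSTRUCT practice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np
from matplotlib.path import Path as MplPath

from .exceptions import FormatError, UnitError, ValidationError
from .rtio import DoseGrid, Structure

DEFAULT_BIN_WIDTH = 0.05   # Gy
DEFAULT_SUPERSAMPLE = 2    # per-axis subdivision factor


class MetricKind(str, Enum):
    V_DOSE = "V_DOSE"
    D_VOLPCT = "D_VOLPCT"
    D_VOLCC = "D_VOLCC"
    DMEAN = "DMEAN"
    DMAX = "DMAX"
    DMIN = "DMIN"


class MetricUnit(str, Enum):
    PCT = "%"
    GY = "Gy"
    CC = "cc"


@dataclass(frozen=True)
class MetricSpec:
    kind: MetricKind
    threshold: float = 0.0
    unit_out: MetricUnit = MetricUnit.PCT

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("metric threshold must be >= 0")
        if self.kind == MetricKind.V_DOSE:
            ok = self.unit_out in (MetricUnit.PCT, MetricUnit.CC)
        else:
            ok = self.unit_out == MetricUnit.GY
        if not ok:
            raise ValidationError(
                f"unit {self.unit_out.value} inconsistent with metric kind {self.kind.value}"
            )


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve: % of volume receiving >= each bin dose."""

    structure_name: str
    dose_bins: np.ndarray
    cum_volume_pct: np.ndarray
    cum_volume_cc: np.ndarray | None = None
    total_volume_cc: float | None = None
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        self.dose_bins = np.asarray(self.dose_bins, dtype=float)
        self.cum_volume_pct = np.asarray(self.cum_volume_pct, dtype=float)
        if self.dose_bins.shape != self.cum_volume_pct.shape:
            raise ValidationError("dose_bins and cum_volume_pct length mismatch")
        if np.any(np.diff(self.cum_volume_pct) > 1e-9):
            raise ValidationError(
                f"cumulative volume rises with dose for {self.structure_name!r}"
            )
        if abs(self.cum_volume_pct[0] - 100.0) > 1e-6:
            raise ValidationError(
                f"cumulative curve must start at 100% for {self.structure_name!r}"
            )


# ---------------------------------------------------------------------------
# DVH computation

def _plane_masks(polygons: list[np.ndarray], xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd membership of the (ys, xs) grid w.r.t. a set of polygons."""
    xx, yy = np.meshgrid(xs, ys)
    points = np.column_stack([xx.ravel(), yy.ravel()])
    inside = np.zeros(len(points), dtype=int)
    for poly in polygons:
        # Path(closed=True) uses the final vertex as the CLOSEPOLY slot, so
        # the ring must carry an explicit duplicate of its first vertex
        ring = np.vstack([poly, poly[:1]])
        inside += MplPath(ring, closed=True).contains_points(points)
    return (inside % 2 == 1).reshape(len(ys), len(xs))


def structure_doses(
    grid: DoseGrid, structure: Structure, supersample: int = DEFAULT_SUPERSAMPLE
) -> tuple[np.ndarray, float]:
    """Sample doses inside *structure*; returns (dose samples, cc per sample)."""
    if supersample < 1:
        raise ValidationError("supersample factor must be >= 1")
    if not structure.evaluable:
        raise ValidationError(f"structure {structure.name!r} has no valid polygon")
    nz, ny, nx = grid.values.shape
    dx, dy, dz = grid.spacing
    x0, y0, z0 = grid.origin
    s = supersample

    xs = x0 + dx * ((np.arange(nx * s) + 0.5) / s - 0.5)
    ys = y0 + dy * ((np.arange(ny * s) + 0.5) / s - 0.5)
    zs = z0 + dz * ((np.arange(nz * s) + 0.5) / s - 0.5)

    planes = structure.planes()
    plane_zs = np.array(sorted(planes))
    # nearest-plane assignment with tolerance dz/2
    nearest = plane_zs[np.argmin(np.abs(zs[:, None] - plane_zs[None, :]), axis=1)]
    in_tol = np.abs(zs - nearest) <= dz / 2 + 1e-9

    doses: list[np.ndarray] = []
    mask_cache: dict[float, np.ndarray] = {}
    for k in np.nonzero(in_tol)[0]:
        zp = float(nearest[k])
        if zp not in mask_cache:
            polys = [p for p in planes[zp] if len(p) >= 3]
            mask_cache[zp] = _plane_masks(polys, xs, ys)
        mask = mask_cache[zp]
        if not mask.any():
            continue
        slab = grid.values[k // s]  # (ny, nx) voxel doses
        expanded = np.repeat(np.repeat(slab, s, axis=0), s, axis=1)
        doses.append(expanded[mask])
    if not doses:
        raise ValidationError(
            f"structure {structure.name!r} has no dose coverage on the grid"
        )
    sample_cc = (dx * dy * dz) / (s ** 3) / 1000.0
    return np.concatenate(doses), sample_cc


def compute_dvh(
    grid: DoseGrid,
    structure: Structure,
    bin_width: float = DEFAULT_BIN_WIDTH,
    supersample: int = DEFAULT_SUPERSAMPLE,
) -> DVHCurve:
    """Compute the cumulative DVH of *structure* on *grid*."""
    samples, sample_cc = structure_doses(grid, structure, supersample)
    n = len(samples)
    dmax = float(samples.max())
    n_bins = int(np.floor(dmax / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width  # covers [0, dmax + bin_width)
    counts, _ = np.histogram(samples, bins=np.append(edges, edges[-1] + bin_width))
    # cum[k] = fraction of samples with dose >= edges[k]
    above = n - np.concatenate([[0], np.cumsum(counts[:-1])])
    cum_pct = 100.0 * above[: n_bins + 1] / n
    total_cc = n * sample_cc
    return DVHCurve(
        structure_name=structure.name,
        dose_bins=edges,
        cum_volume_pct=cum_pct,
        cum_volume_cc=cum_pct / 100.0 * total_cc,
        total_volume_cc=total_cc,
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# metric evaluation

def _dose_at_volume_pct(curve: DVHCurve, vol_pct: float) -> float:
    dose, cum = curve.dose_bins, curve.cum_volume_pct
    if vol_pct <= 0:
        return metric_value(curve, MetricSpec(MetricKind.DMAX, unit_out=MetricUnit.GY))
    if vol_pct >= 100:
        return metric_value(curve, MetricSpec(MetricKind.DMIN, unit_out=MetricUnit.GY))
    below = np.nonzero(cum <= vol_pct + 1e-12)[0]
    if len(below) == 0:
        return float(dose[-1])
    i = below[0]
    if i == 0 or abs(cum[i] - vol_pct) < 1e-12:
        return float(dose[i])  # lowest dose achieving the volume (tie rule)
    d0, d1 = dose[i - 1], dose[i]
    c0, c1 = cum[i - 1], cum[i]
    return float(d0 + (d1 - d0) * (c0 - vol_pct) / (c0 - c1))


def metric_value(curve: DVHCurve, spec: MetricSpec, prescription: float | None = None) -> float:
    """Evaluate *spec* on *curve*; result in ``spec.unit_out``."""
    dose, cum = curve.dose_bins, curve.cum_volume_pct
    kind = spec.kind

    if kind == MetricKind.V_DOSE:
        pct = float(np.interp(spec.threshold, dose, cum, right=0.0))
        if spec.unit_out == MetricUnit.PCT:
            return pct
        if curve.total_volume_cc is None:
            raise UnitError(
                f"absolute volume unavailable for {curve.structure_name!r}; "
                "cannot report V in cc"
            )
        return pct / 100.0 * curve.total_volume_cc

    if kind == MetricKind.D_VOLPCT:
        return _dose_at_volume_pct(curve, spec.threshold)

    if kind == MetricKind.D_VOLCC:
        if curve.total_volume_cc is None:
            raise UnitError(
                f"absolute volume unavailable for {curve.structure_name!r}; "
                "cannot evaluate D at a cc threshold"
            )
        vol_pct = 100.0 * spec.threshold / curve.total_volume_cc
        return _dose_at_volume_pct(curve, min(vol_pct, 100.0))

    if kind == MetricKind.DMEAN:
        diff = cum[:-1] - cum[1:]
        total = cum[0] - cum[-1]
        if len(dose) < 2 or total <= 0:
            return float(dose[-1] + curve.bin_width / 2.0)
        centers = (dose[:-1] + dose[1:]) / 2.0
        # volume remaining beyond the last edge sits in one extra half-bin
        tail = cum[-1]
        mean = float(np.sum(centers * diff) + tail * (dose[-1] + curve.bin_width / 2.0))
        return mean / cum[0]

    if kind == MetricKind.DMAX:
        nonzero = np.nonzero(cum > 1e-12)[0]
        i = int(nonzero[-1]) if len(nonzero) else 0
        return float(dose[i] + curve.bin_width / 2.0)  # bin-center convention

    if kind == MetricKind.DMIN:
        below = np.nonzero(cum < 100.0 - 1e-9)[0]
        if len(below) == 0:
            return float(dose[-1] + curve.bin_width / 2.0)
        i = max(int(below[0]) - 1, 0)
        return float(dose[i] + curve.bin_width / 2.0)

    raise ValidationError(f"unknown metric kind {kind!r}")


# ---------------------------------------------------------------------------
# metric grammar

_GRAMMAR = (
    "V<dose>Gy[%|cc] | D<vol>%[Gy] | D<vol>cc[Gy] | Dmean[Gy] | Dmax[Gy] | Dmin[Gy]"
)

_NUM = r"(\d+(?:\.\d+)?)"
_V_RE = re.compile(rf"^V{_NUM}GY(?:\[(%|CC)\])?$", re.IGNORECASE)
_D_RE = re.compile(rf"^D{_NUM}(%|CC)(?:\[GY\])?$", re.IGNORECASE)
_DSTAT_RE = re.compile(r"^D(MEAN|MAX|MIN)(?:\[GY\])?$", re.IGNORECASE)


def parse_metric(text: str) -> MetricSpec:
    """Parse a metric-grammar string like ``V3Gy[%]`` or ``Dmean[Gy]``."""
    compact = re.sub(r"\s+", "", text)
    m = _V_RE.match(compact)
    if m:
        unit = MetricUnit.CC if (m.group(2) or "%").lower() == "cc" else MetricUnit.PCT
        return MetricSpec(MetricKind.V_DOSE, float(m.group(1)), unit)
    m = _D_RE.match(compact)
    if m:
        kind = MetricKind.D_VOLCC if m.group(2).lower() == "cc" else MetricKind.D_VOLPCT
        return MetricSpec(kind, float(m.group(1)), MetricUnit.GY)
    m = _DSTAT_RE.match(compact)
    if m:
        kind = {"MEAN": MetricKind.DMEAN, "MAX": MetricKind.DMAX, "MIN": MetricKind.DMIN}[
            m.group(1).upper()
        ]
        return MetricSpec(kind, 0.0, MetricUnit.GY)
    raise FormatError(f"cannot parse metric {text!r}; grammar: {_GRAMMAR}")


def _fmt_num(v: float) -> str:
    return f"{v:g}"


def format_metric(spec: MetricSpec) -> str:
    """Canonical string for *spec*; ``parse_metric(format_metric(s)) == s``."""
    if spec.kind == MetricKind.V_DOSE:
        return f"V{_fmt_num(spec.threshold)}Gy[{spec.unit_out.value}]"
    if spec.kind == MetricKind.D_VOLPCT:
        return f"D{_fmt_num(spec.threshold)}%[Gy]"
    if spec.kind == MetricKind.D_VOLCC:
        return f"D{_fmt_num(spec.threshold)}cc[Gy]"
    return {"DMEAN": "Dmean[Gy]", "DMAX": "Dmax[Gy]", "DMIN": "Dmin[Gy]"}[spec.kind.value]
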