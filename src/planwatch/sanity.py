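"""Plan Sanity Check (PSC) and community MU-Sum inspection.

Thresholds are site-configurable; the defaults below are conservative
desk values, not clinical recommendations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .planmodel import PlanProperties, PlanTechnique
from .rtio import PlanInfo
from .scoring import InspectorStats, WorseDirection, inspector_stats


@dataclass(frozen=True)
class SanityRules:
    max_isocenters: int = 1
    mu_sum_range: tuple[float, float] = (50.0, 1500.0)
    allowed_dose_rates: frozenset[float] = frozenset({400.0, 600.0})
    jaw_x_max_mm: float = 150.0
    couch_tolerance_deg: float = 0.5


@dataclass
class CheckResult:
    name: str
    status: str  # PASS | FAIL | SKIPPED
    observed: str
    expected: str


@dataclass
class SanityReport:
    checks: list[CheckResult] = field(default_factory=list)
    mu_sum: float = 0.0

    @property
    def overall(self) -> str:
        return "FAIL" if any(c.status == "FAIL" for c in self.checks) else "PASS"


def mu_sum(plan: PlanInfo) -> float:
    """Algebraic sum of treatment-beam MUs (setup beams excluded)."""
    return float(sum(b.mu for b in plan.treatment_beams))


def sanity_check(
    plan: PlanInfo,
    properties: PlanProperties | None = None,
    rules: SanityRules | None = None,
) -> SanityReport:
    """Run the PSC: isocenters, MU-Sum, dose rates, jaws, setup-beam couch.

    Findings are FAIL statuses, never exceptions. Plan Sums (and dose-only
    plans) have no beams, so every beam-level check is SKIPPED.
    """
    rules = rules or SanityRules()
    report = SanityReport()
    beams = plan.treatment_beams

    if plan.is_plan_sum or not plan.beams:
        reason = "plan sum" if plan.is_plan_sum else "no beams"
        for name in ("isocenters", "mu_sum", "dose_rate", "jaw_x", "setup_couch"):
            report.checks.append(CheckResult(name, "SKIPPED", reason, "n/a"))
        return report

    report.mu_sum = mu_sum(plan)

    isocenters = {
        tuple(np.round(b.isocenter, 1)) for b in beams if b.isocenter is not None
    }
    report.checks.append(CheckResult(
        "isocenters",
        "PASS" if len(isocenters) <= rules.max_isocenters else "FAIL",
        str(len(isocenters)),
        f"<= {rules.max_isocenters}",
    ))

    lo, hi = rules.mu_sum_range
    report.checks.append(CheckResult(
        "mu_sum",
        "PASS" if lo <= report.mu_sum <= hi else "FAIL",
        f"{report.mu_sum:g}",
        f"in [{lo:g}, {hi:g}]",
    ))

    bad_rates = sorted({b.dose_rate for b in beams} - set(rules.allowed_dose_rates))
    report.checks.append(CheckResult(
        "dose_rate",
        "PASS" if not bad_rates else "FAIL",
        ", ".join(f"{r:g}" for r in bad_rates) or "all allowed",
        f"in {sorted(rules.allowed_dose_rates)}",
    ))

    modulated = properties is not None and properties.technique in (
        PlanTechnique.IMRT, PlanTechnique.VMAT, PlanTechnique.HYBRID
    )
    if modulated:
        widths = [b.jaw_x_width for b in beams if b.jaw_x_width is not None]
        too_wide = [w for w in widths if w > rules.jaw_x_max_mm]
        report.checks.append(CheckResult(
            "jaw_x",
            "PASS" if not too_wide else "FAIL",
            ", ".join(f"{w:g}" for w in (too_wide or widths)) or "none",
            f"<= {rules.jaw_x_max_mm:g} mm",
        ))
    else:
        report.checks.append(CheckResult(
            "jaw_x", "SKIPPED", "not IMRT/VMAT", f"<= {rules.jaw_x_max_mm:g} mm"
        ))

    setup = [b for b in plan.beams if b.is_setup]
    if setup:
        bad_couch = [b.couch_rotation for b in setup
                     if abs(b.couch_rotation) > rules.couch_tolerance_deg]
        report.checks.append(CheckResult(
            "setup_couch",
            "PASS" if not bad_couch else "FAIL",
            ", ".join(f"{c:g}" for c in (bad_couch or [0.0])),
            f"0 deg +/- {rules.couch_tolerance_deg:g}",
        ))
    else:
        report.checks.append(CheckResult(
            "setup_couch", "SKIPPED", "no setup beams",
            f"0 deg +/- {rules.couch_tolerance_deg:g}",
        ))
    return report


def mu_sum_inspect(mu_sum_value: float, library_mu_sums: list[float]) -> InspectorStats:
    """Compare a plan's MU-Sum with similarity-filtered community MU-Sums.

    Higher MU-Sum means higher modulation complexity, so greater is worse.
    """
    return inspector_stats(
        library_mu_sums, mu_sum_value, WorseDirection.GREATER_IS_WORSE
    )


def parse_sanity_rules(text: str) -> SanityRules:
    """Parse a ``[sanity]`` key=value section from a preferences file."""
    values: dict[str, str] = {}
    in_section = False
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            in_section = line == "[sanity]"
            continue
        if in_section and "=" in line:
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    kwargs: dict = {}
    if "max_isocenters" in values:
        kwargs["max_isocenters"] = int(values["max_isocenters"])
    if "mu_sum_range" in values:
        lo, hi = (float(v) for v in values["mu_sum_range"].split(","))
        kwargs["mu_sum_range"] = (lo, hi)
    if "allowed_dose_rates" in values:
        kwargs["allowed_dose_rates"] = frozenset(
            float(v) for v in values["allowed_dose_rates"].split(",")
        )
    if "jaw_x_max_mm" in values:
        kwargs["jaw_x_max_mm"] = float(values["jaw_x_max_mm"])
    if "couch_tolerance_deg" in values:
        kwargs["couch_tolerance_deg"] = float(values["couch_tolerance_deg"])
    return SanityRules(**kwargs)
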