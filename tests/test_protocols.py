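import itertools

import numpy as np
import pytest

from planwatch import protocols
from planwatch.dvhcore import DVHCurve, parse_metric
from planwatch.exceptions import NoMatchError, ValidationError
from planwatch.planmodel import Laterality, PlanProperties, StructureMapping, RoleAssignment
from planwatch.protocols import (
    Comparator, ConstraintGroup, DoseConstraint, Status,
    evaluate_constraint, evaluate_plan, format_protocol, load_all_protocols,
    load_protocol, parse_protocol, select_protocol,
)
from planwatch.rtio import PlanInfo


def plan(total_gy, n_fx):
    return PlanInfo("p", prescription_dose=total_gy, n_fractions=n_fx)


class TestSelection:
    def test_fast_forward(self):
        assert select_protocol(plan(26.0, 5), 1).name == "FAST_FORWARD"

    def test_fast(self):
        assert select_protocol(plan(28.5, 5), 1).name == "FAST"

    def test_no_match_lists_rules(self):
        with pytest.raises(NoMatchError, match="FAST_FORWARD"):
            select_protocol(plan(33.0, 7), 1)

    def test_rtog_both_arms(self):
        assert select_protocol(plan(40.0, 15), 2).name == "RTOG1005"
        assert select_protocol(plan(50.0, 25), 2).name == "RTOG1005"

    def test_europa_arms(self):
        assert select_protocol(plan(30.0, 5), 1).name == "EUROPA_PBI"
        assert select_protocol(plan(40.05, 15), 1).name == "EUROPA_WBI"

    def test_override_wins(self):
        assert select_protocol(plan(26.0, 5), 1, override="FAST").name == "FAST"

    def test_shipped_rules_pairwise_disjoint(self):
        shipped = load_all_protocols()
        for dpf in np.arange(1.0, 7.01, 0.05):
            for n_fx, n_ptvs in itertools.product((5, 15, 16, 23, 24, 25), (1, 2, 3)):
                matches = [
                    p.name for p in shipped
                    if p.matches(round(float(dpf), 2), n_fx, n_ptvs)
                ]
                assert len(matches) <= 1, (dpf, n_fx, n_ptvs, matches)


class TestEvaluateConstraint:
    def c(self, mandatory=20.0, optimal=None, cmp=Comparator.LE, extra=False):
        return DoseConstraint(
            role="LUNG_IPSI", metric=parse_metric("V16Gy[%]"), comparator=cmp,
            mandatory_limit=mandatory, optimal_limit=optimal, is_extra=extra,
            group=ConstraintGroup.MAIN_OAR,
        )

    def test_value_below_le_limit_green(self):
        assert evaluate_constraint(15.0, self.c()).status == Status.GREEN

    def test_mandatory_violation_red(self):
        heart = DoseConstraint(
            role="HEART", metric=parse_metric("Dmean[Gy]"), comparator=Comparator.LE,
            mandatory_limit=2.0, is_extra=True, group=ConstraintGroup.MAIN_OAR,
        )
        result = evaluate_constraint(2.4, heart)
        assert result.status == Status.RED
        assert result.display_tier == "EXTRA"

    def test_inclusive_boundary_green(self):
        assert evaluate_constraint(10.0, self.c(mandatory=10.0)).status == Status.GREEN

    def test_display_precision_rounding(self):
        # 20.04 rounds to 20.0 at display precision -> still green
        assert evaluate_constraint(20.04, self.c()).status == Status.GREEN
        assert evaluate_constraint(20.06, self.c()).status == Status.RED

    def test_yellow_needs_optimal(self):
        result = evaluate_constraint(18.0, self.c(mandatory=20.0, optimal=15.0))
        assert result.status == Status.YELLOW
        assert evaluate_constraint(14.0, self.c(mandatory=20.0, optimal=15.0)).status \
            == Status.GREEN

    def test_ge_coverage(self):
        cov = DoseConstraint(
            role="PTV_BREAST", metric=parse_metric("D95%[Gy]"),
            comparator=Comparator.GE, mandatory_limit=24.7, group=ConstraintGroup.PTV,
        )
        assert evaluate_constraint(26.0, cov).status == Status.GREEN
        assert evaluate_constraint(24.0, cov).status == Status.RED

    def test_not_evaluated_propagates(self):
        assert evaluate_constraint(None, self.c()).status == Status.NOT_EVALUATED

    def test_status_monotone_in_value(self):
        rank = {Status.GREEN: 0, Status.YELLOW: 1, Status.RED: 2}
        c = self.c(mandatory=20.0, optimal=15.0)
        statuses = [rank[evaluate_constraint(v, c).status] for v in np.linspace(0, 40, 81)]
        assert statuses == sorted(statuses)

    def test_optimal_must_be_stricter(self):
        with pytest.raises(ValidationError, match="stricter"):
            self.c(mandatory=10.0, optimal=12.0)


class TestProtocolFiles:
    @pytest.mark.parametrize("name", protocols.PROTOCOL_NAMES)
    def test_roundtrip(self, name):
        p = load_protocol(name)
        assert parse_protocol(format_protocol(p)) == p

    def test_key_fast_forward_limits_present(self):
        ff = load_protocol("FAST_FORWARD")
        by_label = {c.label: c for c in ff.constraints}
        v3 = by_label["LUNG_CONTRA V3Gy[%]"]
        assert v3.mandatory_limit == 10.0 and v3.is_extra
        heart = by_label["HEART Dmean[Gy]"]
        assert heart.mandatory_limit == 2.0 and heart.is_extra
        v16 = by_label["LUNG_IPSI V16Gy[%]"]
        assert v16.mandatory_limit == 20.0


def uniform_curve(name, dose, bin_width=0.05):
    bins = np.arange(0, dose + 2 * bin_width, bin_width)
    cum = np.where(bins <= dose + 1e-9, 100.0, 0.0)
    return DVHCurve(name, bins, cum, total_volume_cc=100.0, bin_width=bin_width)


def ff_mapping():
    m = StructureMapping()
    for role, name in [("PTV_BREAST", "ptv"), ("LUNG_IPSI", "lung_i"),
                       ("LUNG_CONTRA", "lung_c"), ("HEART", "heart")]:
        m.roles[role] = RoleAssignment(name)
    return m


def props():
    return PlanProperties(laterality=Laterality.RIGHT)


class TestEvaluatePlan:
    def test_all_green_phantom(self):
        curves = [
            uniform_curve("ptv", 26.0), uniform_curve("lung_i", 1.0),
            uniform_curve("lung_c", 0.2), uniform_curve("heart", 0.5),
        ]
        ev = evaluate_plan(curves, ff_mapping(), load_protocol("FAST_FORWARD"), props())
        statuses = {r.status for r in ev.results if r.value is not None}
        assert statuses == {Status.GREEN}
        assert ev.bw_score == 100

    def test_single_red(self):
        curves = [
            uniform_curve("ptv", 26.0), uniform_curve("lung_i", 1.0),
            uniform_curve("lung_c", 4.0),  # V3Gy = 100% > 10%
            uniform_curve("heart", 0.5),
        ]
        ev = evaluate_plan(curves, ff_mapping(), load_protocol("FAST_FORWARD"), props())
        reds = [r for r in ev.results if r.status == Status.RED]
        assert len(reds) == 1
        assert reds[0].constraint.label == "LUNG_CONTRA V3Gy[%]"
        assert ev.bw_score == int(round(100 * 8 / 9))

    def test_unmapped_roles_not_evaluated(self):
        curves = [uniform_curve("ptv", 26.0)]
        mapping = StructureMapping()
        mapping.roles["PTV_BREAST"] = RoleAssignment("ptv")
        ev = evaluate_plan(curves, mapping, load_protocol("FAST_FORWARD"), props())
        skin = [r for r in ev.results if r.constraint.role == "SKIN"]
        assert all(r.status == Status.NOT_EVALUATED for r in skin)

    def test_results_ordered_by_group(self):
        curves = [uniform_curve("ptv", 26.0)]
        mapping = StructureMapping()
        mapping.roles["PTV_BREAST"] = RoleAssignment("ptv")
        ev = evaluate_plan(curves, mapping, load_protocol("FAST_FORWARD"), props())
        order = [r.constraint.group for r in ev.results]
        ranks = [
            [ConstraintGroup.PTV, ConstraintGroup.MAIN_OAR, ConstraintGroup.OTHER_OAR].index(g)
            for g in order
        ]
        assert ranks == sorted(ranks)

    def test_requires_ptv_breast(self):
        with pytest.raises(ValidationError, match="PTV_BREAST"):
            evaluate_plan([], StructureMapping(), load_protocol("FAST_FORWARD"), props())
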