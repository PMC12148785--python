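import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planwatch import dvhcore, rtio, synthgen
from planwatch.dvhcore import (
    DVHCurve, MetricKind, MetricSpec, MetricUnit,
    compute_dvh, format_metric, metric_value, parse_metric,
)
from planwatch.exceptions import FormatError, ValidationError

from conftest import brute_force_volume, half_box_spec, two_level_spec


def uniform_grid(dose=10.0):
    return rtio.DoseGrid(
        np.full((10, 20, 20), dose), origin=(0, 0, 0), spacing=(2, 2, 2)
    )


def box_structure(name="box_dx", x=(5.0, 21.0), y=(5.0, 21.0), z=(1.0, 13.0)):
    contours = []
    for k in range(10):
        zc = 2.0 * k
        if z[0] <= zc <= z[1]:
            contours.append(np.array([
                [x[0], y[0], zc], [x[1], y[0], zc], [x[1], y[1], zc], [x[0], y[1], zc],
            ]))
    return rtio.Structure(name, contours)


class TestComputeDvh:
    def test_uniform_dose_limits(self):
        curve = compute_dvh(uniform_grid(10.0), box_structure())
        assert metric_value(curve, MetricSpec(MetricKind.V_DOSE, 3.0)) == pytest.approx(100.0)
        assert metric_value(curve, MetricSpec(MetricKind.V_DOSE, 10.1)) == pytest.approx(0.0)
        dmean = metric_value(curve, MetricSpec(MetricKind.DMEAN, unit_out=MetricUnit.GY))
        assert dmean == pytest.approx(10.0, abs=0.05)

    def test_half_box_is_50pct(self, tmp_path):
        spec = half_box_spec()
        paths = synthgen.make_phantom(spec, str(tmp_path))
        grid = rtio.read_rtdose(paths["rtdose"])
        structure = rtio.read_rtstruct(paths["rtstruct"])[0]
        curve = compute_dvh(grid, structure, supersample=2)
        v5 = metric_value(curve, MetricSpec(MetricKind.V_DOSE, 5.0))
        assert v5 == pytest.approx(50.0, abs=0.5)

    def test_supersample_converges_on_misaligned_box(self):
        # box edge at x=8.4 is off the voxel lattice: refinement must not worsen
        grid = rtio.DoseGrid(np.zeros((10, 20, 20)), (0, 0, 0), (2, 2, 2))
        grid.values[:, :, :10] = 10.0  # 10 Gy for x-voxels 0..9 (x <= 19 mm)
        structure = box_structure(x=(8.4, 28.4))
        exact = 100.0 * (19.0 - 8.4) / 20.0
        errs = []
        for ss in (1, 3):
            curve = compute_dvh(grid, structure, supersample=ss)
            v5 = metric_value(curve, MetricSpec(MetricKind.V_DOSE, 5.0))
            errs.append(abs(v5 - exact))
        assert errs[1] <= errs[0] + 1e-9
        assert errs[1] < 2.0

    def test_matches_brute_force_oracle(self, phantom):
        grid, structures, _ = phantom
        for structure in structures:
            curve = compute_dvh(grid, structure, supersample=1)
            doses, _ = brute_force_volume(grid, structure)
            assert curve.total_volume_cc == pytest.approx(
                len(doses) * 8.0 / 1000.0, rel=1e-9
            )
            dmean = metric_value(curve, MetricSpec(MetricKind.DMEAN, unit_out=MetricUnit.GY))
            assert dmean == pytest.approx(doses.mean(), abs=0.05)

    def test_no_coverage_errors(self):
        structure = box_structure(x=(500.0, 520.0), y=(500.0, 520.0))
        with pytest.raises(ValidationError, match="no dose coverage"):
            compute_dvh(uniform_grid(), structure)

    def test_hole_subtracts(self):
        outer = box_structure(x=(1.0, 37.0), y=(1.0, 37.0))
        ring = rtio.Structure("ring", outer.contours + box_structure(x=(9.0, 29.0), y=(9.0, 29.0)).contours)
        full = compute_dvh(uniform_grid(), outer, supersample=1)
        holed = compute_dvh(uniform_grid(), ring, supersample=1)
        assert holed.total_volume_cc < full.total_volume_cc
        inner = compute_dvh(uniform_grid(), box_structure(x=(9.0, 29.0), y=(9.0, 29.0)), supersample=1)
        assert holed.total_volume_cc + inner.total_volume_cc == pytest.approx(
            full.total_volume_cc, rel=1e-9
        )


class TestMetricValue:
    def uniform_curve(self, dose=26.0):
        bins = np.arange(0, dose + 0.1, 0.05)
        cum = np.where(bins <= dose, 100.0, 0.0)
        return DVHCurve("u", bins, cum, total_volume_cc=100.0, bin_width=0.05)

    def test_v16_on_uniform_26(self):
        assert metric_value(
            self.uniform_curve(), MetricSpec(MetricKind.V_DOSE, 16.0)
        ) == pytest.approx(100.0)

    def test_d50_on_uniform_26(self):
        d50 = metric_value(
            self.uniform_curve(), MetricSpec(MetricKind.D_VOLPCT, 50.0, MetricUnit.GY)
        )
        assert d50 == pytest.approx(26.0, abs=0.05)

    def test_two_level_dmean_6(self, tmp_path):
        spec = two_level_spec()
        paths = synthgen.make_phantom(spec, str(tmp_path))
        grid = rtio.read_rtdose(paths["rtdose"])
        structure = rtio.read_rtstruct(paths["rtstruct"])[0]
        doses, _ = brute_force_volume(grid, structure)  # independent oracle
        assert doses.mean() == pytest.approx(6.0, abs=1e-6)
        curve = compute_dvh(grid, structure, supersample=3)
        dmean = metric_value(curve, MetricSpec(MetricKind.DMEAN, unit_out=MetricUnit.GY))
        assert dmean == pytest.approx(6.0, abs=0.05)

    def test_dmin_dmean_dmax_ordering(self, phantom):
        grid, structures, _ = phantom
        for structure in structures:
            curve = compute_dvh(grid, structure)
            dmin = metric_value(curve, MetricSpec(MetricKind.DMIN, unit_out=MetricUnit.GY))
            dmean = metric_value(curve, MetricSpec(MetricKind.DMEAN, unit_out=MetricUnit.GY))
            dmax = metric_value(curve, MetricSpec(MetricKind.DMAX, unit_out=MetricUnit.GY))
            assert dmin <= dmean + 1e-9 <= dmax + 2e-9

    def test_v_monotone_in_dose(self, phantom):
        grid, structures, _ = phantom
        curve = compute_dvh(grid, structures[0])
        thresholds = np.linspace(0, 30, 40)
        values = [
            metric_value(curve, MetricSpec(MetricKind.V_DOSE, t)) for t in thresholds
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_d_at_extremes(self):
        curve = self.uniform_curve(10.0)
        d0 = metric_value(curve, MetricSpec(MetricKind.D_VOLPCT, 0.0, MetricUnit.GY))
        d100 = metric_value(curve, MetricSpec(MetricKind.D_VOLPCT, 100.0, MetricUnit.GY))
        dmax = metric_value(curve, MetricSpec(MetricKind.DMAX, unit_out=MetricUnit.GY))
        dmin = metric_value(curve, MetricSpec(MetricKind.DMIN, unit_out=MetricUnit.GY))
        assert d0 == dmax and d100 == dmin


class TestMetricGrammar:
    @pytest.mark.parametrize("text,kind,threshold,unit", [
        ("V3Gy[%]", MetricKind.V_DOSE, 3.0, MetricUnit.PCT),
        ("V16Gy[%]", MetricKind.V_DOSE, 16.0, MetricUnit.PCT),
        ("V10Gy[cc]", MetricKind.V_DOSE, 10.0, MetricUnit.CC),
        ("Dmean[Gy]", MetricKind.DMEAN, 0.0, MetricUnit.GY),
        ("Dmax[Gy]", MetricKind.DMAX, 0.0, MetricUnit.GY),
        ("D95%[Gy]", MetricKind.D_VOLPCT, 95.0, MetricUnit.GY),
        ("D2cc[Gy]", MetricKind.D_VOLCC, 2.0, MetricUnit.GY),
        ("v3gy", MetricKind.V_DOSE, 3.0, MetricUnit.PCT),
        (" V 1.5 Gy [%] ", MetricKind.V_DOSE, 1.5, MetricUnit.PCT),
    ])
    def test_parse(self, text, kind, threshold, unit):
        spec = parse_metric(text)
        assert spec.kind == kind
        assert spec.threshold == threshold
        assert spec.unit_out == unit

    def test_unparseable_lists_grammar(self):
        with pytest.raises(FormatError, match="Dmean"):
            parse_metric("Q7")

    @given(st.sampled_from(["V3Gy[%]", "V16Gy[%]", "D95%[Gy]", "Dmean[Gy]",
                            "Dmax[Gy]", "Dmin[Gy]", "D2cc[Gy]", "V28.6Gy[cc]"]))
    def test_roundtrip(self, text):
        spec = parse_metric(text)
        assert parse_metric(format_metric(spec)) == spec

    def test_unit_consistency_enforced(self):
        with pytest.raises(ValidationError):
            MetricSpec(MetricKind.DMEAN, unit_out=MetricUnit.PCT)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_curve_invariants_on_random_phantom_structures(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 30, size=(4, 8, 8))
    grid = rtio.DoseGrid(values, (0, 0, 0), (2, 2, 2))
    structure = box_structure(x=(1.0, 15.0), y=(1.0, 15.0), z=(0.0, 6.0))
    structure.contours = [c for c in structure.contours if c[0, 2] <= 6.0]
    curve = compute_dvh(grid, structure, supersample=1)
    assert curve.cum_volume_pct[0] == pytest.approx(100.0)
    assert np.all(np.diff(curve.cum_volume_pct) <= 1e-9)
    assert curve.cum_volume_pct[-1] == pytest.approx(0.0)
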