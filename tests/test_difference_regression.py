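"""Difference-point construction, OLS filtering rules, and the result matrix."""

import numpy as np
import pytest

from coldcomp.io_model import InputError, StudyConfig
from coldcomp.comparative_stats import SignificantPair
from coldcomp.difference_regression import (
    RegressionRejection,
    RegressionResult,
    StratumSpec,
    build_difference_points,
    default_strata,
    fit_difference_regression,
    label_level_regression,
    run_matrix,
)
from coldcomp.group_profiles import LabelMetricTable
from coldcomp.growth_kinetics import GrowthParameters


def gp(org, otg, gr=1.0):
    disp = int(np.floor(otg + 0.5))
    return GrowthParameters(org, {otg: (gr, 0.0, 3)}, otg, disp, gr, (otg, otg), (otg,))


def pair(a, b, mean_a, mean_b, group="ENZY", metric="VMf"):
    return SignificantPair(group, metric, a, b, mean_a, mean_b, 0.01, 100, 100)


class TestBuildPoints:
    def test_orientation_rule(self):
        params = {"A": gp("A", 15), "B": gp("B", 22)}
        pts, _ = build_difference_points([pair("A", "B", 40.0, 38.0)], params, "OTG")
        assert (pts[0].delta_axis, pts[0].delta_metric) == (7.0, -2.0)

    def test_reversed_input_gives_same_point(self):
        params = {"A": gp("A", 15), "B": gp("B", 22)}
        pts1, _ = build_difference_points([pair("A", "B", 40.0, 38.0)], params, "OTG")
        pts2, _ = build_difference_points([pair("B", "A", 38.0, 40.0)], params, "OTG")
        assert (pts1[0].delta_axis, pts1[0].delta_metric) == (
            pts2[0].delta_axis,
            pts2[0].delta_metric,
        )

    def test_equal_axis_pairs_excluded_and_counted(self):
        params = {"A": gp("A", 15), "B": gp("B", 15)}
        pts, n_equal = build_difference_points([pair("A", "B", 40.0, 38.0)], params, "OTG")
        assert pts == [] and n_equal == 1

    def test_missing_growth_params_raise(self):
        with pytest.raises(InputError, match="B"):
            build_difference_points([pair("A", "B", 1.0, 2.0)], {"A": gp("A", 15)}, "OTG")

    def test_all_pairs_enumeration(self, rng):
        otgs = [10, 15, 15, 15, 19, 19, 22, 22]
        orgs = [f"y{i}" for i in range(8)]
        params = {o: gp(o, T) for o, T in zip(orgs, otgs)}
        pairs = [
            pair(orgs[i], orgs[j], float(rng.normal(40, 1)), float(rng.normal(40, 1)))
            for i in range(8)
            for j in range(i + 1, 8)
        ]
        pts, n_equal = build_difference_points(pairs, params, "OTG")
        expect_equal = sum(
            1 for i in range(8) for j in range(i + 1, 8) if otgs[i] == otgs[j]
        )
        assert n_equal == expect_equal
        assert len(pts) == 28 - expect_equal
        assert all(p.delta_axis > 0 for p in pts)

    def test_stratum_filters_both_members(self):
        params = {"A": gp("A", 10), "B": gp("B", 15), "C": gp("C", 22)}
        st = StratumSpec("OTG10-15", "OTG", interval=(10, 15))
        pts, _ = build_difference_points(
            [pair("A", "B", 1.0, 2.0), pair("A", "C", 1.0, 2.0)], params, "OTG", st
        )
        assert len(pts) == 1 and pts[0].delta_axis == 5.0


class TestFit:
    def test_exact_line(self):
        pts, _ = build_difference_points(
            [
                pair("A", "B", 0.0, 2.0),
                pair("A", "C", 0.0, 4.0),
                pair("A", "D", 0.0, 6.0),
            ],
            {"A": gp("A", 10), "B": gp("B", 11), "C": gp("C", 12), "D": gp("D", 13)},
            "OTG",
        )
        fit = fit_difference_regression(pts)
        assert isinstance(fit, RegressionResult)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.direction == "direct"

    def test_two_points_rejected(self):
        pts, _ = build_difference_points(
            [pair("A", "B", 1.0, 0.0), pair("A", "C", 1.0, -1.0)],
            {"A": gp("A", 10), "B": gp("B", 11), "C": gp("C", 12)},
            "OTG",
        )
        out = fit_difference_regression(pts)
        assert isinstance(out, RegressionRejection)
        assert out.reason == "too_few_points"

    def test_zero_axis_variance_rejected(self):
        from coldcomp.difference_regression import DifferencePoint

        pts = [DifferencePoint(2.0, float(y), "a", "b") for y in (1, 2, 3)]
        out = fit_difference_regression(pts)
        assert isinstance(out, RegressionRejection)
        assert out.reason == "zero_axis_variance"

    def test_planted_negative_slope_recovered(self, rng):
        from coldcomp.difference_regression import DifferencePoint

        hits = 0
        for _ in range(50):
            x = rng.uniform(1, 10, 50)
            y = -0.2 * x + rng.normal(0, 0.05, 50)
            pts = [DifferencePoint(float(a), float(b), "a", "b") for a, b in zip(x, y)]
            fit = fit_difference_regression(pts)
            assert fit.direction == "inverse"
            hits += abs(fit.slope - (-0.2)) <= 3 * fit.slope_se
        assert hits >= 47

    def test_gr_axis_unit_coherence(self):
        """Doubling all growth rates halves Gr-axis slopes exactly."""
        params1 = {o: gp(o, 15, g) for o, g in [("A", 0.5), ("B", 1.0), ("C", 1.5), ("D", 2.0)]}
        params2 = {o: gp(o, 15, 2 * g) for o, g in [("A", 0.5), ("B", 1.0), ("C", 1.5), ("D", 2.0)]}
        pairs = [
            pair("A", "B", 0.0, 1.0),
            pair("A", "C", 0.0, 2.5),
            pair("B", "D", 1.0, 3.0),
            pair("C", "D", 2.5, 3.0),
        ]
        f1 = fit_difference_regression(build_difference_points(pairs, params1, "Gr")[0])
        f2 = fit_difference_regression(build_difference_points(pairs, params2, "Gr")[0])
        assert f2.slope == pytest.approx(f1.slope / 2, abs=1e-12)


class TestRunMatrix:
    def test_single_organism_yields_empty(self):
        mat = run_matrix([], {"A": gp("A", 15)})
        assert mat.results == []

    def test_report_and_highlight_thresholds(self):
        cfg = StudyConfig()
        r_low = RegressionResult("G", "Vf", "OTG", "", 5, 1.0, 0.1, 0.0, 0.45)
        r_mid = RegressionResult("G", "Vf", "OTG", "", 5, 1.0, 0.1, 0.0, 0.6)
        r_high = RegressionResult("G", "Vf", "OTG", "", 5, 1.0, 0.1, 0.0, 0.8)
        assert not r_low.reported(cfg)
        assert r_mid.reported(cfg) and not r_mid.highlighted(cfg)
        assert r_high.reported(cfg) and r_high.highlighted(cfg)

    def test_matrix_cells_and_strata(self, rng):
        otgs = [10, 15, 15, 15, 19, 19, 22, 22]
        grs = [0.6, 0.7, 1.2, 1.4, 1.1, 0.8, 1.3, 0.5]
        orgs = [f"y{i}" for i in range(8)]
        params = {o: gp(o, T, g) for o, T, g in zip(orgs, otgs, grs)}
        pairs = []
        for i in range(8):
            for j in range(i + 1, 8):
                pairs.append(
                    pair(orgs[i], orgs[j], float(rng.normal(70, 1)), float(rng.normal(70, 1)))
                )
        cfg = StudyConfig()
        mat = run_matrix(pairs, params, cfg, strata=default_strata(cfg))
        strata_ids = {r.stratum for r in mat.results} | {r.stratum for r in mat.rejections}
        assert "" in strata_ids
        assert {"OTG10-15", "OTG19-22", "Gr>1", "Gr<=1"} <= strata_ids
        # counts of points equal significant pairs with unequal axis values
        for r in mat.results:
            if r.stratum == "" and r.axis == "OTG":
                assert r.n_points == 28 - 5  # minus the 5 equal-display-OTG pairs

    def test_direction_tally(self):
        results = [
            RegressionResult("G1", "Vf", "OTG", "", 5, -1.0, 0.1, 0.0, 0.8),
            RegressionResult("G2", "Vf", "OTG", "", 5, 2.0, 0.1, 0.0, 0.75),
            RegressionResult("G3", "Vf", "OTG", "", 5, 1.0, 0.1, 0.0, 0.55),
        ]
        from coldcomp.difference_regression import MatrixResult

        mat = MatrixResult(results, [], StudyConfig())
        t7 = mat.tally(0.7)
        assert t7[("OTG", "", "inverse")] == 1
        assert t7[("OTG", "", "direct")] == 1
        assert mat.tally(0.5)[("OTG", "", "direct")] == 2


class TestLabelLevel:
    def test_exact_linear_label(self):
        tbl = LabelMetricTable("catalase", "Vf", {"a": 30.0, "b": 32.0, "c": 34.0})
        slopes = label_level_regression([tbl], {"a": 10.0, "b": 15.0, "c": 20.0})
        assert len(slopes) == 1
        assert slopes[0].slope == pytest.approx(0.4, abs=1e-12)
        assert slopes[0].r2 == pytest.approx(1.0, abs=1e-12)

    def test_below_min_points_skipped(self):
        tbl = LabelMetricTable("catalase", "Vf", {"a": 30.0, "b": 32.0})
        assert label_level_regression([tbl], {"a": 10.0, "b": 15.0}) == []

    def test_null_labels_split_near_half(self, rng):
        axis = {f"o{i}": float(10 + i) for i in range(8)}
        tables = [
            LabelMetricTable(f"lab{k}", "Vf", {o: float(rng.normal(30, 1)) for o in axis})
            for k in range(300)
        ]
        slopes = label_level_regression(tables, axis)
        frac_direct = np.mean([s.slope > 0 for s in slopes])
        assert 0.4 < frac_direct < 0.6
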