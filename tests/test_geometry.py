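"""ROI areas, fan geometry, expression ratios, Fisher/Bonferroni tests."""

import numpy as np
import pytest

from parcortex.geometry import (FanGeometry, aggregate_size_summary,
                                crescent_fan, expression_ratio,
                                fraction_within_fan, polarized_fraction_test,
                                roi_area)
from parcortex.synthetic import make_fan_cohort

from conftest import fisher_exact_enumeration


class TestRoiArea:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert roi_area(sq) == pytest.approx(1.0)

    def test_orientation_invariance(self):
        sq = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
        assert roi_area(sq) == pytest.approx(1.0)

    def test_matches_fan_triangulation_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            if np.min(np.diff(angles)) < 1e-3:
                continue
            radii = rng.uniform(0.5, 4.0)
            poly = radii * np.column_stack([np.cos(angles), np.sin(angles)])
            # fan triangulation from vertex 0
            oracle = 0.0
            for i in range(1, n - 1):
                a, b, c = poly[0], poly[i], poly[i + 1]
                oracle += 0.5 * abs(
                    (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                )
            assert roi_area(poly) == pytest.approx(oracle, abs=1e-12)

    def test_rigid_motion_invariance_and_square_scaling(self, rng):
        poly = np.array([[0, 0], [2, 0], [2, 1], [1, 2], [0, 1]], dtype=float)
        a0 = roi_area(poly)
        phi = 0.6
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        assert roi_area(poly @ rot.T + [7, -3]) == pytest.approx(a0)
        assert roi_area(3.0 * poly) == pytest.approx(9.0 * a0)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            roi_area(bowtie)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            roi_area(np.array([[0, 0], [1, 1]], dtype=float))


class TestAggregateSizes:
    def test_identical_groups_ks_p_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        _, ks = aggregate_size_summary(g)
        assert ks[("a", "b")][1] == 1.0

    def test_twofold_shift_detected_in_most_simulations(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.lognormal(np.log(0.78), 0.8, 34)
            b = rng.lognormal(np.log(0.39), 0.8, 33)
            _, ks = aggregate_size_summary({"full": a, "dcr1": b})
            hits += ks[("full", "dcr1")][1] < 0.05
        assert hits >= 80

    def test_summary_mean_sd(self):
        s, _ = aggregate_size_summary({"x": [1.0, 2.0, 3.0]})
        assert s["x"].mean == pytest.approx(2.0)
        assert s["x"].sd == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_size_summary({"x": []})


class TestFanGeometry:
    def test_bisector_centrosome_inside(self):
        # 90-degree crescent, centrosome on the bisector
        fan = crescent_fan((0, 0), (1, 0), (0, 1), (1, 1))
        assert fan.theta1_deg == pytest.approx(90.0)
        assert fan.theta2_deg == pytest.approx(45.0)
        assert fan.within_fan

    def test_opposite_centrosome_outside(self):
        fan = crescent_fan((0, 0), (1, 0), (0, 1), (-1, -1))
        assert not fan.within_fan

    def test_edge_boundary_counts_inside(self):
        fan = crescent_fan((0, 0), (1, 0), (0, 1), (2, 0))
        assert fan.theta2_deg == pytest.approx(0.0)
        assert fan.within_fan

    def test_rotation_and_scaling_invariance(self, rng):
        pts = {"edge_a": (1, 0), "edge_b": (0, 1), "centrosome": (0.9, 0.8)}
        base = crescent_fan((0, 0), *pts.values())
        phi = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = [3.0 * (rot @ np.asarray(p)) for p in pts.values()]
        fan = crescent_fan((0, 0), *moved)
        assert fan.theta1_deg == pytest.approx(base.theta1_deg)
        assert fan.within_fan == base.within_fan

    def test_centrosome_at_center_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            crescent_fan((0, 0), (1, 0), (0, 1), (0, 0))

    def test_cohort_flags_match_construction(self):
        cells, truth = make_fan_cohort(40, (60, 120), 0.8, seed=3)
        fans = [
            crescent_fan(c["center"], c["edge_a"], c["edge_b"], c["centrosome"])
            for c in cells
        ]
        for fan, cell in zip(fans, cells):
            assert fan.within_fan == cell["true_within_fan"]
        inside, n, frac = fraction_within_fan(fans)
        assert (inside, n, frac) == (32, 40, 0.8)

    def test_all_and_none_inside(self):
        for target in (0.0, 1.0):
            cells, _ = make_fan_cohort(10, inside_fraction=target, seed=1)
            fans = [
                crescent_fan(c["center"], c["edge_a"], c["edge_b"],
                             c["centrosome"])
                for c in cells
            ]
            assert fraction_within_fan(fans)[2] == target

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fraction_within_fan([])


class TestExpressionRatio:
    def test_per_cell_mean_intensities_give_sixteen_fold(self):
        # per-cell fluorescence means of the two promoter systems
        ratio = expression_ratio(5.5e4, 1.0, 3.4e3, 1.0)
        assert ratio == pytest.approx(16.2, abs=0.1)

    def test_equal_inputs_give_unity(self):
        assert expression_ratio(10, 0.5, 10, 0.5) == pytest.approx(1.0)

    def test_doubling_reference_efficiency_doubles_ratio(self):
        r1 = expression_ratio(10, 0.5, 10, 0.25)
        r2 = expression_ratio(10, 0.5, 10, 0.5)
        assert r2 == pytest.approx(2 * r1)

    def test_reciprocal_under_swap(self):
        r = expression_ratio(7, 0.4, 3, 0.9)
        assert expression_ratio(3, 0.9, 7, 0.4) == pytest.approx(1 / r)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            expression_ratio(1, 0.0, 1, 0.5)


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        res = polarized_fraction_test([((20, 80), (20, 80))])
        assert res[0]["p_raw"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        tables = [
            ((50, 132), (16, 143)),
            ((5, 15), (12, 8)),
            ((30, 70), (28, 72)),
            ((1, 9), (9, 1)),
        ]
        res = polarized_fraction_test(tables)
        for entry, table in zip(res, tables):
            assert entry["p_raw"] == pytest.approx(
                fisher_exact_enumeration(table), rel=1e-9
            )

    def test_bonferroni_multiplier_and_cap(self):
        tables = [((5, 15), (12, 8))] * 3
        res = polarized_fraction_test(tables)
        for entry in res:
            assert entry["p_adjusted"] == pytest.approx(
                min(1.0, 3 * entry["p_raw"])
            )
        single = polarized_fraction_test([((5, 15), (12, 8))])
        assert single[0]["p_adjusted"] == single[0]["p_raw"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            polarized_fraction_test([((-1, 5), (2, 3))])
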