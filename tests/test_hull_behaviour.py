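"""Visits, durations, eccentricity, classification and time budgets."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import sealrange.hull_behaviour as hb
from sealrange.hull_behaviour import (
    classify_categories,
    count_visits,
    hull_eccentricity,
    mean_locations_per_visit,
    min_enclosing_ellipse,
    normalize_by_area,
    time_budget,
)
from sealrange.tlocoh_core import Hull
from sealrange.track_io import Track


def square_hull(x0=0.0, y0=0.0, side=1000.0, parent=0):
    poly = Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])
    return Hull(
        parent=parent, neighbors=np.arange(3), polygon=poly,
        area_km2=(side / 1000.0) ** 2, degenerate=False,
    )


def track_with_points(x, y, start="2014-06-01", freq="15min"):
    n = len(x)
    ts = pd.date_range(start, periods=n, freq=freq, tz="UTC")
    tr = Track(
        animal_id="A1",
        fixes=pd.DataFrame({
            "timestamp": ts, "lon": np.zeros(n), "lat": np.zeros(n),
            "n_sats": np.full(n, 8), "residual": np.zeros(n),
        }),
    )
    tr.fixes["x"] = np.asarray(x, dtype=float)
    tr.fixes["y"] = np.asarray(y, dtype=float)
    return tr


# ---------------------------------------------------------------------------
# enclosed points


class TestEnclosedPoints:
    def test_members_and_edge_points_enclosed(self):
        hull = square_hull()
        # inside, on edge, on vertex, outside
        tr = track_with_points([500, 0, 1000, 1500], [500, 500, 1000, 1500])
        hb.compute_enclosed_points([hull], tr)
        np.testing.assert_array_equal(hull.enclosed, [0, 1, 2])

    def test_matches_analytic_membership(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-500, 1500, 1000)
        y = rng.uniform(-500, 1500, 1000)
        tr = track_with_points(x, y)
        hull = square_hull()
        hb.compute_enclosed_points([hull], tr)
        expected = np.flatnonzero((x >= 0) & (x <= 1000) & (y >= 0) & (y <= 1000))
        np.testing.assert_array_equal(hull.enclosed, expected)

    def test_degenerate_hull_empty(self):
        hull = Hull(parent=0, neighbors=np.arange(2), polygon=None, area_km2=0, degenerate=True)
        tr = track_with_points([0.0], [0.0])
        hb.compute_enclosed_points([hull], tr)
        assert len(hull.enclosed) == 0


# ---------------------------------------------------------------------------
# visits


class TestVisits:
    def test_continuous_occupancy_single_visit(self):
        t = np.arange(0, 10, 0.25)  # hours, gaps 15 min
        assert count_visits(t) == 1

    def test_gap_of_exactly_12h_same_visit(self):
        t = np.array([0.0, 12.0])
        assert count_visits(t, ivg_h=12.0) == 1
        assert count_visits(np.array([0.0, 12.0001]), ivg_h=12.0) == 2

    def test_hand_counted_gaps(self):
        # gaps: 13 h and 20 h -> three visits
        t = np.array([0.0, 1.0, 14.0, 15.0, 35.0])
        assert count_visits(t) == 3

    def test_empty_is_zero(self):
        assert count_visits(np.array([])) == 0

    def test_nsv_identity_on_random_gap_patterns(self):
        """nsv = 1 + number of gaps strictly over the inter-visit threshold."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = rng.integers(1, 40)
            gaps = rng.exponential(8.0, n - 1) if n > 1 else np.empty(0)
            t = np.concatenate([[0.0], np.cumsum(gaps)])
            assert count_visits(t, 12.0) == 1 + int(np.sum(gaps > 12.0))

    def test_mnlv(self):
        t = np.array([0.0, 1.0, 14.0, 15.0, 16.0, 17.0])  # visits of 2 and 4 fixes
        assert count_visits(t) == 2
        assert mean_locations_per_visit(t) == pytest.approx(3.0)

    def test_mnlv_times_nsv_is_total(self):
        rng = np.random.default_rng(2)
        t = np.cumsum(rng.exponential(6.0, 30))
        assert mean_locations_per_visit(t) * count_visits(t) == pytest.approx(30)


class TestNormalize:
    def test_arithmetic(self):
        assert normalize_by_area(4, 2.0) == 2.0
        assert normalize_by_area(7.5, 1.0) == 7.5

    def test_degenerate_flagged(self):
        assert np.isnan(normalize_by_area(4, 0.0))


# ---------------------------------------------------------------------------
# eccentricity


class TestEccentricity:
    def test_regular_hexagon_is_circular(self):
        th = np.arange(6) * np.pi / 3
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert hull_eccentricity(pts) < 1e-6

    def test_rectangle_4x2(self):
        pts = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], dtype=float)
        assert hull_eccentricity(pts) == pytest.approx(np.sqrt(1 - 0.25), abs=1e-3)

    def test_rectangle_ellipse_matches_constrained_minimisation_oracle(self):
        """Independent oracle: minimise ellipse area subject to containing
        all corners, via scipy on the axis-aligned parametrisation."""
        from scipy.optimize import minimize

        corners = np.array([[2, 1], [2, -1], [-2, 1], [-2, -1]], dtype=float)

        def area(ab):
            return ab[0] * ab[1]

        cons = [
            {"type": "ineq", "fun": lambda ab, c=c: 1 - (c[0] / ab[0]) ** 2 - (c[1] / ab[1]) ** 2}
            for c in corners
        ]
        res = minimize(area, x0=[3.0, 2.0], constraints=cons)
        a, b = sorted(res.x, reverse=True)
        e_oracle = np.sqrt(1 - (b / a) ** 2)
        _, axes = min_enclosing_ellipse(corners)
        assert axes[0] == pytest.approx(a, rel=1e-3)
        assert axes[1] == pytest.approx(b, rel=1e-3)
        assert hull_eccentricity(corners) == pytest.approx(e_oracle, abs=1e-3)

    def test_near_collinear_points(self):
        pts = np.column_stack([np.linspace(0, 100, 8), np.linspace(0, 1, 8) * 0.01])
        assert hull_eccentricity(pts) > 0.99

    def test_invariance_rotation_translation_scale(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (9, 2))
        e0 = hull_eccentricity(pts)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 5.0 * (pts @ R.T) + np.array([100.0, -40.0])
        assert hull_eccentricity(moved) == pytest.approx(e0, abs=2e-3)

    def test_degenerate_hull_convention(self):
        h = Hull(parent=0, neighbors=np.arange(2), polygon=None, area_km2=0, degenerate=True)
        assert hull_eccentricity(h) == 1.0


# ---------------------------------------------------------------------------
# mean p(ARS)


class TestHullMeanPars:
    def test_mean_of_enclosed(self):
        hull = square_hull()
        hull.enclosed = np.array([0, 1, 2])
        pars = np.array([0.2, 0.4, 0.9, 0.0])
        assert hb.hull_mean_pars(hull, pars) == pytest.approx(0.5)

    def test_all_ones(self):
        hull = square_hull()
        hull.enclosed = np.array([0, 1])
        assert hb.hull_mean_pars(hull, np.ones(5)) == 1.0

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(4)
        hull = square_hull()
        hull.enclosed = np.arange(10)
        pars = rng.uniform(0, 1, 10)
        m = hb.hull_mean_pars(hull, pars)
        assert pars.min() <= m <= pars.max()

    def test_empty_undefined(self):
        hull = square_hull()
        hull.enclosed = np.empty(0, dtype=int)
        assert np.isnan(hb.hull_mean_pars(hull, np.ones(5)))


# ---------------------------------------------------------------------------
# colony exclusion


class TestColonyExclusion:
    def make(self, dists):
        n = len(dists)
        tr = track_with_points(np.zeros(n), np.zeros(n))
        tr.fixes["dist_colony"] = np.asarray(dists, dtype=float)
        hulls = [square_hull(parent=i) for i in range(n)]
        return hulls, tr

    def test_boundary(self):
        hulls, tr = self.make([14.9, 15.1, 15.0])
        kept = hb.exclude_near_colony(hulls, tr, radius_km=15.0)
        assert [h.parent for h in kept] == [1, 2]  # 15.0 itself retained (>= radius)

    def test_zero_radius_keeps_all(self):
        hulls, tr = self.make([0.1, 5.0, 100.0])
        assert len(hb.exclude_near_colony(hulls, tr, radius_km=0.0)) == 3


# ---------------------------------------------------------------------------
# classification


def metrics_frame(nsv_km2, mnlv_km2, animal="A1", season="summer"):
    n = len(nsv_km2)
    return pd.DataFrame({
        "animal_id": [animal] * n,
        "season": [season] * n,
        "hull_id": np.arange(n),
        "parent": np.arange(n),
        "nsv_km2": np.asarray(nsv_km2, dtype=float),
        "mnlv_km2": np.asarray(mnlv_km2, dtype=float),
    })


class TestClassification:
    def test_low_visits_short_duration_is_category_1(self):
        rng = np.random.default_rng(5)
        t = metrics_frame(rng.uniform(0, 10, 100), rng.uniform(0, 10, 100))
        cls = classify_categories(t)
        low = cls.table[(cls.table["nsv_km2"] < cls.q1)]
        lowshort = low[low["mnlv_km2"] <= cls.band_medians["infrequent"]]
        assert (lowshort["category"] == 1).all()

    def test_high_visits_long_duration_is_category_6(self):
        rng = np.random.default_rng(6)
        t = metrics_frame(rng.uniform(0, 10, 100), rng.uniform(0, 10, 100))
        cls = classify_categories(t)
        high = cls.table[cls.table["nsv_km2"] > cls.q3]
        hilong = high[high["mnlv_km2"] > cls.band_medians["very_frequent"]]
        assert (hilong["category"] == 6).all()

    def test_partition_and_band_shares(self):
        rng = np.random.default_rng(7)
        t = metrics_frame(rng.normal(5, 1, 400), rng.normal(5, 1, 400))
        cls = classify_categories(t)
        cats = cls.table["category"]
        assert set(cats).issubset({1, 2, 3, 4, 5, 6})
        assert len(cats) == 400
        # quartile construction: ~25 % / 50 % / 25 % split up to ties
        infreq = (cats <= 2).mean()
        freq = ((cats == 3) | (cats == 4)).mean()
        assert infreq == pytest.approx(0.25, abs=0.02)
        assert freq == pytest.approx(0.50, abs=0.02)
        # quantile oracle
        q1, q3 = np.quantile(t["nsv_km2"], [0.25, 0.75])
        assert cls.q1 == pytest.approx(q1)
        assert cls.q3 == pytest.approx(q3)

    def test_order_and_relabel_invariance(self):
        rng = np.random.default_rng(8)
        t = metrics_frame(rng.uniform(0, 10, 60), rng.uniform(0, 10, 60))
        cls1 = classify_categories(t)
        shuffled = t.sample(frac=1, random_state=1)
        shuffled["animal_id"] = "ZZ"
        cls2 = classify_categories(shuffled)
        merged = cls1.table.set_index("hull_id")["category"]
        merged2 = cls2.table.set_index("hull_id")["category"]
        assert (merged.sort_index() == merged2.sort_index()).all()

    def test_identical_metrics_degenerate(self):
        t = metrics_frame(np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="degenerate"):
            classify_categories(t)

    def test_too_few_hulls(self):
        t = metrics_frame([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="4"):
            classify_categories(t)


# ---------------------------------------------------------------------------
# time budgets


class TestTimeBudget:
    def test_single_category_animal(self):
        t = metrics_frame(np.ones(5), np.ones(5))
        t["category"] = 3
        b = time_budget(t)
        row = b.proportions.iloc[0]
        assert [row[f"p{c}"] for c in range(1, 7)] == [0, 0, 1, 0, 0, 0]

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(9)
        frames = []
        for animal in ("A1", "A2", "A3"):
            for season in ("summer", "fall"):
                t = metrics_frame(np.ones(30), np.ones(30), animal=animal, season=season)
                t["category"] = rng.integers(1, 7, 30)
                frames.append(t)
        b = time_budget(pd.concat(frames, ignore_index=True))
        sums = b.proportions[[f"p{c}" for c in range(1, 7)]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)
        assert len(b.proportions) == 6
        assert {"median", "mad"} <= set(b.summary.columns)
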