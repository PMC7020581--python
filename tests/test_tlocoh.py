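"""Time-scaled distance, neighbour selection, hulls and isopleths."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon

import sealrange.hull_behaviour as hb
import sealrange.tlocoh_core as tl
from sealrange.tlocoh_core import Hull, TLoCoHConfig, build_isopleths, tsd
from sealrange.track_io import Track


def track_from_xy(x_m, y_m, times=None, start="2014-06-01", freq="15min"):
    n = len(x_m)
    ts = times if times is not None else pd.date_range(start, periods=n, freq=freq, tz="UTC")
    tr = Track(
        animal_id="A1",
        fixes=pd.DataFrame({
            "timestamp": ts,
            "lon": np.zeros(n),
            "lat": np.zeros(n),
            "n_sats": np.full(n, 8),
            "residual": np.zeros(n),
        }),
    )
    tr.fixes["x"] = np.asarray(x_m, dtype=float)
    tr.fixes["y"] = np.asarray(y_m, dtype=float)
    return tr


def random_track(n=200, seed=0, extent_m=20000, span_h=100):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, extent_m, n)
    y = rng.uniform(0, extent_m, n)
    t0 = pd.Timestamp("2014-06-01", tz="UTC")
    offs = np.sort(rng.uniform(0, span_h, n))
    times = pd.DatetimeIndex([t0 + pd.Timedelta(hours=float(h)) for h in offs])
    return track_from_xy(x, y, times=times)


def brute_force_tsd(track, parent, s, v_max):
    fx = track.fixes
    t_h = fx["timestamp"].astype("int64").to_numpy() / 3.6e12
    out = np.empty(len(fx))
    for j in range(len(fx)):
        out[j] = tsd(
            (fx["x"].iloc[parent], fx["y"].iloc[parent]),
            (fx["x"].iloc[j], fx["y"].iloc[j]),
            s, v_max, dt_h=t_h[parent] - t_h[j],
        )
    return out


# ---------------------------------------------------------------------------
# TSD


class TestTSD:
    def test_s_zero_is_euclidean(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(-1e4, 1e4, 2)
            q = rng.uniform(-1e4, 1e4, 2)
            dt = rng.uniform(0, 48)
            assert tsd(p, q, 0.0, 6000.0, dt) == pytest.approx(np.hypot(*(p - q)), rel=1e-12)

    def test_dt_zero_is_euclidean(self):
        assert tsd((0, 0), (3000, 4000), 0.05, 6000.0, 0.0) == pytest.approx(5000.0)

    def test_worked_example(self):
        # dx=3000, dy=4000, s=0.05, v_max=6000 m/h, dt=2 h -> sqrt(5000^2+600^2)
        val = tsd((0, 0), (3000, 4000), 0.05, 6000.0, 2.0)
        assert val == pytest.approx(np.sqrt(5000**2 + 600**2), rel=1e-12)
        assert val == pytest.approx(5035.9, abs=0.05)

    def test_symmetric_and_dominates_euclidean(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(-1e4, 1e4, 2)
            q = rng.uniform(-1e4, 1e4, 2)
            dt = rng.uniform(0, 24)
            a = tsd(p, q, 0.07, 5000.0, dt)
            b = tsd(q, p, 0.07, 5000.0, -dt)
            assert a == pytest.approx(b, rel=1e-12)
            assert a >= np.hypot(*(p - q)) - 1e-9

    def test_zero_iff_same_place_and_time(self):
        assert tsd((5, 5), (5, 5), 0.1, 6000.0, 0.0) == 0.0
        assert tsd((5, 5), (5, 5), 0.1, 6000.0, 1.0) > 0


# ---------------------------------------------------------------------------
# neighbour selection vs brute force


class TestNeighborSelection:
    @pytest.mark.parametrize("seed", range(5))
    def test_k_method_matches_exhaustive_sort(self, seed):
        track = random_track(n=200, seed=seed)
        d = brute_force_tsd(track, 37, 0.05, 6000.0)
        expected = np.sort(np.lexsort((np.arange(len(d)), d))[:15])
        got = tl.select_neighbors_k(track, 37, 15, 0.05, 6000.0)
        np.testing.assert_array_equal(got, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_a_method_matches_cumulative_sum_oracle(self, seed):
        track = random_track(n=200, seed=seed)
        a_budget = 60000.0
        d = brute_force_tsd(track, 11, 0.05, 6000.0)
        order = np.lexsort((np.arange(len(d)), d))
        csum = np.cumsum(d[order])
        m = max(int(np.searchsorted(csum, a_budget, side="right")), 1)
        expected = np.sort(order[:m])
        got = tl.select_neighbors_a(track, 11, a_budget, 0.05, 6000.0)
        np.testing.assert_array_equal(got, expected)

    def test_k_one_like_selection_returns_parent(self):
        track = random_track(n=50, seed=3)
        got = tl.select_neighbors_a(track, 5, 0.0, 0.05, 6000.0)
        np.testing.assert_array_equal(got, [5])

    def test_a_huge_budget_selects_all(self):
        track = random_track(n=50, seed=4)
        d = brute_force_tsd(track, 0, 0.05, 6000.0)
        got = tl.select_neighbors_a(track, 0, float(d.sum()) + 1, 0.05, 6000.0)
        np.testing.assert_array_equal(got, np.arange(50))

    def test_k_exceeding_n_raises(self):
        track = random_track(n=10, seed=5)
        with pytest.raises(ValueError, match="exceeds"):
            tl.select_neighbors_k(track, 0, 11, 0.05, 6000.0)

    def test_huge_s_selects_temporal_neighbours(self):
        # revisited site: fixes 0..9 and 20..29 at the same place, 10..19 far away
        x = np.concatenate([np.zeros(10), np.full(10, 50000.0), np.zeros(10)])
        track = track_from_xy(x, np.zeros(30))
        nb = tl.select_neighbors_k(track, 5, 5, 1000.0, 6000.0)
        # with huge s the temporally adjacent fixes win despite spatial ties
        np.testing.assert_array_equal(nb, [3, 4, 5, 6, 7])


# ---------------------------------------------------------------------------
# hull construction


class TestBuildHull:
    def test_unit_square_km(self):
        pts = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        poly, area, degen = tl.build_hull(pts)
        assert not degen
        assert area == pytest.approx(1.0)

    def test_collinear_degenerate(self):
        pts = np.array([[0, 0], [500, 500], [1000, 1000]])
        poly, area, degen = tl.build_hull(pts)
        assert degen and area == 0

    def test_matches_scipy_convex_hull(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 1000, (100, 2))
        poly, area, degen = tl.build_hull(pts)
        oracle = ConvexHull(pts)
        assert area * 1e6 == pytest.approx(oracle.volume, rel=1e-9)


# ---------------------------------------------------------------------------
# time-selected fraction


class TestTimeSelected:
    def test_s_zero_fraction_zero(self, sim_track):
        cfg = TLoCoHConfig(s=0.0, k=15)
        assert tl.time_selected_fraction(sim_track, 0.0, cfg) == 0.0

    def test_fraction_increases_with_s(self):
        # revisited patch: the track alternates between two sites
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 500, 50), rng.normal(20000, 500, 50),
                            rng.normal(0, 500, 50), rng.normal(20000, 500, 50)])
        y = rng.normal(0, 500, 200)
        track = track_from_xy(x, y)
        cfg = TLoCoHConfig(s=0.05, k=10)
        svals = [0.0, 0.01, 0.05, 0.2, 1.0]
        fracs = [tl.time_selected_fraction(track, s, cfg, v_max=6000.0) for s in svals]
        assert fracs[0] == 0.0
        assert fracs[-1] >= fracs[0]
        assert max(fracs) > 0.3

    def test_choose_s_recommends_in_band(self, sim_track):
        cfg = TLoCoHConfig(s=0.05, k=15)
        diag = tl.choose_s(sim_track, [0.0, 0.01, 0.03, 0.05, 0.1, 0.3], cfg)
        assert diag.recommendation is None or 0.0 < diag.recommendation <= 0.3
        if diag.recommendation is not None:
            i = list(diag.candidates).index(diag.recommendation)
            assert 0.40 <= diag.time_selected_fraction[i] <= 0.80


# ---------------------------------------------------------------------------
# isopleths


def toy_hulls():
    """10 hand-built unit-ish square hulls with assigned enclosed points."""
    hulls = []
    # squares along the x axis; hull i encloses points [10i .. 10i+9]
    for i in range(10):
        x0 = i * 2000.0
        poly = Polygon([(x0, 0), (x0 + 1000, 0), (x0 + 1000, 1000), (x0, 1000)])
        h = Hull(
            parent=i, neighbors=np.arange(3), polygon=poly, area_km2=1.0, degenerate=False,
            enclosed=np.arange(10 * i, 10 * i + 10),
        )
        hulls.append(h)
    return hulls


class TestIsopleths:
    def test_level_one_includes_everything(self):
        hulls = toy_hulls()
        # densities equal; area tie-breaking applies
        iso = build_isopleths(hulls, 100, "point_density", (1.0,))
        assert iso.levels[0].achieved_fraction == 1.0
        assert iso.levels[0].n_hulls == 10
        assert iso.levels[0].area_km2 == pytest.approx(10.0)

    def test_manual_union_oracle(self):
        hulls = toy_hulls()
        # give hulls distinct enclosed counts so density ranks them 9,8,...,0
        for i, h in enumerate(hulls):
            h.enclosed = np.arange(0, 10 + i) + 100 * i  # ids only need uniqueness
        # re-index enclosed to a compact space for counting
        ids = {}
        for h in hulls:
            h.enclosed = np.array([ids.setdefault(v, len(ids)) for v in h.enclosed])
        n = len(ids)
        iso = build_isopleths(hulls, n, "point_density", (0.3, 0.95))
        # hand computation: hulls sorted by density desc = 9, 8, 7, ...
        sizes = [10 + i for i in range(10)]
        order = sorted(range(10), key=lambda i: -sizes[i])
        cum, k = 0, 0
        while cum < 0.3 * n:
            cum += sizes[order[k]]
            k += 1
        assert iso.levels[0].n_hulls == k
        assert iso.levels[0].area_km2 == pytest.approx(k * 1.0)

    def test_nested_levels_monotone_area(self, sim_track, sim_hulls):
        iso = build_isopleths(sim_hulls, len(sim_track.fixes), "point_density", (0.3, 0.95))
        a30, a95 = iso.levels[0].area_km2, iso.levels[1].area_km2
        assert a30 <= a95
        assert iso.levels[0].achieved_fraction >= 0.3
        assert iso.levels[1].achieved_fraction >= 0.95

    def test_visit_sorting_requires_nsv(self):
        hulls = toy_hulls()
        for h in hulls:
            h.nsv = None
        with pytest.raises(ValueError, match="nsv"):
            build_isopleths(hulls, 100, "visit_frequency", (0.3,))

    def test_no_valid_hulls_errors(self):
        h = Hull(parent=0, neighbors=np.arange(2), polygon=None, area_km2=0.0, degenerate=True)
        with pytest.raises(ValueError, match="no valid"):
            build_isopleths([h], 10, "point_density", (0.95,))

    def test_all_single_visits_core_matches_density_up_to_ties(self):
        hulls = toy_hulls()
        for i, h in enumerate(hulls):
            h.enclosed = np.arange(10 * i, 10 * i + 10)
            h.nsv = 1
        byd = build_isopleths(hulls, 100, "point_density", (0.3,))
        byv = build_isopleths(hulls, 100, "visit_frequency", (0.3,))
        # equal metrics everywhere -> same tie-break path -> same hull count
        assert byd.levels[0].n_hulls == byv.levels[0].n_hulls
        assert byd.levels[0].area_km2 == pytest.approx(byv.levels[0].area_km2)

    def test_translation_rotation_invariance(self, sim_track):
        cfg = TLoCoHConfig(s=0.05, k=15)
        base = tl.build_hulls(sim_track, cfg)
        hb.compute_enclosed_points(base, sim_track)
        moved = sim_track.copy()
        theta = 0.7
        x = sim_track.fixes["x"].to_numpy()
        y = sim_track.fixes["y"].to_numpy()
        moved.fixes["x"] = 12345.0 + x * np.cos(theta) - y * np.sin(theta)
        moved.fixes["y"] = -999.0 + x * np.sin(theta) + y * np.cos(theta)
        rot = tl.build_hulls(moved, cfg)
        hb.compute_enclosed_points(rot, moved)
        iso1 = build_isopleths(base, len(sim_track.fixes), "point_density", (0.95,))
        iso2 = build_isopleths(rot, len(moved.fixes), "point_density", (0.95,))
        assert iso2.levels[0].area_km2 == pytest.approx(iso1.levels[0].area_km2, rel=1e-6)


# ---------------------------------------------------------------------------
# parameter diagnostics


class TestDiagnostics:
    def test_area_non_decreasing_in_k_per_hull(self, sim_track):
        small = tl.build_hulls(sim_track, TLoCoHConfig(s=0.05, k=8))
        large = tl.build_hulls(sim_track, TLoCoHConfig(s=0.05, k=16))
        # a larger neighbourhood contains the smaller one, so per-hull area
        # cannot shrink
        for hs, hl in zip(small, large):
            assert hl.area_km2 >= hs.area_km2 - 1e-12

    def test_single_candidate_no_recommendation(self, sim_track):
        cfg = TLoCoHConfig(s=0.05, k=15)
        diag = tl.isopleth_diagnostics(sim_track, [10], cfg, parameter="k")
        assert diag.recommendation is None
        assert len(diag.isopleth_area) == 1

    def test_a_candidates_centred_on_a_k15(self, sim_track):
        v = tl.resolve_vmax(sim_track)
        a15 = tl.a_for_k(sim_track, 15, 0.05, v)
        assert a15 > 0
        cfg = TLoCoHConfig(s=0.05, k=15)
        cands = [0.5 * a15, a15, 1.5 * a15]
        diag = tl.isopleth_diagnostics(sim_track, cands, cfg, parameter="a")
        assert len(diag.isopleth_area) == 3
        assert np.all(np.isfinite(diag.isopleth_area))
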