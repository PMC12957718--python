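"""Night extraction, interval blocking, attendance detection, weights."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from roostkit.detection import (
    DetectionConfig,
    assign_intervals,
    cluster_roost_sites,
    compute_weights,
    detect_attendance,
    extract_night_locations,
    intervals_per_winter,
    project_coordinates,
    sensitivity_sweep,
)
from roostkit.geo import TransverseMercator

from conftest import brute_force_attendance, random_nights


def _fixes(rows):
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "lon", "lat"])


PROJ = TransverseMercator(lon0=7.2, lat0=46.75)


class TestExtractNightLocations:
    def test_evening_fixes_one_night(self):
        # dusk on Dec 1 near Bern is ~17:10 CET; 18:00-20:00 CET all qualify
        fixes = _fixes([
            ("b1", pd.Timestamp("2017-12-01 17:00", tz="UTC"), 7.25, 46.80),
            ("b1", pd.Timestamp("2017-12-01 18:00", tz="UTC"), 7.25, 46.80),
            ("b1", pd.Timestamp("2017-12-01 19:00", tz="UTC"), 7.25, 46.80),
        ])
        nights = extract_night_locations(project_coordinates(fixes, PROJ))
        assert len(nights) == 1
        assert nights.night_date.iloc[0] == np.datetime64("2017-12-01")
        assert nights.n_fixes.iloc[0] == 3

    def test_morning_fix_joins_previous_night(self):
        # 07:00 CET on Dec 2 is before civil dawn (~07:40) -> night Dec 1
        fixes = _fixes([
            ("b1", pd.Timestamp("2017-12-01 18:00", tz="UTC"), 7.25, 46.80),
            ("b1", pd.Timestamp("2017-12-02 06:00", tz="UTC"), 7.25, 46.80),
        ])
        nights = extract_night_locations(project_coordinates(fixes, PROJ))
        assert len(nights) == 1
        assert nights.n_fixes.iloc[0] == 2

    def test_daytime_fix_excluded(self):
        fixes = _fixes([
            ("b1", pd.Timestamp("2017-12-01 11:00", tz="UTC"), 7.25, 46.80),
        ])
        nights = extract_night_locations(project_coordinates(fixes, PROJ))
        assert len(nights) == 0

    def test_median_of_odd_collinear_fixes_is_middle(self):
        base = pd.Timestamp("2017-12-01 17:00", tz="UTC")
        lons = [7.2500, 7.2501, 7.2502]
        fixes = _fixes([("b1", base + pd.Timedelta(hours=i), lon, 46.80)
                        for i, lon in enumerate(lons)])
        proj = project_coordinates(fixes, PROJ)
        nights = extract_night_locations(proj)
        assert nights.x.iloc[0] == pytest.approx(np.median(proj.x), abs=1e-9)


class TestAssignIntervals:
    @pytest.mark.parametrize("day,expected", [
        ("2016-11-01", 1), ("2016-11-05", 1), ("2016-11-06", 2),
        ("2017-01-30", 19), ("2017-01-31", 19),
    ])
    def test_block_index(self, day, expected):
        df = pd.DataFrame(dict(bird_id=["b"], night_date=[pd.Timestamp(day)],
                               x=[0.0], y=[0.0], n_fixes=[1]))
        out = assign_intervals(df)
        assert out.interval_index.iloc[0] == expected
        assert out.winter_id.iloc[0] == 2016

    def test_six_winters_yield_114_blocks(self):
        dates = []
        for year in range(2016, 2022):
            dates.extend(pd.date_range(f"{year}-11-01", f"{year + 1}-01-31"))
        df = pd.DataFrame(dict(bird_id="b", night_date=dates, x=0.0, y=0.0,
                               n_fixes=1))
        out = assign_intervals(df)
        blocks = out.groupby(["winter_id", "interval_index"]).size()
        assert len(blocks) == 114
        assert intervals_per_winter() * 6 == 114

    def test_out_of_window_dropped(self):
        df = pd.DataFrame(dict(bird_id=["b", "b"],
                               night_date=[pd.Timestamp("2017-06-15"),
                                           pd.Timestamp("2017-11-02")],
                               x=0.0, y=0.0, n_fixes=1))
        out = assign_intervals(df)
        assert len(out) == 1


def _night_frame(rows):
    df = pd.DataFrame(rows, columns=["bird_id", "night_date", "x", "y"])
    df["night_date"] = pd.to_datetime(df.night_date)
    df["n_fixes"] = 1
    return assign_intervals(df)


class TestDetectAttendance:
    def test_twelve_birds_within_radius_all_attend(self):
        rng = np.random.default_rng(1)
        rows = [(f"b{i}", "2020-11-16", *rng.uniform(0, 200, 2))
                for i in range(12)]
        _, units = detect_attendance(_night_frame(rows))
        assert len(units) == 12
        assert (units.attendance == 1).all()

    def test_single_neighbour_insufficient(self):
        rows = [("a", f"2020-11-0{d}", 0.0, 0.0) for d in range(1, 6)]
        rows += [("b", f"2020-11-0{d}", 100.0, 0.0) for d in range(1, 6)]
        _, units = detect_attendance(_night_frame(rows))
        assert (units.attendance == 0).all()
        assert (units.neighbour_count == 1).all()

    def test_cross_night_vs_same_night(self):
        rows = [("a", "2020-11-01", 0.0, 0.0),
                ("a", "2020-11-03", 0.0, 0.0),
                ("b", "2020-11-01", 200.0, 0.0),
                ("c", "2020-11-03", 0.0, 200.0)]
        nights = _night_frame(rows)
        _, cross = detect_attendance(nights, DetectionConfig(matching="cross_night"))
        _, same = detect_attendance(nights, DetectionConfig(matching="same_night"))
        a_cross = cross.set_index("bird_id").loc["a"]
        assert a_cross.neighbour_count == 2 and a_cross.attendance == 1
        # b on night 1 and c on night 3 are never within radius simultaneously
        # of each other, but both meet a; same-night counting still finds both
        b_same = same.set_index("bird_id").loc["b"]
        assert b_same.neighbour_count == 1

    def test_never_simultaneous_pair_differs_by_matching(self):
        rows = [("a", "2020-11-01", 0.0, 0.0),
                ("b", "2020-11-02", 100.0, 0.0)]
        nights = _night_frame(rows)
        _, cross = detect_attendance(nights, DetectionConfig(matching="cross_night"))
        _, same = detect_attendance(nights, DetectionConfig(matching="same_night"))
        assert cross.set_index("bird_id").loc["a", "neighbour_count"] == 1
        assert same.set_index("bird_id").loc["a", "neighbour_count"] == 0

    def test_tie_at_radius_counts(self):
        rows = [("a", "2020-11-01", 0.0, 0.0),
                ("b", "2020-11-01", 300.0, 0.0),
                ("c", "2020-11-01", -300.0, 0.0)]
        _, units = detect_attendance(_night_frame(rows))
        assert units.set_index("bird_id").loc["a", "attendance"] == 1

    @pytest.mark.parametrize("matching", ["cross_night", "same_night"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed, matching):
        nights = random_nights(seed, n_birds=10, n_nights=12, spread=1500.0)
        cfg = DetectionConfig(radius=400.0, matching=matching)
        _, units = detect_attendance(nights, cfg)
        oracle = brute_force_attendance(nights, radius=400.0,
                                        matching=matching)
        got = {(r.bird_id, r.winter_id, r.interval_index): r.attendance
               for r in units.itertuples()}
        assert got == oracle

    def test_same_night_counts_symmetric(self):
        nights = random_nights(3, n_birds=8, spread=1200.0)
        night_counts, _ = detect_attendance(nights, DetectionConfig())
        # rebuild the per-night neighbour relation by brute force; symmetry
        for nd, g in nights.groupby("night_date"):
            pts = list(g.itertuples())
            for a in pts:
                for b in pts:
                    if a.bird_id >= b.bird_id:
                        continue
                    ab = np.hypot(a.x - b.x, a.y - b.y) <= 300.0
                    ca = night_counts[(night_counts.bird_id == a.bird_id)
                                      & (night_counts.night_date == nd)]
                    cb = night_counts[(night_counts.bird_id == b.bird_id)
                                      & (night_counts.night_date == nd)]
                    if ab:
                        assert ca.n_neighbours.iloc[0] >= 1
                        assert cb.n_neighbours.iloc[0] >= 1

    def test_monotonicity(self):
        nights = random_nights(5, n_birds=12, spread=2500.0)
        def total(cfg):
            _, u = detect_attendance(nights, cfg)
            return u.attendance.sum(), u.set_index(
                ["bird_id", "winter_id", "interval_index"]).attendance
        base_sum, base = total(DetectionConfig(radius=300))
        wide_sum, wide = total(DetectionConfig(radius=600))
        assert (wide.reindex(base.index) >= base).all()
        _, strict = detect_attendance(nights, DetectionConfig(min_others=3))
        s = strict.set_index(["bird_id", "winter_id", "interval_index"]).attendance
        assert (s.reindex(base.index) <= base).all()


class TestClusterRoostSites:
    def test_chain_is_one_component(self):
        rows = [("a", "2020-11-01", 0.0, 0.0), ("b", "2020-11-01", 250.0, 0.0),
                ("c", "2020-11-01", 500.0, 0.0)]
        sites = cluster_roost_sites(_night_frame(rows))
        assert len(sites) == 1
        assert sites.n_tagged.iloc[0] == 3

    def test_isolated_bird_singleton(self):
        rows = [("a", "2020-11-01", 0.0, 0.0), ("b", "2020-11-01", 10000.0, 0.0)]
        sites = cluster_roost_sites(_night_frame(rows))
        assert len(sites) == 2
        assert set(sites.n_tagged) == {1}

    def test_centroid_is_member_mean(self):
        rows = [("a", "2020-11-01", 0.0, 0.0), ("b", "2020-11-01", 100.0, 0.0)]
        sites = cluster_roost_sites(_night_frame(rows))
        assert sites.centroid_x.iloc[0] == pytest.approx(50.0)


class TestComputeWeights:
    area = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])

    def _units(self, nights):
        _, units = detect_attendance(nights)
        return units

    def test_all_inside_weight_one(self):
        nights = _night_frame([("a", "2020-11-01", 500.0, 500.0),
                               ("b", "2020-11-01", 400.0, 400.0)])
        units = compute_weights(self._units(nights), nights, self.area)
        assert (units.weight == 1.0).all()

    def test_formula_exact(self):
        # unit distances outside: 0 (inside), d/2, d -> weights 1, 0.5, 0
        nights = _night_frame([
            ("a", "2020-11-01", 500.0, 500.0),
            ("b", "2020-11-01", 1400.0, 500.0),   # 400 m out
            ("c", "2020-11-01", 1800.0, 500.0),   # 800 m out (max)
        ])
        units = compute_weights(self._units(nights), nights, self.area)
        w = units.set_index("bird_id").weight
        assert w["a"] == pytest.approx(1.0, abs=1e-9)
        assert w["b"] == pytest.approx(0.5, abs=1e-9)
        assert w["c"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_polygon_rejected(self):
        nights = _night_frame([("a", "2020-11-01", 0.0, 0.0)])
        with pytest.raises(ValueError):
            compute_weights(self._units(nights), nights,
                            Polygon([(0, 0), (1, 0), (0, 0)]))


class TestSensitivitySweep:
    def test_empty_grid_rejected(self):
        nights = random_nights(0)
        with pytest.raises(ValueError):
            sensitivity_sweep(nights, [], [5], [2])

    def test_monotone_in_radius_and_min_others(self):
        nights = random_nights(7, n_birds=10, spread=2000.0)
        table = sensitivity_sweep(nights, [300, 600], [5], [2, 3])
        t = table.set_index(["radius", "min_others"])
        assert t.loc[(600, 2), "n_attending"] >= t.loc[(300, 2), "n_attending"]
        assert t.loc[(300, 3), "n_attending"] <= t.loc[(300, 2), "n_attending"]

    def test_window_shrink_never_increases_cross_night(self):
        nights = random_nights(11, n_birds=10, spread=2000.0)
        table = sensitivity_sweep(nights, [300], [5, 1], [2])
        t = table.set_index("window")
        assert t.loc[1, "n_attending"] <= t.loc[5, "n_attending"]
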