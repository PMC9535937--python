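"""Segmentation, temporal correction, snapping, aggregation and matching."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from lurtransfer import data_prep
from lurtransfer.data_prep import (
    LongTermSite,
    ReferenceSeries,
    aggregate_segments,
    match_sites_to_segments,
    segment_road_network,
    snap_to_segments,
    temporal_correct,
)


def make_obs(rows):
    return pd.DataFrame(rows, columns=["timestamp", "x", "y", "pollutant", "value"])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_120m_line_gives_50_50_20(self):
        segs = segment_road_network({"a": LineString([(0, 0), (120, 0)])}, 50.0)
        assert [round(s.length, 9) for s in segs] == [50.0, 50.0, 20.0]

    def test_exact_multiple_is_identity(self):
        segs = segment_road_network({"a": LineString([(0, 0), (50, 0)])}, 50.0)
        assert len(segs) == 1 and segs[0].length == pytest.approx(50.0)

    def test_sliver_remainder_merges_into_predecessor(self):
        segs = segment_road_network({"a": LineString([(0, 0), (105, 0)])}, 50.0)
        assert [round(s.length, 9) for s in segs] == [50.0, 55.0]

    def test_length_conservation_random_polylines(self, rng):
        lines = {}
        for i in range(10):
            pts = rng.uniform(0, 500, size=(rng.integers(2, 6), 2))
            lines[f"l{i}"] = LineString(pts)
        segs = segment_road_network(lines, 50.0)
        total_in = sum(l.length for l in lines.values())
        total_out = sum(s.length for s in segs)
        assert total_out == pytest.approx(total_in, rel=1e-6)

    def test_ids_unique_and_reject_degenerate(self):
        segs = segment_road_network({"a": LineString([(0, 0), (120, 0)])}, 50.0)
        assert len({s.segment_id for s in segs}) == len(segs)
        with pytest.raises(ValueError, match="bad"):
            segment_road_network({"bad": LineString([(1, 1), (1, 1)])}, 50.0)


# ---------------------------------------------------------------------------
# temporal correction
# ---------------------------------------------------------------------------

class TestTemporalCorrection:
    def ref_series(self, values, start="2019-06-03 08:00"):
        ts = pd.date_range(start, periods=len(values), freq="h")
        return ReferenceSeries(ts, np.asarray(values, float))

    def test_additive_and_multiplicative_formulas(self):
        # window mean 25, campaign mean 20, observation 30
        ref = self.ref_series([25, 15])  # campaign mean 20
        obs = make_obs([("2019-06-03 08:30", 0, 0, "NO2", 30.0)])
        add = temporal_correct(obs, ref, "additive")
        assert add["value"].iloc[0] == pytest.approx(25.0)  # 30 - (25-20)
        mul = temporal_correct(obs, ref, "multiplicative")
        assert mul["value"].iloc[0] == pytest.approx(24.0)  # 30 * 20/25

    @pytest.mark.parametrize("mode", ["additive", "multiplicative"])
    def test_constant_reference_is_noop(self, mode, rng):
        ref = self.ref_series([18.0] * 24)
        ts = pd.date_range("2019-06-03 08:00", periods=20, freq="17min")
        obs = make_obs([(t, 0, 0, "NO2", v) for t, v in
                        zip(ts, rng.uniform(5, 50, 20))])
        out = temporal_correct(obs, ref, mode)
        np.testing.assert_allclose(out["value"], obs["value"], rtol=1e-12)

    def test_uncovered_observations_are_dropped(self):
        ref = self.ref_series([20.0])
        obs = make_obs([
            ("2019-06-03 08:30", 0, 0, "NO2", 30.0),
            ("2019-07-01 12:00", 0, 0, "NO2", 30.0),  # no reference coverage
        ])
        out = temporal_correct(obs, ref, "additive")
        assert len(out) == 1

    def test_multiplicative_rejects_nonpositive_window_mean(self):
        ref = self.ref_series([-5.0, 45.0])
        obs = make_obs([("2019-06-03 08:30", 0, 0, "NO2", 30.0)])
        with pytest.raises(ValueError, match="<= 0"):
            temporal_correct(obs, ref, "multiplicative")

    def test_campaign_mean_matches_series_mean(self):
        ref = self.ref_series([10, 20, 30])
        assert ref.campaign_mean == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

class TestSnapping:
    segs = segment_road_network(
        {"a": LineString([(0, 0), (50, 0)]), "b": LineString([(0, 40), (50, 40)])},
        50.0,
    )

    def test_nearest_segment_wins(self):
        obs = make_obs([("2019-06-03 09:00", 25, 1, "NO2", 10.0)])
        out = snap_to_segments(obs, self.segs, max_snap_distance=30)
        assert out["segment_id"].iloc[0] == "a.0"

    def test_equidistant_tie_breaks_to_smaller_id(self):
        obs = make_obs([("2019-06-03 09:00", 25, 20, "NO2", 10.0)])
        out = snap_to_segments(obs, self.segs, max_snap_distance=30)
        assert out["segment_id"].iloc[0] == "a.0"

    def test_beyond_cutoff_left_unassigned(self):
        obs = make_obs([("2019-06-03 09:00", 25, -26, "NO2", 10.0)])
        out = snap_to_segments(obs, self.segs, max_snap_distance=25)
        assert out["segment_id"].isna().all()

    def test_matches_brute_force_nearest_oracle(self, rng):
        lines = {
            f"l{i}": LineString(rng.uniform(0, 300, size=(3, 2))) for i in range(7)
        }
        segs = segment_road_network(lines, 50.0)
        pts = rng.uniform(0, 300, size=(200, 2))
        obs = make_obs(
            [("2019-06-03 09:00", x, y, "NO2", 1.0) for x, y in pts]
        )
        out = snap_to_segments(obs, segs, max_snap_distance=1e9)
        for (x, y), got in zip(pts, out["segment_id"]):
            p = Point(x, y)
            d = {s.segment_id: p.distance(s.geometry) for s in segs}
            dmin = min(d.values())
            expected = min(k for k, v in d.items() if v <= dmin + 1e-9)
            assert got == expected

    def test_snapping_is_idempotent(self, rng):
        pts = rng.uniform(0, 50, size=(30, 2))
        obs = make_obs([("2019-06-03 09:00", x, y, "NO2", 1.0) for x, y in pts])
        once = snap_to_segments(obs, self.segs, 100)
        twice = snap_to_segments(once, self.segs, 100)
        pd.testing.assert_series_equal(once["segment_id"], twice["segment_id"])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregation:
    def test_mean_count_and_drive_passes(self):
        obs = make_obs([
            ("2019-06-03 09:00", 0, 0, "NO2", 10.0),
            ("2019-06-04 10:00", 0, 0, "NO2", 20.0),
        ])
        obs["segment_id"] = "s1"
        out = aggregate_segments(obs)
        row = out.iloc[0]
        assert row["mean_conc"] == pytest.approx(15.0)
        assert row["n_obs"] == 2
        assert row["n_drive_passes"] == 2

    def test_same_day_is_one_drive_pass(self):
        obs = make_obs([
            ("2019-06-03 09:00", 0, 0, "NO2", 10.0),
            ("2019-06-03 21:00", 0, 0, "NO2", 30.0),
        ])
        obs["segment_id"] = "s1"
        assert aggregate_segments(obs)["n_drive_passes"].iloc[0] == 1

    def test_matches_independent_groupby_oracle(self, rng):
        n = 300
        obs = make_obs([
            (pd.Timestamp("2019-06-03") + pd.Timedelta(hours=int(h)), 0, 0,
             rng.choice(["NO2", "UFP"]), v)
            for h, v in zip(rng.integers(0, 24 * 20, n), rng.uniform(1, 50, n))
        ])
        obs["segment_id"] = rng.choice([f"s{i}" for i in range(12)], n)
        out = aggregate_segments(obs).set_index(["segment_id", "pollutant"])
        # oracle: plain-python accumulation
        acc = {}
        for _, r in obs.iterrows():
            key = (r["segment_id"], r["pollutant"])
            acc.setdefault(key, []).append((r["value"], r["timestamp"].date()))
        for key, vals in acc.items():
            got = out.loc[key]
            assert got["mean_conc"] == pytest.approx(np.mean([v for v, _ in vals]))
            assert got["n_obs"] == len(vals)
            assert got["n_drive_passes"] == len({d for _, d in vals})
            assert min(v for v, _ in vals) <= got["mean_conc"] <= max(
                v for v, _ in vals)


# ---------------------------------------------------------------------------
# site matching
# ---------------------------------------------------------------------------

class TestSiteMatching:
    segs = segment_road_network({"a": LineString([(0, 0), (100, 0)])}, 50.0)

    def test_site_7m_away_matches_within_30m(self):
        segs = segment_road_network({"a": LineString([(0, 0), (50, 0)])}, 50.0)
        sites = [LongTermSite("s1", 25, 7, "NO2", 20.0)]
        out = match_sites_to_segments(sites, segs, radius=30)
        assert out[0].matched_segment_ids == ("a.0",)

    def test_site_31m_away_is_flagged_unmatched(self):
        sites = [LongTermSite("s1", 25, 31, "NO2", 20.0)]
        out = match_sites_to_segments(sites, self.segs, radius=30)
        assert out[0].matched_segment_ids == ()

    def test_matches_pairwise_distance_oracle(self, rng):
        lines = {f"l{i}": LineString(rng.uniform(0, 400, (3, 2))) for i in range(6)}
        segs = segment_road_network(lines, 50.0)
        sites = [
            LongTermSite(f"s{i}", x, y, "NO2", 10.0)
            for i, (x, y) in enumerate(rng.uniform(0, 400, (25, 2)))
        ]
        out = match_sites_to_segments(sites, segs, radius=30)
        for site in out:
            p = Point(site.x, site.y)
            expected = tuple(sorted(
                s.segment_id for s in segs if p.distance(s.geometry) <= 30
            ))
            assert site.matched_segment_ids == expected


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_roads_geojson_round_trip(self, tmp_path, small_scene):
        path = tmp_path / "roads.geojson"
        data_prep.write_roads_geojson(path, small_scene.polylines)
        back = data_prep.read_roads_geojson(path)
        assert set(back) == set(small_scene.polylines)
        for k in back:
            assert back[k].equals(small_scene.polylines[k])

    def test_sites_geojson_round_trip(self, tmp_path):
        sites = [LongTermSite("s1", 1.5, 2.5, "NO2", 20.25)]
        path = tmp_path / "sites.geojson"
        data_prep.write_sites_geojson(path, sites)
        back = data_prep.read_sites_geojson(path)
        assert back[0].site_id == "s1"
        assert back[0].value == pytest.approx(20.25)

    def test_observation_csv_schema_checks(self, tmp_path):
        path = tmp_path / "obs.csv"
        make_obs([("2019-06-03 09:00", 0, 0, "NO2", -3.0)]).to_csv(
            path, index=False)
        with pytest.raises(ValueError, match="negative"):
            data_prep.read_observations_csv(path)
        path2 = tmp_path / "obs2.csv"
        pd.DataFrame({"timestamp": [], "x": []}).to_csv(path2, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            data_prep.read_observations_csv(path2)
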