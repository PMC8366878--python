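import numpy as np
import pandas as pd
import pytest

import rotorrisk as rr
from conftest import cell_table_by_keys

REF = (42.7, -106.0)

SIEMENS = dict(
    model_name="siemens", rotor_diameter=101.0, hub_height=80.0, max_blade_height=131.5
)


def turbine_at(enu_xy, turbine_id="S1", **kw):
    spec = {**SIEMENS, **kw}
    lat, lon = rr.enu_unproject(enu_xy[0], enu_xy[1], *REF)
    return rr.TurbineSpec(turbine_id=turbine_id, lat=lat, lon=lon, **spec)


def track_from_enu(x, y, z, track_id="trk", conf=0.95, t0=1_557_000_000.0,
                   unit_xy=(0.0, -500.0)):
    """1-Hz track through the given ENU points (single-turbine test frame)."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    lat, lon = rr.enu_unproject(x, y, *REF)
    ulat, ulon = rr.enu_unproject(*unit_xy, *REF)
    return rr.FlightTrack(
        track_id=track_id,
        unit_id="U1",
        unit_lat=ulat,
        unit_lon=ulon,
        t=t0 + np.arange(len(x), dtype=float),
        lat=np.atleast_1d(lat),
        lon=np.atleast_1d(lon),
        alt=z,
        conf=np.full(len(x), conf),
    )


def straight_pass(d, z, n=61, speed=10.0):
    """East-west pass at horizontal offset d (north of the axis), altitude z."""
    s = (np.arange(n) - n // 2) * speed
    return s, np.full(n, float(d)), np.full(n, float(z))


CRIT = rr.CurtailmentCriteria()


class TestReadTracks:
    def _write(self, tmp_path, rows):
        path = tmp_path / "tracks.csv"
        pd.DataFrame(
            rows,
            columns=[
                "track_id", "unit_id", "unit_lat", "unit_lon",
                "timestamp", "lat", "lon", "alt_m", "confidence",
            ],
        ).to_csv(path, index=False)
        return path

    def test_two_row_file_one_track(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                ("a", "U1", 42.7, -106.0, 0.0, 42.70, -106.00, 80, 0.95),
                ("a", "U1", 42.7, -106.0, 1.0, 42.7001, -106.00, 81, 0.95),
            ],
        )
        tracks = rr.read_tracks(p)
        assert len(tracks) == 1 and tracks[0].n_points == 2

    def test_rows_out_of_order_sorted(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                ("a", "U1", 42.7, -106.0, 5.0, 42.7, -106.0, 85, 0.95),
                ("a", "U1", 42.7, -106.0, 1.0, 42.7, -106.0, 81, 0.95),
                ("a", "U1", 42.7, -106.0, 3.0, 42.7, -106.0, 83, 0.95),
            ],
        )
        (track,) = rr.read_tracks(p)
        assert list(track.t) == [1.0, 3.0, 5.0]
        assert list(track.alt) == [81.0, 83.0, 85.0]

    def test_single_point_track_rejected(self, tmp_path):
        rows = []
        for tid in ("a", "b"):
            for k in range(3):
                rows.append((tid, "U1", 42.7, -106.0, float(k), 42.7, -106.0, 80, 0.9))
        rows.append(("c", "U1", 42.7, -106.0, 0.0, 42.7, -106.0, 80, 0.9))
        tracks = rr.read_tracks(self._write(tmp_path, rows))
        assert sorted(tr.track_id for tr in tracks) == ["a", "b"]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"track_id": ["a"], "lat": [42.7]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="unit_id"):
            rr.read_tracks(path)

    def test_unparseable_timestamp_reports_line(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                ("a", "U1", 42.7, -106.0, 0.0, 42.7, -106.0, 80, 0.9),
                ("a", "U1", 42.7, -106.0, "not-a-time", 42.7, -106.0, 80, 0.9),
            ],
        )
        with pytest.raises(ValueError, match="line 3"):
            rr.read_tracks(p)

    def test_deep_negative_altitude_clipped(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                ("a", "U1", 42.7, -106.0, 0.0, 42.7, -106.0, -25.0, 0.9),
                ("a", "U1", 42.7, -106.0, 1.0, 42.7, -106.0, 80.0, 0.9),
            ],
        )
        (track,) = rr.read_tracks(p)
        assert track.alt[0] == 0.0

    def test_write_read_round_trip(self, tmp_path, small_sim):
        _, _, _, tracks = small_sim[1], small_sim[2], small_sim[3], small_sim[4]
        subset = small_sim[4][:5]
        rr.write_tracks(subset, tmp_path / "t.csv")
        back = rr.read_tracks(tmp_path / "t.csv")
        assert len(back) == 5
        assert {t.track_id for t in back} == {t.track_id for t in subset}


class TestDeduplication:
    def _pair(self, far_offset=900.0):
        x, y, z = straight_pass(d=100, z=80)
        near = track_from_enu(x, y, z, track_id="near", unit_xy=(0.0, -100.0))
        far = track_from_enu(x, y, z, track_id="far", unit_xy=(0.0, -far_offset))
        far.unit_id = "U2"
        return near, far

    def test_nearest_unit_wins(self):
        near, far = self._pair()
        merged = rr.deduplicate_simultaneous([near, far])
        assert len(merged) == 1
        assert merged[0].unit_id == "U1"
        assert merged[0].n_points == near.n_points

    def test_distant_tracks_both_retained(self):
        x, y, z = straight_pass(d=0, z=80)
        a = track_from_enu(x, y, z, track_id="a")
        b = track_from_enu(x, np.asarray(y) + 500.0, z, track_id="b")
        b.unit_id = "U2"
        assert len(rr.deduplicate_simultaneous([a, b])) == 2

    def test_single_unit_identity(self, small_sim):
        tracks = small_sim[4][:20]
        out = rr.deduplicate_simultaneous(tracks)
        assert {t.track_id for t in out} == {t.track_id for t in tracks}

    def test_idempotent(self):
        near, far = self._pair()
        once = rr.deduplicate_simultaneous([near, far])
        twice = rr.deduplicate_simultaneous(once)
        assert len(twice) == len(once) == 1
        assert np.array_equal(once[0].t, twice[0].t)
        assert np.array_equal(once[0].lat, twice[0].lat)


class TestDetectApproaches:
    def test_pass_through_hub_enters(self):
        t = turbine_at((0, 0))
        x, y, z = straight_pass(d=0, z=80)
        evs = rr.detect_approaches(track_from_enu(x, y, z), [t], CRIT)
        assert len(evs) == 1
        assert evs[0].entered == 1
        assert evs[0].turbine_id == "S1"
        assert evs[0].t_first_inside_rsz is not None
        assert evs[0].month_key == "2019-05"

    def test_track_holding_160m_no_event(self):
        t = turbine_at((0, 0))
        x, y, z = straight_pass(d=160, z=80)
        # keep every point at exactly 160 m: circle arc instead of chord
        theta = np.linspace(0, np.pi / 2, 30)
        evs = rr.detect_approaches(
            track_from_enu(160 * np.cos(theta), 160 * np.sin(theta), np.full(30, 80.0)),
            [t],
            CRIT,
        )
        assert evs == []

    def test_close_pass_without_entry(self):
        t = turbine_at((0, 0))
        x, y, z = straight_pass(d=100, z=80)
        evs = rr.detect_approaches(track_from_enu(x, y, z), [t], CRIT)
        assert len(evs) == 1
        assert evs[0].entered == 0
        assert evs[0].t_first_inside_rsz is None
        assert evs[0].min_horizontal_distance == pytest.approx(100.0, abs=0.5)

    def test_two_turbines_two_events(self):
        ta = turbine_at((0, 0), turbine_id="A")
        tb = turbine_at((220, 0), turbine_id="B")
        # fly between them at 110 m from each, outside both RSZs
        x = np.full(40, 110.0)
        y = (np.arange(40) - 20) * 10.0
        evs = rr.detect_approaches(
            track_from_enu(x, y, np.full(40, 80.0)), [ta, tb], CRIT
        )
        assert sorted(e.turbine_id for e in evs) == ["A", "B"]
        assert all(e.entered == 0 for e in evs)

    def test_confidence_gate(self):
        t = turbine_at((0, 0))
        x, y, z = straight_pass(d=0, z=80)
        evs = rr.detect_approaches(track_from_enu(x, y, z, conf=0.85), [t], CRIT)
        assert evs == []

    def test_horizontal_only_mode_ignores_altitude(self):
        t = turbine_at((0, 0))
        x, y, z = straight_pass(d=100, z=250.0)  # above the inner-cylinder band
        tr = track_from_enu(x, y, z)
        assert rr.detect_approaches(tr, [t], CRIT) == []
        evs = rr.detect_approaches(tr, [t], CRIT, approach_mode="horizontal_only")
        assert len(evs) == 1

    def test_empty_turbine_list_rejected(self):
        x, y, z = straight_pass(d=0, z=80)
        with pytest.raises(ValueError):
            rr.detect_approaches(track_from_enu(x, y, z), [], CRIT)


class TestBuildDataset:
    def test_counts_and_rate(self):
        turbines = [turbine_at((0, 0))]
        tracks = []
        for i in range(10):
            d, z = (0, 80) if i < 3 else (100, 80)
            x, yy, zz = straight_pass(d=d, z=z)
            tracks.append(track_from_enu(x, yy, zz, track_id=f"t{i}"))
        data, maps, summary = rr.build_dataset(tracks, turbines, CRIT)
        assert len(data) == 10
        assert data["y"].sum() == 3
        assert summary["entry_rate"] == pytest.approx(0.3)
        assert summary["frac_tracks_single_turbine"] == 1.0

    def test_multi_turbine_track_two_rows(self):
        ta = turbine_at((0, 0), turbine_id="A")
        tb = turbine_at((220, 0), turbine_id="B")
        x = np.full(40, 110.0)
        y = (np.arange(40) - 20) * 10.0
        data, _, summary = rr.build_dataset(
            [track_from_enu(x, y, np.full(40, 80.0))], [ta, tb], CRIT
        )
        assert len(data) == 2
        assert set(data["turbine_id"]) == {"A", "B"}
        assert data["track_id"].nunique() == 1
        assert summary["frac_tracks_multi_turbine"] == 1.0

    def test_zero_approaches_is_an_error(self):
        t = turbine_at((0, 0))
        theta = np.linspace(0, np.pi / 2, 30)
        tr = track_from_enu(
            500 * np.cos(theta), 500 * np.sin(theta), np.full(30, 80.0)
        )
        with pytest.raises(ValueError, match="no approaches"):
            rr.build_dataset([tr], [t], CRIT)

    def test_no_duplicate_track_turbine_events(self, small_sim):
        cfg, turbines, units, gt, tracks = small_sim
        data, _, _ = rr.build_dataset(tracks, turbines, CRIT)
        assert not data.duplicated(subset=["track_id", "turbine_id"]).any()

    def test_round_trip_matches_generator_exactly(self, small_sim):
        """The geometry pipeline reproduces the generating outcome table."""
        cfg, turbines, units, gt, tracks = small_sim
        data, _, _ = rr.build_dataset(tracks, turbines, CRIT)
        n, y = cell_table_by_keys(data, cfg)
        assert np.array_equal(n, gt.n)
        assert np.array_equal(y, gt.y_sum)

    def test_entries_are_approaches(self, small_sim):
        cfg, turbines, units, gt, tracks = small_sim
        frame = rr.FacilityFrame(turbines, CRIT)
        for tr in tracks[:100]:
            evs = rr.detect_approaches(tr, turbines, CRIT, frame=frame)
            for e in evs:
                assert e.min_horizontal_distance <= CRIT.inner_radius
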