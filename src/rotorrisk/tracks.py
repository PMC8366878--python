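"""Flight-track ingestion, deduplication and approach/entry extraction.

Tracks are time-ordered 3-D positions (1 Hz nominal) recorded by camera
units, each carrying an eagle-classification confidence.  The pipeline
turns tracks into the risk model's observation unit: one binary datum per
*approach*, i.e. per track x turbine pair for which the track comes within
the inner curtailment cylinder (150 m by default), with outcome 1 when any
track point lies inside that turbine's rotor-swept zone.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .geometry import (
    CurtailmentCriteria,
    TurbineSpec,
    build_zones,
    enu_project,
)

__all__ = [
    "TrackPoint",
    "FlightTrack",
    "ApproachEvent",
    "FacilityFrame",
    "read_tracks",
    "write_tracks",
    "deduplicate_simultaneous",
    "detect_approaches",
    "build_dataset",
]

log = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "track_id",
    "unit_id",
    "unit_lat",
    "unit_lon",
    "timestamp",
    "lat",
    "lon",
    "alt_m",
    "confidence",
]


@dataclass(frozen=True)
class TrackPoint:
    """One recorded position; altitude in metres above local ground."""

    timestamp: float
    lat: float
    lon: float
    altitude: float
    confidence: float


@dataclass
class FlightTrack:
    """A time-ordered track from one recording unit.

    Point data are stored as parallel numpy arrays for speed; the
    ``points`` property materialises :class:`TrackPoint` objects on demand.
    """

    track_id: str
    unit_id: str
    unit_lat: float
    unit_lon: float
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    alt: np.ndarray
    conf: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError(f"track {self.track_id}: timestamps not strictly increasing")
        med = float(np.median(np.diff(self.t)))
        if not 0.2 <= med <= 5.0:
            raise ValueError(
                f"track {self.track_id}: median sampling interval {med:.3f} s "
                "outside [0.2, 5] s"
            )

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(*vals)
            for vals in zip(self.t, self.lat, self.lon, self.alt, self.conf)
        ]

    @property
    def max_confidence(self) -> float:
        return float(np.max(self.conf))


@dataclass(frozen=True)
class ApproachEvent:
    """One approach of one turbine by one track (the Bernoulli trial)."""

    track_id: str
    turbine_id: str
    month_key: str
    min_horizontal_distance: float
    entered: int
    t_first_inside_rsz: float | None


def month_key_of(timestamp: float) -> str:
    """Calendar month ('YYYY-MM', UTC) of a POSIX timestamp."""
    return datetime.fromtimestamp(float(timestamp), tz=timezone.utc).strftime("%Y-%m")


def _clip_altitudes(track_id: str, alt: np.ndarray) -> np.ndarray:
    below = alt < -10.0
    if np.any(below):
        log.warning(
            "track %s: %d altitude(s) below -10 m clipped to 0", track_id, int(below.sum())
        )
    return np.clip(alt, 0.0, None)


def _track_from_group(track_id: str, g: pd.DataFrame) -> FlightTrack:
    g = g.sort_values("timestamp", kind="mergesort")
    g = g.drop_duplicates(subset="timestamp", keep="first")
    return FlightTrack(
        track_id=str(track_id),
        unit_id=str(g["unit_id"].iloc[0]),
        unit_lat=float(g["unit_lat"].iloc[0]),
        unit_lon=float(g["unit_lon"].iloc[0]),
        t=g["timestamp"].to_numpy(dtype=float),
        lat=g["lat"].to_numpy(dtype=float),
        lon=g["lon"].to_numpy(dtype=float),
        alt=_clip_altitudes(str(track_id), g["alt_m"].to_numpy(dtype=float)),
        conf=g["confidence"].to_numpy(dtype=float),
    )


def read_tracks(path) -> list[FlightTrack]:
    """Read a track CSV, group by track id and validate each track.

    Tracks with fewer than two points, non-increasing time after
    deduplication, or an implausible sampling interval are dropped with a
    logged count rather than failing the whole file.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing column(s): {', '.join(missing)}")
    bad_ts = pd.to_numeric(df["timestamp"], errors="coerce").isna()
    if bad_ts.any():
        line = int(df.index[bad_ts][0]) + 2  # header + 1-based
        raise ValueError(f"unparseable timestamp at line {line}")
    tracks: list[FlightTrack] = []
    n_rejected = 0
    for tid, g in df.groupby("track_id", sort=True):
        try:
            tracks.append(_track_from_group(tid, g))
        except ValueError as exc:
            n_rejected += 1
            log.info("rejected track: %s", exc)
    if n_rejected:
        log.warning("rejected %d invalid track(s)", n_rejected)
    return tracks


def write_tracks(tracks: list[FlightTrack], path) -> None:
    """Write tracks in the same CSV schema that :func:`read_tracks` consumes."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "unit_id": tr.unit_id,
                    "unit_lat": tr.unit_lat,
                    "unit_lon": tr.unit_lon,
                    "timestamp": tr.t,
                    "lat": tr.lat,
                    "lon": tr.lon,
                    "alt_m": tr.alt,
                    "confidence": tr.conf,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def _los_distance(track: FlightTrack, idx: np.ndarray, frame: "FacilityFrame") -> float:
    """Mean 3-D line-of-sight distance from the recording unit to the bird."""
    ux, uy = enu_project(track.unit_lat, track.unit_lon, frame.ref_lat, frame.ref_lon)
    x, y = enu_project(track.lat[idx], track.lon[idx], frame.ref_lat, frame.ref_lon)
    return float(
        np.mean(np.sqrt((x - ux) ** 2 + (y - uy) ** 2 + track.alt[idx] ** 2))
    )


def deduplicate_simultaneous(
    tracks: list[FlightTrack],
    link_distance: float = 50.0,
    link_time: float = 1.0,
) -> list[FlightTrack]:
    """Merge tracks of the same bird recorded simultaneously by two units.

    Two tracks from different units are linked when their time ranges
    overlap and their positions at matched timestamps (within
    ``link_time`` seconds) lie within ``link_distance`` metres (median over
    matches).  Within the overlap, points from the unit with the greater
    mean 3-D line-of-sight distance to the bird are dropped; surviving
    points are merged into one track.  Pairs are examined in sorted
    (unit_id, track_id) order so 3-way overlaps resolve deterministically.
    """
    if not tracks:
        return []
    ref_lat = float(np.mean([tr.unit_lat for tr in tracks]))
    ref_lon = float(np.mean([tr.unit_lon for tr in tracks]))
    frame = _BareFrame(ref_lat, ref_lon)

    pool = sorted(tracks, key=lambda tr: (tr.unit_id, tr.track_id))
    out: list[FlightTrack] = []
    while pool:
        cur = pool.pop(0)
        merged = True
        while merged:
            merged = False
            for j, other in enumerate(pool):
                if other.unit_id == cur.unit_id:
                    continue
                pair = _try_link(cur, other, link_distance, link_time, frame)
                if pair is not None:
                    cur = pair
                    pool.pop(j)
                    merged = True
                    break
        out.append(cur)
    return out


class _BareFrame:
    def __init__(self, ref_lat: float, ref_lon: float) -> None:
        self.ref_lat = ref_lat
        self.ref_lon = ref_lon


def _try_link(a: FlightTrack, b: FlightTrack, link_distance, link_time, frame):
    lo = max(a.t[0], b.t[0])
    hi = min(a.t[-1], b.t[-1])
    if lo > hi:
        return None
    # Match each overlap point of a to its nearest-in-time point of b.
    ia = np.where((a.t >= lo) & (a.t <= hi))[0]
    if ia.size == 0:
        return None
    jb = np.searchsorted(b.t, a.t[ia])
    jb = np.clip(jb, 0, len(b.t) - 1)
    jb_prev = np.clip(jb - 1, 0, len(b.t) - 1)
    pick_prev = np.abs(b.t[jb_prev] - a.t[ia]) < np.abs(b.t[jb] - a.t[ia])
    jb = np.where(pick_prev, jb_prev, jb)
    close_t = np.abs(b.t[jb] - a.t[ia]) <= link_time
    if not np.any(close_t):
        return None
    ia, jb = ia[close_t], jb[close_t]
    ax, ay = enu_project(a.lat[ia], a.lon[ia], frame.ref_lat, frame.ref_lon)
    bx, by = enu_project(b.lat[jb], b.lon[jb], frame.ref_lat, frame.ref_lon)
    d = np.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (a.alt[ia] - b.alt[jb]) ** 2)
    if float(np.median(d)) > link_distance:
        return None

    # Same bird: drop the farther unit's points within the overlap.
    ib = np.where((b.t >= lo) & (b.t <= hi))[0]
    if _los_distance(a, ia, frame) <= _los_distance(b, ib, frame):
        near, far, far_overlap = a, b, ib
    else:
        near, far, far_overlap = b, a, np.where((a.t >= lo) & (a.t <= hi))[0]
    keep = np.setdiff1d(np.arange(far.n_points), far_overlap)
    t = np.concatenate([near.t, far.t[keep]])
    order = np.argsort(t, kind="mergesort")
    t = t[order]
    uniq = np.concatenate([[True], np.diff(t) > 0])
    cols = {}
    for name in ("lat", "lon", "alt", "conf"):
        merged = np.concatenate([getattr(near, name), getattr(far, name)[keep]])
        cols[name] = merged[order][uniq]
    return FlightTrack(
        track_id=near.track_id,
        unit_id=near.unit_id,
        unit_lat=near.unit_lat,
        unit_lon=near.unit_lon,
        t=t[uniq],
        lat=cols["lat"],
        lon=cols["lon"],
        alt=cols["alt"],
        conf=cols["conf"],
    )


class FacilityFrame:
    """Projected turbine layout: shared ENU frame plus per-turbine zones.

    The reference point is the centroid of the turbine locations, so all
    distances are consistent across tracks and turbines.
    """

    def __init__(self, turbines: list[TurbineSpec], criteria: CurtailmentCriteria):
        if not turbines:
            raise ValueError("empty turbine list")
        self.turbines = list(turbines)
        self.criteria = criteria
        self.ref_lat = float(np.mean([t.lat for t in turbines]))
        self.ref_lon = float(np.mean([t.lon for t in turbines]))
        x, y = enu_project(
            np.array([t.lat for t in turbines]),
            np.array([t.lon for t in turbines]),
            self.ref_lat,
            self.ref_lon,
        )
        self.x = np.atleast_1d(x)
        self.y = np.atleast_1d(y)
        self.zones = [
            build_zones(t, criteria, center_xy=(float(xi), float(yi)))
            for t, xi, yi in zip(turbines, self.x, self.y)
        ]
        self.rsz_radius = np.array([z["rsz"].radius for z in self.zones])
        self.rsz_zmin = np.array([z["rsz"].z_min for z in self.zones])
        self.rsz_zmax = np.array([z["rsz"].z_max for z in self.zones])
        self.inner_zmin = np.array([z["inner"].z_min for z in self.zones])
        self.inner_zmax = np.array([z["inner"].z_max for z in self.zones])

    def project_track(self, track: FlightTrack):
        x, y = enu_project(track.lat, track.lon, self.ref_lat, self.ref_lon)
        return np.atleast_1d(x), np.atleast_1d(y)


def detect_approaches(
    track: FlightTrack,
    turbines: list[TurbineSpec],
    criteria: CurtailmentCriteria,
    approach_mode: str = "inner_cylinder",
    frame: FacilityFrame | None = None,
) -> list[ApproachEvent]:
    """Find every turbine this track approaches and whether it entered.

    An approach is membership of the turbine's inner curtailment cylinder
    at >= 1 point (default), or pure horizontal distance <= inner radius
    when ``approach_mode='horizontal_only'``.  Entry is evaluated over the
    whole track: 1 when any point lies inside that turbine's rotor-swept
    zone.  The month key is the calendar month of the first in-cylinder
    point.  Tracks failing the confidence gate yield no events.
    """
    if approach_mode not in ("inner_cylinder", "horizontal_only"):
        raise ValueError(f"unknown approach_mode: {approach_mode}")
    if frame is None:
        frame = FacilityFrame(turbines, criteria)
    if track.max_confidence < criteria.confidence_threshold:
        return []
    x, y = frame.project_track(track)
    z = track.alt
    # (n_points, n_turbines) horizontal distances.
    d = np.sqrt((x[:, None] - frame.x[None, :]) ** 2 + (y[:, None] - frame.y[None, :]) ** 2)
    within_r = d <= criteria.inner_radius
    if approach_mode == "inner_cylinder":
        in_band = (z[:, None] >= frame.inner_zmin[None, :]) & (
            z[:, None] <= frame.inner_zmax[None, :]
        )
        in_approach = within_r & in_band
    else:
        in_approach = within_r
    in_rsz = (
        (d <= frame.rsz_radius[None, :])
        & (z[:, None] >= frame.rsz_zmin[None, :])
        & (z[:, None] <= frame.rsz_zmax[None, :])
    )
    events: list[ApproachEvent] = []
    for k in np.where(in_approach.any(axis=0))[0]:
        first_in = int(np.argmax(in_approach[:, k]))
        entered = bool(in_rsz[:, k].any())
        t_first_rsz = (
            float(track.t[int(np.argmax(in_rsz[:, k]))]) if entered else None
        )
        events.append(
            ApproachEvent(
                track_id=track.track_id,
                turbine_id=frame.turbines[k].turbine_id,
                month_key=month_key_of(track.t[first_in]),
                min_horizontal_distance=float(d[:, k].min()),
                entered=int(entered),
                t_first_inside_rsz=t_first_rsz,
            )
        )
    return events


def build_dataset(
    tracks: list[FlightTrack],
    turbines: list[TurbineSpec],
    criteria: CurtailmentCriteria,
    approach_mode: str = "inner_cylinder",
):
    """Assemble the entry-datum table from all tracks.

    Returns ``(data, maps, summary)`` where ``data`` is a DataFrame with
    one row per approach (columns track_id, turbine_id, month_key,
    turbine_index, month_index, y), ``maps`` holds the 1-based
    turbine/month index mappings, and ``summary`` the headline counts.
    """
    frame = FacilityFrame(turbines, criteria)
    rows = []
    n_tracks_used = 0
    per_track_counts: list[int] = []
    for tr in tracks:
        evs = detect_approaches(tr, turbines, criteria, approach_mode, frame)
        if tr.max_confidence >= criteria.confidence_threshold:
            n_tracks_used += 1
        if evs:
            per_track_counts.append(len(evs))
        for ev in evs:
            rows.append(
                {
                    "track_id": ev.track_id,
                    "turbine_id": ev.turbine_id,
                    "month_key": ev.month_key,
                    "y": ev.entered,
                }
            )
    if not rows:
        raise ValueError(
            "no approaches detected; supply more tracks or check turbine layout"
        )
    data = pd.DataFrame(rows)
    turbine_ids = sorted(data["turbine_id"].unique())
    month_keys = sorted(data["month_key"].unique())
    t_map = {tid: i + 1 for i, tid in enumerate(turbine_ids)}
    m_map = {mk: i + 1 for i, mk in enumerate(month_keys)}
    data["turbine_index"] = data["turbine_id"].map(t_map)
    data["month_index"] = data["month_key"].map(m_map)
    counts = np.array(per_track_counts)
    summary = {
        "n_tracks": n_tracks_used,
        "n_tracks_approaching": int(len(counts)),
        "n_approaches": int(len(data)),
        "n_entries": int(data["y"].sum()),
        "entry_rate": float(data["y"].mean()),
        "frac_tracks_single_turbine": float(np.mean(counts == 1)) if len(counts) else 0.0,
        "frac_tracks_multi_turbine": float(np.mean(counts >= 2)) if len(counts) else 0.0,
    }
    maps = {"turbine_index": t_map, "month_index": m_map}
    return data, maps, summary
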