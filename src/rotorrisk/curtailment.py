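"""Informed-curtailment decision rule and batch simulation.

A turbine is curtailed for a detected bird only when the bird is
classified as an eagle with sufficient confidence AND is inside the outer
cylinder, and then either (a) it is already inside the inner cylinder —
curtailment is always ordered — or (b) its straight-line extrapolated
trajectory would enter the rotor-swept zone within the time-to-collision
threshold.  Evaluation order: confidence, outer gate, inner trigger, TTC
trigger.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    CurtailmentCriteria,
    TurbineSpec,
    ZoneCylinder,
    point_in_cylinder,
    ray_cylinder_entry_time,
)
from .tracks import FacilityFrame, FlightTrack

__all__ = ["CurtailmentEvent", "curtailment_decision", "simulate_curtailments"]

TRIGGER_INNER = "inner_cylinder"
TRIGGER_TTC = "time_to_collision"


@dataclass(frozen=True)
class CurtailmentEvent:
    track_id: str
    turbine_id: str
    trigger: str
    timestamp: float

    def __post_init__(self) -> None:
        if self.trigger not in (TRIGGER_INNER, TRIGGER_TTC):
            raise ValueError(f"unknown trigger: {self.trigger}")


def curtailment_decision(
    position,
    velocity,
    confidence: float,
    zones: dict[str, ZoneCylinder],
    criteria: CurtailmentCriteria,
) -> str | None:
    """Decide whether one observed position triggers curtailment.

    Returns the trigger cause (``'inner_cylinder'`` or
    ``'time_to_collision'``) or ``None``.  ``velocity`` is the bird's ENU
    velocity in m/s, estimated upstream from consecutive track points.
    """
    if confidence < criteria.confidence_threshold:
        return None
    if not point_in_cylinder(position, zones["outer"]):
        return None
    if point_in_cylinder(position, zones["inner"]):
        return TRIGGER_INNER
    ttc = ray_cylinder_entry_time(position, velocity, zones["rsz"])
    if ttc is not None and ttc <= criteria.time_to_collision_threshold:
        return TRIGGER_TTC
    return None


def simulate_curtailments(
    tracks: list[FlightTrack],
    turbines: list[TurbineSpec],
    criteria: CurtailmentCriteria,
    frame: FacilityFrame | None = None,
):
    """Replay the decision rule over a track set.

    Each track is scanned point by point against each turbine; at most one
    event (the first trigger) is recorded per (track, turbine) pair.
    Velocity is the backward finite difference of consecutive points, so
    the first point of a track can only raise the inner-cylinder trigger.
    Returns ``(counts, events)`` with per-turbine order counts.
    """
    if frame is None:
        frame = FacilityFrame(turbines, criteria)
    counts = {t.turbine_id: 0 for t in turbines}
    events: list[CurtailmentEvent] = []
    for tr in tracks:
        if tr.max_confidence < criteria.confidence_threshold:
            continue
        x, y = frame.project_track(tr)
        z = tr.alt
        dt = np.diff(tr.t)
        vx = np.concatenate([[0.0], np.diff(x) / dt])
        vy = np.concatenate([[0.0], np.diff(y) / dt])
        vz = np.concatenate([[0.0], np.diff(z) / dt])
        # Pre-select turbines whose outer cylinder the track ever occupies.
        d2 = (x[:, None] - frame.x[None, :]) ** 2 + (y[:, None] - frame.y[None, :]) ** 2
        candidate = np.where((d2 <= criteria.outer_radius**2).any(axis=0))[0]
        for k in candidate:
            zones = frame.zones[k]
            conf_ok = tr.conf >= criteria.confidence_threshold
            in_outer = point_in_cylinder(np.column_stack([x, y, z]), zones["outer"])
            for i in np.where(conf_ok & in_outer)[0]:
                pos = (x[i], y[i], z[i])
                if point_in_cylinder(pos, zones["inner"]):
                    trig = TRIGGER_INNER
                elif i > 0:
                    ttc = ray_cylinder_entry_time(pos, (vx[i], vy[i], vz[i]), zones["rsz"])
                    if ttc is None or ttc > criteria.time_to_collision_threshold:
                        continue
                    trig = TRIGGER_TTC
                else:
                    continue
                tid = frame.turbines[k].turbine_id
                events.append(
                    CurtailmentEvent(
                        track_id=tr.track_id,
                        turbine_id=tid,
                        trigger=trig,
                        timestamp=float(tr.t[i]),
                    )
                )
                counts[tid] += 1
                break
    return counts, events
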