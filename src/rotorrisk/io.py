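"""CSV schemas for turbine tables and pipeline artifacts."""
from __future__ import annotations

import json

import pandas as pd

from .geometry import TurbineSpec

__all__ = ["read_turbines", "write_turbines", "write_json"]

TURBINE_COLUMNS = [
    "turbine_id",
    "model_name",
    "lat",
    "lon",
    "ground_elevation_m",
    "rotor_diameter_m",
    "hub_height_m",
    "max_blade_height_m",
]


def read_turbines(path) -> list[TurbineSpec]:
    df = pd.read_csv(path)
    missing = [c for c in TURBINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"turbine CSV missing column(s): {', '.join(missing)}")
    return [
        TurbineSpec(
            turbine_id=str(r.turbine_id),
            model_name=str(r.model_name),
            lat=float(r.lat),
            lon=float(r.lon),
            ground_elevation=float(r.ground_elevation_m),
            rotor_diameter=float(r.rotor_diameter_m),
            hub_height=float(r.hub_height_m),
            max_blade_height=float(r.max_blade_height_m),
        )
        for r in df.itertuples()
    ]


def write_turbines(turbines: list[TurbineSpec], path) -> None:
    pd.DataFrame(
        {
            "turbine_id": [t.turbine_id for t in turbines],
            "model_name": [t.model_name for t in turbines],
            "lat": [t.lat for t in turbines],
            "lon": [t.lon for t in turbines],
            "ground_elevation_m": [t.ground_elevation for t in turbines],
            "rotor_diameter_m": [t.rotor_diameter for t in turbines],
            "hub_height_m": [t.hub_height for t in turbines],
            "max_blade_height_m": [t.max_blade_height for t in turbines],
        }
    ).to_csv(path, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
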