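"""Result artifacts: risk map (GeoJSON), summary tables, monthly ranges.

The three standard outputs mirror how facility-level entry-risk results
are communicated: a map of turbines coloured by safer/average/riskier
class, per-scope posterior summary tables, and a per-turbine table of the
range of monthly entry probabilities for turbines monitored more than one
month.  Outputs are data files (GeoJSON / CSV), not rendered images.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .geometry import TurbineSpec
from .model import PosteriorDraws, cell_probabilities

__all__ = ["risk_map_geojson", "monthly_range_table"]


def risk_map_geojson(
    turbines: list[TurbineSpec],
    summary: pd.DataFrame,
    path=None,
) -> dict:
    """GeoJSON FeatureCollection of turbines with their risk class.

    Turbines absent from the summary (never approached) get class
    'unmonitored'.  Each turbine appears exactly once.
    """
    t_rows = summary[summary["scope"] == "turbine"].set_index("id")
    features = []
    for t in turbines:
        if t.turbine_id in t_rows.index:
            r = t_rows.loc[t.turbine_id]
            props = {
                "turbine_id": t.turbine_id,
                "model_name": t.model_name,
                "class": str(r["class_label"]),
                "posterior_mean": float(r["posterior_mean"]),
                "cri_low": float(r["cri_low"]),
                "cri_high": float(r["cri_high"]),
                "probability_of_direction": float(r["probability_of_direction"]),
            }
        else:
            props = {
                "turbine_id": t.turbine_id,
                "model_name": t.model_name,
                "class": "unmonitored",
            }
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [t.lon, t.lat]},
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh, indent=1)
    return fc


def monthly_range_table(
    draws: PosteriorDraws,
    turbine_ids: dict[int, str] | None = None,
    month_keys: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Min/max monthly entry probability per turbine observed > 1 month."""
    p_mean = cell_probabilities(draws, pooled=True).mean(axis=0)
    t_names = turbine_ids or {}
    m_names = month_keys or {}
    rows = []
    for t in np.unique(draws.cell_t):
        sel = draws.cell_t == t
        months = draws.cell_m[sel]
        if len(np.unique(months)) < 2:
            continue
        vals = p_mean[sel]
        i_min, i_max = int(np.argmin(vals)), int(np.argmax(vals))
        rows.append(
            {
                "turbine_id": t_names.get(int(t) + 1, f"turbine_{int(t) + 1}"),
                "n_months": int(len(np.unique(months))),
                "min_month": m_names.get(int(months[i_min]) + 1, f"month_{int(months[i_min]) + 1}"),
                "min_probability": float(vals[i_min]),
                "max_month": m_names.get(int(months[i_max]) + 1, f"month_{int(months[i_max]) + 1}"),
                "max_probability": float(vals[i_max]),
                "range": float(vals[i_max] - vals[i_min]),
            }
        )
    return pd.DataFrame(rows)
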