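"""Posterior summaries: reference average, probability of direction, classes.

The facility-wide reference is the average probability of entry — entries
divided by approaches — carried through the posterior as the count-weighted
mean of the cell probabilities in every draw.  Each turbine, month, and
turbine-month cell is compared against this reference by the probability
of direction: the proportion of draws in which (reference - quantity) is
strictly positive.  pd > 0.95 marks the quantity statistically safer than
average (lower entry probability), pd < 0.05 riskier.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .model import PosteriorDraws, cell_probabilities

__all__ = [
    "reference_average",
    "group_means",
    "probability_of_direction",
    "classify",
    "binomial_rate_cri",
    "extremal_ratio",
    "summary_table",
]

SAFER, AVERAGE, RISKIER = "safer", "average", "riskier"


def reference_average(p_draws: np.ndarray, n, y):
    """Facility average probability of entry, per posterior draw.

    ``p_draws`` is (n_draws, n_cells); ``n`` and ``y`` the per-cell
    approach and entry counts.  Returns ``(avg_draws, empirical)`` where
    ``avg_draws[s] = sum_c n_c * p_draws[s, c] / sum_c n_c`` (count-
    weighted, matching the empirical definition) and ``empirical`` is the
    observed entries/approaches ratio.
    """
    n = np.asarray(n, dtype=float)
    y = np.asarray(y, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("no approaches: reference average undefined")
    avg = p_draws @ n / total
    return avg, float(y.sum() / total)


def group_means(p_draws: np.ndarray, cell_t, cell_m, by: str):
    """Per-draw group means over observed cells.

    ``by='turbine'``: for each turbine, the unweighted mean of its cell
    probabilities over the months in which it was observed.  ``by='month'``:
    mean over the turbines observed in that month.  Returns
    ``(group_ids, means)`` with means shaped (n_draws, n_groups).
    """
    if by == "turbine":
        key = np.asarray(cell_t)
    elif by == "month":
        key = np.asarray(cell_m)
    else:
        raise ValueError("by must be 'turbine' or 'month'")
    ids = np.unique(key)
    means = np.empty((p_draws.shape[0], len(ids)))
    for j, g in enumerate(ids):
        means[:, j] = p_draws[:, key == g].mean(axis=1)
    return ids, means


def probability_of_direction(avg_draws: np.ndarray, quantity_draws: np.ndarray) -> float:
    """Proportion of draws with (average - quantity) strictly positive."""
    avg_draws = np.asarray(avg_draws, float)
    quantity_draws = np.asarray(quantity_draws, float)
    if avg_draws.shape != quantity_draws.shape:
        raise ValueError("draw vectors must be aligned")
    return float(np.mean(avg_draws - quantity_draws > 0))


def classify(pd_value: float, safer_threshold: float = 0.95, riskier_threshold: float = 0.05) -> str:
    """Label a quantity relative to the facility average.

    High pd means the quantity sits below the average in most draws
    (safer); low pd means above (riskier).
    """
    if not 0 <= pd_value <= 1:
        raise ValueError("probability of direction must be in [0, 1]")
    if pd_value > safer_threshold:
        return SAFER
    if pd_value < riskier_threshold:
        return RISKIER
    return AVERAGE


def binomial_rate_cri(successes: int, trials: int, level: float = 0.95):
    """Equal-tailed credible interval for a binomial rate, uniform prior.

    Posterior is Beta(successes + 1, trials - successes + 1); returns the
    (lower, upper) fractions.
    """
    if not 0 <= successes <= trials or trials <= 0:
        raise ValueError("need 0 <= successes <= trials, trials > 0")
    a = successes + 1
    b = trials - successes + 1
    tail = (1.0 - level) / 2.0
    return (
        float(beta_dist.ppf(tail, a, b)),
        float(beta_dist.ppf(1.0 - tail, a, b)),
    )


def extremal_ratio(values) -> float:
    """Ratio of the largest to the smallest value (riskiest vs least risky)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("need positive values")
    return float(v.max() / v.min())


def _row(scope, ident, q_draws, avg_draws, safer_t, riskier_t):
    pd_val = probability_of_direction(avg_draws, q_draws)
    lo, hi = np.percentile(q_draws, [2.5, 97.5])
    return {
        "scope": scope,
        "id": ident,
        "posterior_mean": float(np.mean(q_draws)),
        "cri_low": float(lo),
        "cri_high": float(hi),
        "probability_of_direction": pd_val,
        "class_label": classify(pd_val, safer_t, riskier_t),
    }


def summary_table(
    draws: PosteriorDraws,
    turbine_ids: dict[int, str] | None = None,
    month_keys: dict[int, str] | None = None,
    safer_threshold: float = 0.95,
    riskier_threshold: float = 0.05,
):
    """Full posterior summary: one row per scope plus headline statistics.

    Returns ``(table, headline)``.  The table holds the overall reference
    and every turbine, month, and observed turbine-month cell with its
    posterior mean, equal-tailed 95% CRI, probability of direction against
    the reference, and class label.  ``headline`` carries the facility-level
    statistics: empirical rate, reference CRI, max/min ratios of per-turbine
    and per-cell posterior means, the posterior SD of the cell
    probabilities, per-turbine monthly ranges, and class tallies.
    """
    p = cell_probabilities(draws, pooled=True)
    avg, empirical = reference_average(p, draws.cell_n, draws.cell_y)

    t_names = turbine_ids or {}
    m_names = month_keys or {}

    rows = [_row("overall", "facility", avg, avg, safer_threshold, riskier_threshold)]
    # overall row: pd against itself is 0 by the strict-inequality convention;
    # relabel as the reference row.
    rows[0]["probability_of_direction"] = np.nan
    rows[0]["class_label"] = AVERAGE

    t_ids, t_means = group_means(p, draws.cell_t, draws.cell_m, "turbine")
    for j, t in enumerate(t_ids):
        ident = t_names.get(int(t) + 1, f"turbine_{int(t) + 1}")
        rows.append(_row("turbine", ident, t_means[:, j], avg, safer_threshold, riskier_threshold))
    m_ids, m_means = group_means(p, draws.cell_t, draws.cell_m, "month")
    for j, m in enumerate(m_ids):
        ident = m_names.get(int(m) + 1, f"month_{int(m) + 1}")
        rows.append(_row("month", ident, m_means[:, j], avg, safer_threshold, riskier_threshold))
    for c in range(draws.n_cells):
        t, m = int(draws.cell_t[c]) + 1, int(draws.cell_m[c]) + 1
        ident = f"{t_names.get(t, f'turbine_{t}')}|{m_names.get(m, f'month_{m}')}"
        rows.append(_row("turbine_month", ident, p[:, c], avg, safer_threshold, riskier_threshold))

    table = pd.DataFrame(rows)

    cell_means = p.mean(axis=0)
    turbine_mean_pt = t_means.mean(axis=0)
    sd_draws = p.std(axis=1, ddof=1) if draws.n_cells > 1 else np.zeros(p.shape[0])
    sd_lo, sd_hi = (
        np.percentile(sd_draws, [2.5, 97.5]) if draws.n_cells > 1 else (0.0, 0.0)
    )

    # Per-turbine monthly range (turbines observed in > 1 month).
    ranges = {}
    for j, t in enumerate(t_ids):
        months = draws.cell_m[draws.cell_t == t]
        if len(np.unique(months)) > 1:
            vals = cell_means[draws.cell_t == t]
            ident = t_names.get(int(t) + 1, f"turbine_{int(t) + 1}")
            ranges[ident] = float(vals.max() - vals.min())

    avg_lo, avg_hi = np.percentile(avg, [2.5, 97.5])
    tm_table = table[table["scope"] == "turbine_month"]
    t_table = table[table["scope"] == "turbine"]
    m_table = table[table["scope"] == "month"]
    headline = {
        "empirical_entry_rate": empirical,
        "reference_mean": float(np.mean(avg)),
        "reference_cri": [float(avg_lo), float(avg_hi)],
        "turbine_ratio": extremal_ratio(turbine_mean_pt),
        "turbine_min": float(turbine_mean_pt.min()),
        "turbine_max": float(turbine_mean_pt.max()),
        "cell_ratio": extremal_ratio(cell_means),
        "cell_min": float(cell_means.min()),
        "cell_max": float(cell_means.max()),
        "cell_sd_mean": float(np.mean(sd_draws)),
        "cell_sd_cri": [float(sd_lo), float(sd_hi)],
        "monthly_range_max": max(ranges.values()) if ranges else 0.0,
        "monthly_range_min": min(ranges.values()) if ranges else 0.0,
        "monthly_ranges": ranges,
        "n_turbines_safer": int((t_table["class_label"] == SAFER).sum()),
        "n_turbines_riskier": int((t_table["class_label"] == RISKIER).sum()),
        "n_months_safer": int((m_table["class_label"] == SAFER).sum()),
        "n_months_riskier": int((m_table["class_label"] == RISKIER).sum()),
        "n_cells_safer": int((tm_table["class_label"] == SAFER).sum()),
        "n_cells_riskier": int((tm_table["class_label"] == RISKIER).sum()),
    }
    return table, headline
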