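import numpy as np
import pytest

import rotorrisk as rr
from rotorrisk.simulate import month_keys


@pytest.fixture(scope="session")
def small_sim():
    """A compact facility (12 turbines, ~400 approaches) for unit tests."""
    cfg = rr.SimulationConfig(
        n_turbines=12, n_siemens=5, total_approaches=400, seed=42
    )
    turbines, units, gt, tracks = rr.simulate_all(cfg)
    return cfg, turbines, units, gt, tracks


@pytest.fixture(scope="session")
def default_sim():
    """The study-scale fixture: 110 turbines, 11 months, ~10^4 approaches."""
    cfg = rr.SimulationConfig(seed=1)
    turbines, units, gt, tracks = rr.simulate_all(cfg)
    return cfg, turbines, units, gt, tracks


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """Full-regime MCMC fit (3 x 5,000, burn-in 500, thin 2) on the fixture."""
    cfg, turbines, units, gt, tracks = default_sim
    draws = rr.fit_mcmc(gt.outcomes, rr.ModelConfig(seed=1))
    return gt, draws


@pytest.fixture(scope="session")
def null_fit():
    """Fit on data generated with all effect SDs at zero (null facility)."""
    cfg = rr.SimulationConfig(
        sigma_alpha=0.0, sigma_beta=0.0, sigma_gamma=0.0, seed=5
    )
    gt = rr.simulate_outcomes(cfg)
    draws = rr.fit_mcmc(gt.outcomes, rr.ModelConfig(seed=5))
    return gt, draws


def cell_table_by_keys(data, cfg):
    """Map a processed dataset to (n, y) matrices on the generator's grid."""
    mk = {k: i for i, k in enumerate(month_keys(cfg))}
    n = np.zeros((cfg.n_turbines, cfg.n_months), dtype=int)
    y = np.zeros_like(n)
    g = (
        data.groupby(["turbine_id", "month_key"])["y"]
        .agg(["count", "sum"])
        .reset_index()
    )
    for r in g.itertuples():
        t = int(r.turbine_id[1:]) - 1
        n[t, mk[r.month_key]] = r.count
        y[t, mk[r.month_key]] = r.sum
    return n, y
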