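"""Hierarchical Bayesian Bernoulli model of rotor-swept-zone entry.

Each approach i of turbine t(i) in month m(i) is a Bernoulli trial:

    y_i ~ Bernoulli(p_{t(i), m(i)})
    logit p_tm = mu + alpha_t + beta_m + gamma_tm
    alpha_t ~ N(0, sigma2_alpha),  beta_m ~ N(0, sigma2_beta),
    gamma_tm ~ N(0, sigma2_gamma)

— a two-way random-effects ANOVA on the logit scale with a turbine x month
interaction, vague uniform priors on the grand mean and on each variance
component.  ``include_main_effects=False`` drops alpha and beta, leaving a
single random effect per turbine-month cell.

The sampler is an adaptive random-walk Metropolis-within-Gibbs: elementwise
random-walk updates for mu and the effect vectors (the Bernoulli likelihood
factorises over turbines / months / cells, so whole vectors are proposed and
accepted coordinate-wise), exact Gibbs draws for the variance components
(truncated inverse-gamma conditionals under the uniform-on-variance prior),
and likelihood-invariant translation moves that trade the grand mean against
each effect vector to decorrelate the weakly identified location split.
Step sizes adapt toward ~30% acceptance during burn-in only, preserving
detailed balance afterwards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import invgamma

__all__ = [
    "ModelConfig",
    "PosteriorDraws",
    "log_posterior",
    "fit_mcmc",
    "gelman_rubin",
    "cell_probabilities",
    "diagnostics_table",
    "save_draws",
    "load_draws",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """MCMC regime and prior bounds.

    Defaults follow a standard applied-Bayes setup for this model class:
    3 chains of 5,000 iterations, burn-in 500, thinning 2, uniform priors
    mu in [-10, 10] and each variance in [0, 25] (vague on the logit scale).
    """

    n_chains: int = 3
    n_iterations: int = 5000
    burn_in: int = 500
    thin: int = 2
    seed: int = 0
    mu_range: tuple[float, float] = (-10.0, 10.0)
    variance_range: tuple[float, float] = (0.0, 25.0)
    include_main_effects: bool = True

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for lo, hi in (self.mu_range, self.variance_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError("prior ranges must be finite with positive width")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Post-burn-in thinned draws, shaped (n_chains, n_kept, ...).

    ``cell_t``/``cell_m`` are 0-based turbine/month indices of the observed
    cells (cells with >= 1 approach), ``cell_n``/``cell_y`` the per-cell
    approach and entry counts.  gamma is stored per observed cell.
    """

    mu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sigma2_alpha: np.ndarray
    sigma2_beta: np.ndarray
    sigma2_gamma: np.ndarray
    cell_t: np.ndarray
    cell_m: np.ndarray
    cell_n: np.ndarray
    cell_y: np.ndarray
    n_turbines: int
    n_months: int
    config: ModelConfig

    @property
    def n_cells(self) -> int:
        return len(self.cell_t)

    def eta(self) -> np.ndarray:
        """Linear predictor per draw and observed cell, (chains, kept, cells)."""
        e = self.mu[..., None] + self.gamma
        if self.alpha.shape[-1]:
            e = e + self.alpha[..., self.cell_t] + self.beta[..., self.cell_m]
        return e


def prepare_cells(data: pd.DataFrame):
    """Aggregate the approach table to per-cell sufficient statistics.

    ``data`` needs columns turbine_index, month_index (1-based), y.
    Returns (cell_t, cell_m, cell_n, cell_y, T, M) with 0-based indices.
    """
    for col in ("turbine_index", "month_index", "y"):
        if col not in data.columns:
            raise ValueError(f"data missing column {col}")
    g = (
        data.groupby(["turbine_index", "month_index"])["y"]
        .agg(cell_y="sum", cell_n="count")
        .reset_index()
        .sort_values(["turbine_index", "month_index"], kind="mergesort")
    )
    cell_t = g["turbine_index"].to_numpy(int) - 1
    cell_m = g["month_index"].to_numpy(int) - 1
    if cell_t.min() < 0 or cell_m.min() < 0:
        raise ValueError("indices must be 1-based")
    T = int(cell_t.max()) + 1
    M = int(cell_m.max()) + 1
    return cell_t, cell_m, g["cell_n"].to_numpy(float), g["cell_y"].to_numpy(float), T, M


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _cell_loglik(eta, cell_y, cell_n):
    return cell_y * _log_sigmoid(eta) + (cell_n - cell_y) * _log_sigmoid(-eta)


def _normal_logpdf_sum(x: np.ndarray, s2: float) -> float:
    n = x.size
    return float(-0.5 * n * np.log(2 * np.pi * s2) - np.sum(x**2) / (2 * s2))


def log_posterior(params: dict, data: pd.DataFrame, config: ModelConfig) -> float:
    """Unnormalised log posterior density at one parameter point.

    ``params`` holds mu (scalar), alpha, beta (length T / M arrays; may be
    absent when main effects are off), gamma (one per observed cell, in
    (turbine, month) sort order), and the three variances.  Returns -inf
    outside the uniform prior support.
    """
    cell_t, cell_m, cell_n, cell_y, T, M = prepare_cells(data)
    mu = float(params["mu"])
    gamma = np.asarray(params["gamma"], dtype=float)
    if gamma.shape != cell_t.shape:
        raise ValueError("gamma must have one element per observed cell")
    mu_lo, mu_hi = config.mu_range
    v_lo, v_hi = config.variance_range
    if not mu_lo <= mu <= mu_hi:
        return -np.inf
    s2g = float(params["sigma2_gamma"])
    variances = [s2g]
    eta = mu + gamma
    lp = 0.0
    if config.include_main_effects:
        alpha = np.asarray(params["alpha"], dtype=float)
        beta = np.asarray(params["beta"], dtype=float)
        if alpha.size != T or beta.size != M:
            raise ValueError(f"alpha/beta must have length {T}/{M}")
        s2a = float(params["sigma2_alpha"])
        s2b = float(params["sigma2_beta"])
        variances += [s2a, s2b]
        if not all(v_lo <= v <= v_hi for v in variances):
            return -np.inf
        if s2a <= 0 or s2b <= 0 or s2g <= 0:
            return -np.inf
        eta = eta + alpha[cell_t] + beta[cell_m]
        lp += _normal_logpdf_sum(alpha, s2a) + _normal_logpdf_sum(beta, s2b)
    else:
        if not v_lo <= s2g <= v_hi or s2g <= 0:
            return -np.inf
    lp += _normal_logpdf_sum(gamma, s2g)
    lp += float(np.sum(_cell_loglik(eta, cell_y, cell_n)))
    return lp


def _sample_variance(rng, ss: float, k: int, lo: float, hi: float, current: float) -> float:
    """Draw sigma^2 from its conditional: truncated InvGamma(k/2 - 1, ss/2)."""
    shape = k / 2.0 - 1.0
    eps = 1e-12
    lo = max(lo, eps)
    if ss <= eps:
        return current
    if shape > 0.05:
        c_lo = invgamma.cdf(lo, shape, scale=ss / 2.0)
        c_hi = invgamma.cdf(hi, shape, scale=ss / 2.0)
        if c_hi - c_lo < 1e-12:
            return float(np.clip(current, lo, hi))
        u = rng.uniform(c_lo, c_hi)
        return float(np.clip(invgamma.ppf(u, shape, scale=ss / 2.0), lo, hi))
    # Few effects: conditional has no standard form worth trusting; use a
    # random-walk step on sigma^2 against the exact conditional density.
    prop = current + 0.5 * (hi - lo) * 0.1 * rng.standard_normal()
    if not lo <= prop <= hi:
        return current
    logdens = lambda v: -0.5 * k * np.log(v) - ss / (2.0 * v)
    if np.log(rng.uniform()) < logdens(prop) - logdens(current):
        return float(prop)
    return current


class _Adapt:
    """Per-block step sizes with acceptance-rate adaptation during burn-in."""

    def __init__(self, size, step=0.3, target=0.3, interval=50):
        self.log_step = np.full(size, np.log(step))
        self.acc = np.zeros(size)
        self.target = target
        self.interval = interval
        self.count = 0

    @property
    def step(self):
        return np.exp(self.log_step)

    def update(self, accepted, adapting: bool):
        self.acc += accepted
        self.count += 1
        if adapting and self.count % self.interval == 0:
            rate = self.acc / self.interval
            self.log_step += np.clip(rate - self.target, -0.5, 0.5)
            self.log_step = np.clip(self.log_step, np.log(1e-4), np.log(10.0))
            self.acc[:] = 0.0


def fit_mcmc(data: pd.DataFrame, config: ModelConfig | None = None) -> PosteriorDraws:
    """Fit the model by MCMC; reproducible given ``config.seed``."""
    if config is None:
        config = ModelConfig()
    if len(data) == 0:
        raise ValueError("empty dataset")
    cell_t, cell_m, cell_n, cell_y, T, M = prepare_cells(data)
    C = len(cell_t)
    total_y = cell_y.sum()
    total_n = cell_n.sum()
    if total_y == 0 or total_y == total_n:
        log.warning("all responses identical (%d/%d); posterior near prior boundary",
                    int(total_y), int(total_n))
    main = config.include_main_effects

    K = config.n_kept
    out = {
        "mu": np.empty((config.n_chains, K)),
        "alpha": np.empty((config.n_chains, K, T if main else 0)),
        "beta": np.empty((config.n_chains, K, M if main else 0)),
        "gamma": np.empty((config.n_chains, K, C)),
        "s2a": np.empty((config.n_chains, K)),
        "s2b": np.empty((config.n_chains, K)),
        "s2g": np.empty((config.n_chains, K)),
    }

    mu_lo, mu_hi = config.mu_range
    v_lo, v_hi = config.variance_range
    v_mid = v_lo + 0.5 * (v_hi - v_lo)
    mu_emp = float(np.log((total_y + 0.5) / (total_n - total_y + 0.5)))

    for chain in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, chain)))
        mu = float(np.clip(mu_emp + 0.5 * rng.standard_normal(), mu_lo, mu_hi))
        alpha = 0.1 * rng.standard_normal(T) if main else np.zeros(0)
        beta = 0.1 * rng.standard_normal(M) if main else np.zeros(0)
        gamma = 0.1 * rng.standard_normal(C)
        s2a = float(np.clip(v_mid * rng.uniform(0.5, 1.5), v_lo + 1e-6, v_hi))
        s2b = float(np.clip(v_mid * rng.uniform(0.5, 1.5), v_lo + 1e-6, v_hi))
        s2g = float(np.clip(v_mid * rng.uniform(0.5, 1.5), v_lo + 1e-6, v_hi))

        ad_mu = _Adapt(1, step=0.1)
        ad_alpha = _Adapt(T, step=0.3) if main else None
        ad_beta = _Adapt(M, step=0.3) if main else None
        ad_gamma = _Adapt(C, step=0.5)
        ad_shift_a = _Adapt(1, step=0.1)
        ad_shift_b = _Adapt(1, step=0.1)
        ad_shift_g = _Adapt(1, step=0.1)

        def eta_of():
            e = mu + gamma
            if main:
                e = e + alpha[cell_t] + beta[cell_m]
            return e

        eta = eta_of()
        ll = _cell_loglik(eta, cell_y, cell_n)
        kept = 0
        for it in range(config.n_iterations):
            adapting = it < config.burn_in

            # -- grand mean --
            delta = float(ad_mu.step[0] * rng.standard_normal())
            prop = mu + delta
            if mu_lo <= prop <= mu_hi:
                ll_new = _cell_loglik(eta + delta, cell_y, cell_n)
                acc = np.log(rng.uniform()) < (ll_new.sum() - ll.sum())
                if acc:
                    mu, eta, ll = prop, eta + delta, ll_new
            else:
                acc = False
            ad_mu.update(np.array([acc]), adapting)

            # -- turbine main effects (coordinate-wise; likelihood factorises) --
            if main:
                d_a = ad_alpha.step * rng.standard_normal(T)
                ll_new = _cell_loglik(eta + d_a[cell_t], cell_y, cell_n)
                dll = np.bincount(cell_t, weights=ll_new - ll, minlength=T)
                dprior = (alpha**2 - (alpha + d_a) ** 2) / (2.0 * s2a)
                acc_a = np.log(rng.uniform(size=T)) < dll + dprior
                alpha = np.where(acc_a, alpha + d_a, alpha)
                hit = acc_a[cell_t]
                eta = np.where(hit, eta + d_a[cell_t], eta)
                ll = np.where(hit, ll_new, ll)
                ad_alpha.update(acc_a, adapting)

                d_b = ad_beta.step * rng.standard_normal(M)
                ll_new = _cell_loglik(eta + d_b[cell_m], cell_y, cell_n)
                dll = np.bincount(cell_m, weights=ll_new - ll, minlength=M)
                dprior = (beta**2 - (beta + d_b) ** 2) / (2.0 * s2b)
                acc_b = np.log(rng.uniform(size=M)) < dll + dprior
                beta = np.where(acc_b, beta + d_b, beta)
                hit = acc_b[cell_m]
                eta = np.where(hit, eta + d_b[cell_m], eta)
                ll = np.where(hit, ll_new, ll)
                ad_beta.update(acc_b, adapting)

            # -- interaction effects (cell-wise) --
            d_g = ad_gamma.step * rng.standard_normal(C)
            ll_new = _cell_loglik(eta + d_g, cell_y, cell_n)
            dprior = (gamma**2 - (gamma + d_g) ** 2) / (2.0 * s2g)
            acc_g = np.log(rng.uniform(size=C)) < (ll_new - ll) + dprior
            gamma = np.where(acc_g, gamma + d_g, gamma)
            eta = np.where(acc_g, eta + d_g, eta)
            ll = np.where(acc_g, ll_new, ll)
            ad_gamma.update(acc_g, adapting)

            # -- variance components: exact Gibbs --
            if main:
                s2a = _sample_variance(rng, float(np.sum(alpha**2)), T, v_lo, v_hi, s2a)
                s2b = _sample_variance(rng, float(np.sum(beta**2)), M, v_lo, v_hi, s2b)
            s2g = _sample_variance(rng, float(np.sum(gamma**2)), C, v_lo, v_hi, s2g)

            # -- translation moves: mu <-> effect vector (likelihood invariant) --
            for vec, s2, nvec, ad in (
                ((alpha, s2a, T, ad_shift_a) if main else (None, 0, 0, None)),
                ((beta, s2b, M, ad_shift_b) if main else (None, 0, 0, None)),
                (gamma, s2g, C, ad_shift_g),
            ):
                if vec is None:
                    continue
                d = float(ad.step[0] * rng.standard_normal())
                prop_mu = mu + d
                if mu_lo <= prop_mu <= mu_hi:
                    # prior ratio of shifting the whole vector by -d
                    dlp = (2.0 * d * vec.sum() - nvec * d * d) / (2.0 * s2)
                    acc_s = np.log(rng.uniform()) < dlp
                    if acc_s:
                        mu = prop_mu
                        vec -= d
                else:
                    acc_s = False
                ad.update(np.array([acc_s]), adapting)

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                out["mu"][chain, kept] = mu
                if main:
                    out["alpha"][chain, kept] = alpha
                    out["beta"][chain, kept] = beta
                out["gamma"][chain, kept] = gamma
                out["s2a"][chain, kept] = s2a
                out["s2b"][chain, kept] = s2b
                out["s2g"][chain, kept] = s2g
                kept += 1

    return PosteriorDraws(
        mu=out["mu"],
        alpha=out["alpha"],
        beta=out["beta"],
        gamma=out["gamma"],
        sigma2_alpha=out["s2a"],
        sigma2_beta=out["s2b"],
        sigma2_gamma=out["s2g"],
        cell_t=cell_t,
        cell_m=cell_m,
        cell_n=cell_n,
        cell_y=cell_y,
        n_turbines=T,
        n_months=M,
        config=config,
    )


def gelman_rubin(chains) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar.

    ``chains`` is (m, n): m >= 2 chains of n >= 2 draws.  Computes
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with B = n * Var(chain means)
    and W the mean within-chain sample variance.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    n = x.shape[1]
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        log.warning("constant chains; R-hat undefined, returning 1.0")
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def cell_probabilities(draws: PosteriorDraws, pooled: bool = True) -> np.ndarray:
    """Entry probability per draw for every observed turbine-month cell.

    Returns (n_draws_total, n_cells) with chains pooled (default) or
    (n_chains, n_kept, n_cells).
    """
    p = expit(draws.eta())
    if pooled:
        return p.reshape(-1, draws.n_cells)
    return p


def _ess(chains: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    m, n = chains.shape
    x = chains - chains.mean(axis=1, keepdims=True)
    var = np.mean(np.var(chains, axis=1, ddof=1))
    if var == 0:
        return float(m * n)
    max_lag = min(n - 1, 200)
    rho_sum = 0.0
    for lag in range(1, max_lag, 2):
        r1 = np.mean([np.dot(x[c, :-lag], x[c, lag:]) / n for c in range(m)]) / var
        if lag + 1 < n:
            r2 = np.mean(
                [np.dot(x[c, : -(lag + 1)], x[c, lag + 1 :]) / n for c in range(m)]
            ) / var
        else:
            r2 = 0.0
        if r1 + r2 < 0:
            break
        rho_sum += r1 + r2
    return float(m * n / (1.0 + 2.0 * rho_sum))


def diagnostics_table(draws: PosteriorDraws) -> pd.DataFrame:
    """R-hat and effective draw count for the monitored quantities.

    Monitors the grand mean, the variance components, and every observed
    cell probability (the identified quantities); effect vectors are only
    identified jointly with mu, so their convergence is assessed through
    the cell probabilities.
    """
    rows = []

    def add(name, chains):
        rows.append(
            {"parameter": name, "rhat": gelman_rubin(chains), "ess": _ess(chains)}
        )

    add("mu", draws.mu)
    if draws.alpha.shape[-1]:
        add("sigma2_alpha", draws.sigma2_alpha)
        add("sigma2_beta", draws.sigma2_beta)
    add("sigma2_gamma", draws.sigma2_gamma)
    p = cell_probabilities(draws, pooled=False)
    for c in range(draws.n_cells):
        add(f"p[{draws.cell_t[c] + 1},{draws.cell_m[c] + 1}]", p[:, :, c])
    return pd.DataFrame(rows)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist draws as a compact .npz cache (exact round trip)."""
    import json as _json
    from dataclasses import asdict

    cfg = asdict(draws.config)
    cfg["mu_range"] = list(cfg["mu_range"])
    cfg["variance_range"] = list(cfg["variance_range"])
    np.savez_compressed(
        path,
        mu=draws.mu,
        alpha=draws.alpha,
        beta=draws.beta,
        gamma=draws.gamma,
        sigma2_alpha=draws.sigma2_alpha,
        sigma2_beta=draws.sigma2_beta,
        sigma2_gamma=draws.sigma2_gamma,
        cell_t=draws.cell_t,
        cell_m=draws.cell_m,
        cell_n=draws.cell_n,
        cell_y=draws.cell_y,
        dims=np.array([draws.n_turbines, draws.n_months]),
        config=np.array(_json.dumps(cfg)),
    )


def load_draws(path) -> PosteriorDraws:
    import json as _json

    with np.load(path, allow_pickle=False) as z:
        cfg = _json.loads(str(z["config"]))
        cfg["mu_range"] = tuple(cfg["mu_range"])
        cfg["variance_range"] = tuple(cfg["variance_range"])
        return PosteriorDraws(
            mu=z["mu"],
            alpha=z["alpha"],
            beta=z["beta"],
            gamma=z["gamma"],
            sigma2_alpha=z["sigma2_alpha"],
            sigma2_beta=z["sigma2_beta"],
            sigma2_gamma=z["sigma2_gamma"],
            cell_t=z["cell_t"],
            cell_m=z["cell_m"],
            cell_n=z["cell_n"],
            cell_y=z["cell_y"],
            n_turbines=int(z["dims"][0]),
            n_months=int(z["dims"][1]),
            config=ModelConfig(**cfg),
        )
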