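import numpy as np
import pandas as pd
import pytest

import rotorrisk as rr
from rotorrisk.model import ModelConfig, PosteriorDraws


def make_draws(p_cells, cell_t, cell_m, n=None, y=None, jitter=0.0, seed=0):
    """Posterior-draw container with prescribed cell probabilities."""
    rng = np.random.default_rng(seed)
    p_cells = np.asarray(p_cells, dtype=float)
    C = len(p_cells)
    S = 400
    from scipy.special import logit

    eta = logit(p_cells)[None, None, :] + jitter * rng.standard_normal((1, S, C))
    cfg = ModelConfig(n_chains=1, n_iterations=S + 1, burn_in=1, thin=1)
    cell_t = np.asarray(cell_t)
    cell_m = np.asarray(cell_m)
    return PosteriorDraws(
        mu=np.zeros((1, S)),
        alpha=np.zeros((1, S, 0)),
        beta=np.zeros((1, S, 0)),
        gamma=eta,
        sigma2_alpha=np.ones((1, S)),
        sigma2_beta=np.ones((1, S)),
        sigma2_gamma=np.ones((1, S)),
        cell_t=cell_t,
        cell_m=cell_m,
        cell_n=np.full(C, 10.0) if n is None else np.asarray(n, float),
        cell_y=np.full(C, 3.0) if y is None else np.asarray(y, float),
        n_turbines=int(cell_t.max()) + 1,
        n_months=int(cell_m.max()) + 1,
        config=cfg,
    )


class TestReferenceAverage:
    def test_study_counts_give_29_5_percent(self):
        p = np.full((5, 1), 0.3)
        avg, empirical = rr.reference_average(p, [10222], [3015])
        assert round(empirical * 100, 1) == 29.5
        assert empirical == pytest.approx(3015 / 10222)

    def test_constant_cells_ignore_weights(self):
        p = np.full((3, 4), 0.3)
        avg, _ = rr.reference_average(p, [1, 10, 100, 5], [0, 1, 2, 3])
        assert np.allclose(avg, 0.3)

    def test_weighted_mean(self):
        p = np.array([[0.1, 0.5]])
        avg, emp = rr.reference_average(p, [10, 30], [1, 15])
        assert avg[0] == pytest.approx(0.4)
        assert emp == pytest.approx(16 / 40)

    def test_zero_approaches_error(self):
        with pytest.raises(ValueError):
            rr.reference_average(np.ones((1, 1)), [0], [0])

    def test_bounded_by_cell_extremes_per_draw(self, default_fit):
        gt, draws = default_fit
        p = rr.cell_probabilities(draws)[:500]
        avg, _ = rr.reference_average(p, draws.cell_n, draws.cell_y)
        assert np.all(avg >= p.min(axis=1) - 1e-12)
        assert np.all(avg <= p.max(axis=1) + 1e-12)


class TestGroupMeans:
    def test_turbine_mean_over_observed_months(self):
        p = np.array([[0.2, 0.4, 0.6]])
        ids, m = rr.group_means(p, [0, 0, 1], [0, 1, 0], "turbine")
        assert list(ids) == [0, 1]
        assert m[0, 0] == pytest.approx(0.3)
        assert m[0, 1] == pytest.approx(0.6)  # single-month turbine

    def test_month_mean_over_turbines(self):
        p = np.array([[0.1, 0.2, 0.6]])
        ids, m = rr.group_means(p, [0, 1, 2], [0, 0, 0], "month")
        assert m[0, 0] == pytest.approx(0.3)


class TestProbabilityOfDirection:
    def test_always_below_average_gives_one(self):
        assert rr.probability_of_direction([0.3, 0.3], [0.1, 0.2]) == 1.0

    def test_mixed_directions_counted(self):
        pd_val = rr.probability_of_direction([0.3, 0.3, 0.3], [0.2, 0.4, 0.2])
        assert pd_val == pytest.approx(2 / 3)

    def test_exact_ties_count_as_not_greater(self):
        assert rr.probability_of_direction([0.3, 0.3], [0.3, 0.3]) == 0.0


class TestClassify:
    @pytest.mark.parametrize(
        "pd_val,expected", [(0.976, "safer"), (0.0, "riskier"), (0.5, "average")]
    )
    def test_default_thresholds(self, pd_val, expected):
        assert rr.classify(pd_val) == expected

    def test_configurable_thresholds(self):
        assert rr.classify(0.92, safer_threshold=0.90, riskier_threshold=0.10) == "safer"
        assert rr.classify(0.92) == "average"


class TestBinomialRateCri:
    def test_study_counts_reproduce_printed_bounds(self):
        lo, hi = rr.binomial_rate_cri(3015, 10222)
        assert round(lo * 100, 1) == 28.6
        assert round(hi * 100, 1) == 30.4

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rr.binomial_rate_cri(5, 0)


class TestExtremalRatio:
    def test_per_turbine_printed_extremes(self):
        assert round(rr.extremal_ratio([0.190, 0.454]), 2) == 2.39

    def test_per_cell_printed_extremes(self):
        assert round(rr.extremal_ratio([0.153, 0.617]), 2) == 4.03

    def test_constant_values_ratio_one(self):
        assert rr.extremal_ratio([0.3, 0.3, 0.3]) == 1.0


class TestSummaryTable:
    def test_degenerate_identical_cells(self):
        d = make_draws([0.3, 0.3, 0.3], [0, 1, 2], [0, 0, 0])
        table, headline = rr.summary_table(d)
        tm = table[table["scope"] == "turbine_month"]
        # exact ties: strict ">" makes every pd 0 (documented degenerate case)
        assert np.allclose(tm["probability_of_direction"], 0.0)
        assert headline["turbine_ratio"] == pytest.approx(1.0)
        assert headline["cell_ratio"] == pytest.approx(1.0)
        assert headline["cell_sd_mean"] == pytest.approx(0.0)

    def test_permutation_equivariance(self):
        p = [0.15, 0.35, 0.55, 0.25]
        d1 = make_draws(p, [0, 0, 1, 1], [0, 1, 0, 1], jitter=0.3, seed=1)
        perm = [0.55, 0.25, 0.15, 0.35]  # swap turbine labels 0 <-> 1
        d2 = make_draws(perm, [0, 0, 1, 1], [0, 1, 0, 1], jitter=0.3, seed=1)
        # same draws, relabeled: regenerate d2's gamma as d1's permuted
        d2.gamma = d1.gamma[:, :, [2, 3, 0, 1]]
        t1, h1 = rr.summary_table(d1)
        t2, h2 = rr.summary_table(d2)
        r1 = t1[t1["scope"] == "turbine"].set_index("id")
        r2 = t2[t2["scope"] == "turbine"].set_index("id")
        assert r1.loc["turbine_1", "posterior_mean"] == pytest.approx(
            r2.loc["turbine_2", "posterior_mean"]
        )
        assert h1["turbine_ratio"] == pytest.approx(h2["turbine_ratio"])
        assert h1["cell_ratio"] == pytest.approx(h2["cell_ratio"])

    def test_pd_complement_sums_to_one_without_ties(self):
        d = make_draws([0.2, 0.5], [0, 1], [0, 0], jitter=0.4, seed=2)
        p = rr.cell_probabilities(d)
        avg, _ = rr.reference_average(p, d.cell_n, d.cell_y)
        pd_lo = rr.probability_of_direction(avg, p[:, 0])
        pd_hi_complement = np.mean(avg - p[:, 0] <= 0)
        assert pd_lo + pd_hi_complement == pytest.approx(1.0)

    def test_named_rows_and_monthly_ranges(self, default_fit):
        gt, draws = default_fit
        table, headline = rr.summary_table(draws)
        assert set(table["scope"]) == {"overall", "turbine", "month", "turbine_month"}
        n_turbines = len(np.unique(draws.cell_t))
        n_months = len(np.unique(draws.cell_m))
        assert (table["scope"] == "turbine").sum() == n_turbines
        assert (table["scope"] == "month").sum() == n_months
        assert (table["scope"] == "turbine_month").sum() == draws.n_cells
        assert (table["cri_low"] <= table["posterior_mean"]).all()
        assert (table["posterior_mean"] <= table["cri_high"]).all()
        assert headline["monthly_range_max"] >= headline["monthly_range_min"] >= 0.0


class TestNullCalibration:
    def test_few_cells_flagged_when_no_true_variation(self, null_fit):
        """False-flag rate at 0.95/0.05 stays under 10% with flat truth."""
        gt, draws = null_fit
        table, headline = rr.summary_table(draws)
        tm = table[table["scope"] == "turbine_month"]
        frac_flagged = (tm["class_label"] != "average").mean()
        assert frac_flagged <= 0.10
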