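"""ABC machinery against brute-force and weighted-least-squares oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from metapopabc.inference import (
    PosteriorSample,
    ReferenceTable,
    loclinear_adjust,
    model_choice,
    posterior_summary,
    reject,
    weighted_quantile,
)
from metapopabc.models import PriorSpec


def toy_table(stats, params=None, model="COS"):
    stats = np.asarray(stats, dtype=float)
    if params is None:
        params = pd.DataFrame({"N": np.arange(len(stats), dtype=float) + 1})
    return ReferenceTable(model, params, stats)


class TestRejection:
    def test_retained_set_equals_brute_force_sort(self):
        rng = np.random.default_rng(0)
        stats = rng.normal(size=(10, 3))
        obs = rng.normal(size=3)
        table = toy_table(stats)
        sample = reject(table, obs, 3)
        # independent oracle: exhaustive standardized euclidean sort
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        d = np.sqrt((((stats - obs) / mad) ** 2).sum(axis=1))
        expect = np.argsort(d, kind="stable")[:3]
        assert (sample.indices == expect).all()
        assert (np.diff(sample.distances) >= 0).all()

    def test_exact_match_retained_at_distance_zero(self):
        stats = np.arange(12, dtype=float).reshape(6, 2)
        table = toy_table(stats)
        sample = reject(table, stats[4], 2)
        assert sample.indices[0] == 4
        assert sample.distances[0] == 0.0

    def test_no_rejection_limit_retains_everything(self):
        table = toy_table(np.random.default_rng(1).normal(size=(50, 2)))
        sample = reject(table, np.zeros(2), 50)
        assert sample.n == 50
        assert sample.weights.sum() == pytest.approx(1.0)

    def test_invariant_to_affine_rescaling_of_statistics(self):
        rng = np.random.default_rng(2)
        stats = rng.normal(size=(40, 3))
        obs = rng.normal(size=3)
        scaled = stats.copy()
        scaled[:, 1] = 1000.0 * scaled[:, 1] - 77.0
        obs2 = obs.copy()
        obs2[1] = 1000.0 * obs2[1] - 77.0
        a = reject(toy_table(stats), obs, 10)
        b = reject(toy_table(scaled), obs2, 10)
        assert (a.indices == b.indices).all()

    def test_bad_arguments_rejected(self):
        table = toy_table(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            reject(table, np.zeros(2), 0)
        with pytest.raises(ValueError):
            reject(table, np.zeros(2), 6)
        with pytest.raises(ValueError):
            reject(table, np.zeros(3), 2)


class TestLocalLinearAdjustment:
    def make_linear_sample(self, slope=2.0, noise=0.05, n=200, seed=3):
        # theta straddles zero so the adjustment stays on the linear scale
        rng = np.random.default_rng(seed)
        stat = rng.uniform(0, 1, size=(n, 1))
        theta = slope * stat[:, 0] - 1.0 + rng.normal(0, noise, n)
        table = ReferenceTable("COS", pd.DataFrame({"theta": theta}), stat)
        return table

    def test_zero_slope_leaves_values_unchanged(self):
        rng = np.random.default_rng(4)
        stats = rng.normal(size=(100, 2))
        params = pd.DataFrame({"theta": np.full(100, 5.0)})  # no dependence at all
        sample = reject(ReferenceTable("COS", params, stats), np.zeros(2), 50)
        adj = loclinear_adjust(sample, np.zeros(2))
        assert np.allclose(adj.params["theta"], 5.0, atol=1e-8)

    def test_planted_linear_relation_matches_wls_oracle(self):
        # theta = 2*stat + eps: the adjusted posterior mean at the observed
        # statistic must match an explicit weighted-least-squares prediction
        table = self.make_linear_sample()
        obs = np.array([0.5])
        sample = reject(table, obs, 100)
        adj = loclinear_adjust(sample, obs)
        # independent WLS oracle on the same retained points/weights
        X = np.column_stack([np.ones(sample.n), sample.stats[:, 0] - 0.5])
        W = np.diag(sample.weights)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ sample.params["theta"].to_numpy())
        post_mean = float(np.sum(adj.params["theta"] * adj.weights))
        assert post_mean == pytest.approx(beta[0], abs=0.02)
        assert post_mean == pytest.approx(2 * 0.5 - 1.0, abs=0.1)

    def test_adjustment_reduces_posterior_mean_error(self):
        errs_rej, errs_adj = [], []
        for seed in range(10):
            table = self.make_linear_sample(seed=seed, noise=0.1)
            obs = np.array([0.25])
            sample = reject(table, obs, 120)
            adj = loclinear_adjust(sample, obs)
            truth = 2 * 0.25 - 1.0
            errs_rej.append((np.sum(sample.params["theta"] * sample.weights) - truth) ** 2)
            errs_adj.append((np.sum(adj.params["theta"] * adj.weights) - truth) ** 2)
        assert np.mean(errs_adj) < np.mean(errs_rej)

    def test_adjusted_draws_clamped_to_prior_support(self):
        rng = np.random.default_rng(5)
        n = 150
        nm = rng.uniform(0.05, 250, n)
        stat = (nm / 250 + rng.normal(0, 0.02, n))[:, None]
        table = ReferenceTable("FIM", pd.DataFrame({"Nm": nm}), stat)
        priors = {"Nm": PriorSpec("Nm", "uniform", (0.05, 250.0))}
        for obs in ([0.0], [1.0]):  # push the regression beyond both bounds
            sample = reject(table, np.array(obs), 80)
            adj = loclinear_adjust(sample, np.array(obs), priors)
            assert adj.params["Nm"].min() >= 0.05
            assert adj.params["Nm"].max() <= 250.0

    def test_exactly_collinear_statistics_still_adjust(self):
        # proportions summing to one must not trigger the singular fallback
        table = self.make_linear_sample()
        stats3 = np.column_stack([table.stats[:, 0], 1 - table.stats[:, 0], table.stats[:, 0]])
        table3 = ReferenceTable("COS", table.params, stats3)
        obs = np.array([0.5, 0.5, 0.5])
        sample = reject(table3, obs, 100)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            adj = loclinear_adjust(sample, obs)
        assert adj.adjusted
        assert not np.allclose(adj.params["theta"], sample.params["theta"])

    def test_too_few_retained_points_rejected(self):
        table = self.make_linear_sample(n=3)
        sample = reject(table, np.array([0.5]), 2)
        with pytest.raises(ValueError, match="p\\+2"):
            loclinear_adjust(sample, np.array([0.5]))


class TestModelChoice:
    def make_tables(self, mu_a, mu_b, n=400, seed=6):
        rng = np.random.default_rng(seed)
        ta = toy_table(rng.normal(mu_a, 1, size=(n, 2)), model="A")
        tb = toy_table(rng.normal(mu_b, 1, size=(n, 2)), model="B")
        return {"A": ta, "B": tb}

    def test_identical_models_get_equal_probability(self):
        tables = self.make_tables(0.0, 0.0)
        probs = model_choice(tables, np.zeros(2), 400)
        assert probs["A"] == pytest.approx(0.5, abs=0.15)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_model_centred_on_observation_wins(self):
        tables = self.make_tables(0.0, 8.0)
        probs = model_choice(tables, np.zeros(2), 300)
        assert probs["A"] > 0.9
        # frequency-in-retained oracle agrees on the direction
        pooled = np.vstack([tables["A"].stats, tables["B"].stats])
        d = np.linalg.norm(pooled - 0.0, axis=1)
        frac_a = (np.argsort(d)[:300] < 400).mean()
        assert frac_a > 0.9

    def test_three_model_probabilities_sum_to_one(self):
        rng = np.random.default_rng(7)
        tables = {
            m: toy_table(rng.normal(mu, 1, size=(300, 2)), model=m)
            for m, mu in [("COS", 0.0), ("CHG1", 1.0), ("FIM", 2.0)]
        }
        probs = model_choice(tables, np.array([1.0, 1.0]), 500)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_absent_model_gets_zero_with_warning(self):
        tables = self.make_tables(0.0, 50.0)
        with pytest.warns(RuntimeWarning, match="absent"):
            probs = model_choice(tables, np.zeros(2), 100)
        assert probs["B"] == 0.0 and probs["A"] == 1.0

    def test_needs_at_least_two_models(self):
        with pytest.raises(ValueError):
            model_choice({"A": toy_table(np.zeros((5, 1)))}, np.zeros(1), 3)


class TestPosteriorSummary:
    def test_single_point_posterior_collapses(self):
        sample = PosteriorSample(
            "COS", pd.DataFrame({"N": [7.0]}), np.zeros((1, 1)), np.zeros(1), np.ones(1), np.zeros(1, int)
        )
        summ = posterior_summary(sample)
        assert (summ.loc["N"] == 7.0).all()

    def test_uniform_weights_match_unweighted_quantiles(self):
        v = np.arange(1, 101, dtype=float)
        sample = PosteriorSample(
            "COS", pd.DataFrame({"N": v}), np.zeros((100, 1)), np.zeros(100), np.ones(100), np.arange(100)
        )
        summ = posterior_summary(sample)
        assert summ.loc["N", "median"] == pytest.approx(50.5)
        assert summ.loc["N", "q025"] == pytest.approx(3.0, abs=0.5)
        assert summ.loc["N", "q975"] == pytest.approx(98.0, abs=0.5)

    def test_resize_reported_for_step_change_model(self):
        rng = np.random.default_rng(8)
        params = pd.DataFrame(
            {"N_mod": rng.uniform(900, 1100, 500), "N_anc": rng.uniform(400, 600, 500),
             "T_c": rng.uniform(1000, 2000, 500)}
        )
        sample = PosteriorSample(
            "CHG1", params, np.zeros((500, 1)), np.zeros(500), np.ones(500), np.arange(500)
        )
        summ = posterior_summary(sample)
        assert "resize" in summ.index
        assert summ.loc["resize", "median"] == pytest.approx(0.5, abs=0.05)
        # paper-shaped report: all four fields for every parameter
        assert list(summ.columns) == ["median", "mode", "q025", "q975"]

    def test_weighted_quantile_oracle(self):
        # all mass on one value -> every quantile equals it
        assert weighted_quantile(np.array([1.0, 9.0]), np.array([1.0, 0.0]), [0.1, 0.9]).tolist() == [1.0, 1.0]


class TestReferenceTableIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        table = ReferenceTable(
            "FIM",
            pd.DataFrame({"Nm": rng.uniform(0, 1, 20), "T_i": rng.uniform(0, 1, 20)}),
            rng.normal(size=(20, 3)),
            ["sfs_1", "sfs_2", "S"],
        )
        table.to_tsv(tmp_path / "t.tsv")
        back = ReferenceTable.from_tsv(tmp_path / "t.tsv")
        assert back.model == "FIM"
        assert list(back.params.columns) == ["Nm", "T_i"]
        assert np.allclose(back.stats, table.stats)
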