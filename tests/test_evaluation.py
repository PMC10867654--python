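import itertools

import numpy as np
import pandas as pd
import pytest

import fatiguecast as fc
from fatiguecast import evaluation as ev
from fatiguecast.config import FatiguecastError
from helpers import feature_table, impute_zeros_inplace


class TestParticipantMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.4, -1.2, 0.8])
        m = ev.participant_metrics(y, y)
        assert m == {"r2": 100.0, "mae": 0.0, "rmse": 0.0}

    def test_zero_prediction_scores_exactly_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1.3, 40)
        assert ev.participant_metrics(y, np.zeros(40))["r2"] == 0.0

    def test_half_way_prediction(self):
        m = ev.participant_metrics([1.0, -1.0], [0.5, -0.5])
        assert m["r2"] == pytest.approx(75.0)
        assert m["mae"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(FatiguecastError):
            ev.participant_metrics([], [])

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.normal(0, 1, 15)
            yhat = rng.normal(0, 1, 15)
            m = ev.participant_metrics(y, yhat)
            assert m["mae"] <= m["rmse"] + 1e-12


class TestWilcoxon:
    def test_identical_vectors(self):
        a = np.arange(10.0)
        assert ev.compare_wilcoxon(a, a) == 1.0

    def test_constant_shift_exact_p(self):
        """All ten differences positive: the exact two-sided p is the
        probability of the two extreme sign assignments, 2/2^10."""
        a = np.arange(10.0)
        assert ev.compare_wilcoxon(a + 1.0, a) == pytest.approx(2 / 1024)

    def test_matches_enumeration_oracle(self):
        """Exact signed-rank p for n=8 continuous pairs, checked against
        full enumeration of the 2^8 sign assignments."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.4, 1, 8)
        d = a - b
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        w_plus = ranks[d > 0].sum()
        total = ranks.sum()
        stats = []
        for signs in itertools.product([0, 1], repeat=8):
            stats.append(sum(r for s, r in zip(signs, ranks) if s))
        stats = np.array(stats)
        w = min(w_plus, total - w_plus)
        p_exact = np.mean(np.minimum(stats, total - stats) <= w)
        assert ev.compare_wilcoxon(a, b) == pytest.approx(p_exact, abs=1e-12)

    def test_short_input_raises(self):
        with pytest.raises(FatiguecastError):
            ev.compare_wilcoxon([1.0, 2.0], [2.0, 1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        out = ev.correlate_mean_vas_fsmc(pd.DataFrame(
            {"mean_vas": [1, 2, 3], "fsmc": [10, 20, 30]}))
        assert out["rho"] == pytest.approx(1.0)

    def test_reversed(self):
        out = ev.correlate_mean_vas_fsmc(pd.DataFrame(
            {"mean_vas": [1, 2, 3], "fsmc": [30, 20, 10]}))
        assert out["rho"] == pytest.approx(-1.0)

    def test_matches_pearson_on_ranks(self):
        rng = np.random.default_rng(2)
        x = rng.normal(4, 1, 25)
        y = 10 * x + rng.normal(0, 8, 25)
        out = ev.correlate_mean_vas_fsmc(pd.DataFrame(
            {"mean_vas": x, "fsmc": y}))
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        expect = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"] == pytest.approx(expect, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(FatiguecastError):
            ev.correlate_mean_vas_fsmc(pd.DataFrame(
                {"mean_vas": [1, 2], "fsmc": [3, 4]}))


class TestBaseline:
    def test_group_mean_r2_exactly_zero(self):
        table = feature_table(6, 20, {"f_a": lambda x: 0.5 * x},
                              noise_sd=1.0, seed=3)
        res = ev.baseline_evaluate(table)
        assert (res.per_participant["r2_cc"] == 0.0).all()
        assert res.group_mean("r2", "cc") == 0.0

    def test_unit_variance_rmse(self):
        table = feature_table(6, 200, {}, noise_sd=1.0, seed=4)
        res = ev.baseline_evaluate(table)
        assert res.group_mean("rmse", "cc") == pytest.approx(1.0, abs=0.1)


class TestLopoAndAcrossGroup:
    @pytest.fixture(scope="class")
    def config(self):
        return fc.RunConfig(smooth_criterion="efs")

    def test_signal_recovery_beats_baseline(self, config):
        table = feature_table(
            8, 30, {"f_a": lambda x: 0.6 * x,
                    "f_b": lambda x: 0.5 * np.tanh(x)},
            noise_sd=0.8, seed=6)
        res = ev.lopo_evaluate(table, ["f_a", "f_b"], config)
        base = ev.baseline_evaluate(table)
        assert res.group_mean("r2", "cc") > 10.0
        p = ev.compare_wilcoxon(res.metric_values("r2", "cc"),
                                base.metric_values("r2", "cc"))
        assert p < 0.05

    def test_pure_noise_stays_near_zero(self, config):
        r2s = []
        for seed in (7, 8, 9):
            table = feature_table(8, 30, {}, noise_sd=1.0, seed=seed,
                                  n_noise_features=2)
            res = ev.lopo_evaluate(table, table.feature_names, config)
            r2s.append(res.group_mean("r2", "cc"))
        assert abs(np.mean(r2s)) < 5.0

    def test_transfer_under_identical_truth(self, config):
        effects = {"f_a": lambda x: 0.7 * x}
        t1 = feature_table(8, 30, effects, noise_sd=0.8, seed=10)
        t2 = feature_table(8, 30, effects, noise_sd=0.8, seed=11)
        t2.df["participant_id"] = t2.df["participant_id"].str.replace(
            "P", "Q")
        within = ev.lopo_evaluate(t2, ["f_a"], config)
        across = ev.across_group_evaluate(t1, t2, ["f_a"], config)
        assert abs(within.group_mean("r2", "cc")
                   - across.group_mean("r2", "cc")) < 5.0

    def test_transfer_under_different_truth_degrades(self, config):
        t1 = feature_table(8, 30, {"f_a": lambda x: 0.7 * x,
                                   "f_b": lambda x: 0.0 * x},
                           noise_sd=0.8, seed=12)
        t2 = feature_table(8, 30, {"f_a": lambda x: 0.0 * x,
                                   "f_b": lambda x: 0.7 * x},
                           noise_sd=0.8, seed=13)
        t2.df["participant_id"] = t2.df["participant_id"].str.replace(
            "P", "Q")
        within = ev.lopo_evaluate(t2, ["f_b"], config)
        across = ev.across_group_evaluate(t1, t2, ["f_a"], config)
        assert across.group_mean("r2", "cc") < within.group_mean("r2", "cc")
        p = ev.compare_wilcoxon(across.metric_values("r2", "cc"),
                                within.metric_values("r2", "cc"))
        assert p < 0.05

    def test_overlapping_participants_rejected(self, config):
        t1 = feature_table(5, 20, {"f_a": lambda x: x}, 1.0, seed=14)
        with pytest.raises(FatiguecastError, match="overlap"):
            ev.across_group_evaluate(t1, t1, ["f_a"], config)

    def test_single_participant_test_group(self, config):
        t1 = feature_table(6, 20, {"f_a": lambda x: x}, 1.0, seed=15)
        t2 = feature_table(1, 20, {"f_a": lambda x: x}, 1.0, seed=16)
        t2.df["participant_id"] = "Q00"
        res = ev.across_group_evaluate(t1, t2, ["f_a"], config)
        assert res.n_participants == 1

    def test_imputed_variant_reported(self, config):
        table = feature_table(8, 30, {"f_a": lambda x: 0.6 * x},
                              noise_sd=0.8, seed=17, missing_rate=0.3)
        table = impute_zeros_inplace(table)
        res = ev.lopo_evaluate(table, ["f_a"], config)
        per = res.per_participant
        assert (per["n_all"] >= per["n_cc"]).all()
        assert np.isfinite(res.group_mean("r2", "imp"))


class TestAblation:
    def test_configuration_combinatorics(self):
        configs = ev.ablation_configurations()
        assert len(configs) == 10
        assert configs["all"] == ("CAR", "EDA", "ACC", "WEA")
        assert configs["routine_only"] == ()
        for g in ("CAR", "EDA", "ACC", "WEA"):
            assert g not in configs[f"no_{g}"]
            assert configs[f"only_{g}"] == (g,)

    def test_attribution_to_true_feature_group(self):
        """When the truth lives in one feature group, removing that group
        hurts more than removing an uninformative one."""
        config = fc.RunConfig(smooth_criterion="efs", n_subsamples=15,
                              n_perturbations=12)
        table = feature_table(
            10, 25,
            {"car_f": lambda x: 0.7 * x, "routine_f": lambda x: 0.4 * x},
            noise_sd=0.8, seed=18, n_noise_features=2)
        table.groups.update({
            "car_f": "CAR", "routine_f": "ROUTINE",
            "f_noise_0": "EDA", "f_noise_1": "WEA"})
        res = ev.ablation_study(table, table.feature_names, config, seed=19)
        rows = res.table.set_index("config")["mean_r2_cc"]
        assert rows["no_CAR"] < rows["all"]
        assert rows["only_CAR"] > rows["no_CAR"]
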