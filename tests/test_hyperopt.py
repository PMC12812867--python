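import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mtmepred._stats import compact_letters, compare_groups
from mtmepred.hyperopt import (
    HYPERPARAMETERS,
    HyperGrid,
    TuningResult,
    default_grid,
    grid_search,
    resume_hyperparameters,
)


def anova_oracle(values, groups):
    """From-scratch one-way ANOVA via explicit sums of squares."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    grand = values.mean()
    ss_between = sum(
        (values[groups == lv]).size * (values[groups == lv].mean() - grand) ** 2
        for lv in levels
    )
    ss_within = sum(
        ((values[groups == lv] - values[groups == lv].mean()) ** 2).sum()
        for lv in levels
    )
    df_b = len(levels) - 1
    df_w = values.size - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


class TestDefaultGrid:
    def test_combination_count_is_288(self):
        grid = default_grid()
        assert grid.n_combinations == 288
        assert len(grid.combinations()) == 288

    def test_level_cardinalities(self):
        grid = default_grid()
        counts = tuple(len(getattr(grid, n)) for n in HYPERPARAMETERS)
        assert counts == (3, 2, 3, 2, 2, 2, 2)

    def test_every_combination_is_valid_config(self):
        for cfg in default_grid().combinations():
            assert cfg.loss_weight > 0  # constructor already validated

    def test_removing_one_optimizer_halves_grid(self):
        grid = default_grid()
        grid.optimizer = ["adam"]
        assert grid.n_combinations == 144

    def test_empty_level_list_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid(optimizer=[])


MICRO_GRID = dict(
    activation=["tanh"],
    optimizer=["adam"],
    batch_size=[16],
    loss=["mean_squared_error"],
    metric=["mse"],
    loss_weight=[1.0],
)


class TestGridSearch:
    def test_row_count(self, utue_ds):
        grid = HyperGrid(epochs=[2], **MICRO_GRID)
        tr = grid_search(utue_ds, grid, n_reps=2, base_seed=1)
        assert len(tr.table) == 2  # 1 combination x 2 reps x 1 trait

    def test_worker_count_does_not_change_results(self, utue_ds):
        grid = HyperGrid(epochs=[2, 4], **MICRO_GRID)
        a = grid_search(utue_ds, grid, n_reps=2, base_seed=3, workers=1)
        b = grid_search(utue_ds, grid, n_reps=2, base_seed=3, workers=2)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_more_epochs_beat_one_epoch_on_linear_target(self, linear_fixture):
        X, y = linear_fixture
        from mtmepred.prepare import PreparedDataset

        ds = PreparedDataset(
            X=X, Y=y, approach="UTUE", blocks={"genotype": (0, X.shape[1])},
            sample_ids=[f"s{i}" for i in range(len(y))], env_labels=None,
            trait_names=["t"],
        )
        grid = HyperGrid(epochs=[200, 1], **MICRO_GRID)
        tr = grid_search(ds, grid, n_reps=5, base_seed=2)
        means = tr.table.groupby("epochs")["prediction_ability"].mean()
        assert means[200] > means[1]

    def test_metric_only_variants_score_identically(self, utue_ds):
        grid = HyperGrid(epochs=[3], **{**MICRO_GRID, "metric": ["mse", "mae"]})
        tr = grid_search(utue_ds, grid, n_reps=2, base_seed=5)
        piv = tr.table.pivot_table(index="repetition", columns="metric",
                                   values="prediction_ability")
        np.testing.assert_array_equal(piv["mse"].to_numpy(), piv["mae"].to_numpy())


class TestResumeHyperparameters:
    @staticmethod
    def synthetic_result(level_scores: dict, n_obs: int, jitter: float, seed: int = 0):
        """A TuningResult varying only the activation hyperparameter."""
        rng = np.random.default_rng(seed)
        rows = []
        for ci, (lv, mu) in enumerate(sorted(level_scores.items())):
            for rep in range(n_obs):
                rows.append(
                    {
                        "combination": ci,
                        "activation": lv,
                        "optimizer": "adam",
                        "epochs": 100,
                        "batch_size": 32,
                        "loss": "mean_squared_error",
                        "metric": "mse",
                        "loss_weight": 1.0,
                        "repetition": rep,
                        "trait": "t",
                        "prediction_ability": mu + jitter * rng.standard_normal(),
                        "mse": 1.0 - mu,
                        "failed": False,
                    }
                )
        return TuningResult(pd.DataFrame(rows))

    def test_identical_scores_share_letter(self):
        tr = self.synthetic_result({"tanh": 0.5, "relu": 0.5}, 10, jitter=1e-6)
        s = resume_hyperparameters(tr)
        gc = s.per_hyperparameter["activation"]
        letters = set(gc.level_means["letters"])
        assert letters == {"a"}

    def test_separated_scores_get_distinct_letters(self):
        tr = self.synthetic_result({"tanh": 0.9, "relu": 0.1}, 20, jitter=1e-3)
        s = resume_hyperparameters(tr)
        gc = s.per_hyperparameter["activation"]
        assert gc.p_value < 0.05
        assert gc.level_means.loc["tanh", "letters"] != gc.level_means.loc["relu", "letters"]

    def test_f_statistic_matches_sums_of_squares_oracle(self):
        tr = self.synthetic_result({"tanh": 0.6, "relu": 0.4, "sigmoid": 0.5},
                                   10, jitter=0.1, seed=3)
        s = resume_hyperparameters(tr)
        gc = s.per_hyperparameter["activation"]
        df = tr.table
        expected = anova_oracle(df["prediction_ability"], df["activation"])
        assert gc.f_statistic == pytest.approx(expected, abs=1e-10)

    def test_tukey_q_matches_hand_formula(self):
        tr = self.synthetic_result({"a": 0.6, "b": 0.4, "c": 0.5}, 10, jitter=0.1, seed=4)
        s = resume_hyperparameters(tr)
        gc = s.per_hyperparameter["activation"]
        df = tr.table
        # hand Tukey: q = |mean_i - mean_j| / sqrt(MSW / n); p from studentized range
        vals, grp = df["prediction_ability"].to_numpy(), df["activation"].to_numpy()
        msw = np.mean(
            [vals[grp == lv].var(ddof=1) for lv in ("a", "b", "c")]
        )
        n_per = 10
        row = gc.tukey.iloc[0]
        diff = abs(
            vals[grp == row["level2"]].mean() - vals[grp == row["level1"]].mean()
        )
        q = diff / np.sqrt(msw / n_per)
        p_expected = sps.studentized_range.sf(q, 3, 27)
        assert float(row["p_adj"]) == pytest.approx(p_expected, abs=1e-4)

    def test_single_level_hyperparameters_skipped(self):
        tr = self.synthetic_result({"tanh": 0.6, "relu": 0.4}, 5, jitter=0.05)
        s = resume_hyperparameters(tr)
        assert "optimizer" in s.skipped
        assert "activation" in s.per_hyperparameter

    def test_ranking_order_and_tiebreak(self):
        tr = self.synthetic_result({"tanh": 0.8, "relu": 0.2, "sigmoid": 0.5},
                                   5, jitter=1e-9)
        s = resume_hyperparameters(tr)
        assert s.ranking["mean_prediction_ability"].is_monotonic_decreasing
        assert s.best()["activation"] == "tanh"

    def test_ranking_invariant_to_row_order(self):
        tr = self.synthetic_result({"tanh": 0.8, "relu": 0.2}, 5, jitter=0.01)
        shuffled = TuningResult(
            tr.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        a = resume_hyperparameters(tr).ranking
        b = resume_hyperparameters(shuffled).ranking
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_chart_written(self, tmp_path):
        tr = self.synthetic_result({"tanh": 0.6, "relu": 0.4}, 5, jitter=0.05)
        resume_hyperparameters(tr, chart_path=tmp_path / "bars.png")
        assert (tmp_path / "bars.png").stat().st_size > 0


class TestCompactLetters:
    def test_order_invariant_partition(self):
        means = {"a": 0.9, "b": 0.5, "c": 0.1}
        sig = {frozenset(("a", "c"))}
        l1 = compact_letters(["a", "b", "c"], means, sig)
        l2 = compact_letters(["c", "a", "b"], means, sig)
        assert l1 == l2
        assert l1["a"] != l1["c"]
        # b overlaps with both
        assert set(l1["b"]) & set(l1["a"]) and set(l1["b"]) & set(l1["c"])

    def test_all_significant_gives_distinct_letters(self):
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        sig = {frozenset(p) for p in (("x", "y"), ("x", "z"), ("y", "z"))}
        letters = compact_letters(["x", "y", "z"], means, sig)
        assert len({letters[k] for k in letters}) == 3

    def test_compare_groups_requires_two_levels(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(np.ones(5), np.array(["a"] * 5))
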