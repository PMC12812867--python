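"""Grid-based hyperparameter search and its ANOVA/Tukey summarisation.

The default grid crosses seven training hyperparameters —
3 activations × 2 optimizers × 3 epoch settings × 2 batch sizes ×
2 loss functions × 2 monitoring metrics × 2 loss weights — for 288
combinations. Every combination is scored on the same seeded 80/20
train/test partitions (shared within a repetition) so that differences
between combinations are not confounded with differences between splits.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._stats import GroupComparison, compare_groups
from .deepnet import ModelConfig, fit_network, predict as net_predict
from .evaluate import mse as _mse, pearson as _pearson, split_individuals
from .prepare import PreparedDataset

log = logging.getLogger(__name__)

HYPERPARAMETERS = (
    "activation",
    "optimizer",
    "epochs",
    "batch_size",
    "loss",
    "metric",
    "loss_weight",
)


@dataclass
class HyperGrid:
    """Named level lists for the seven training hyperparameters."""

    activation: list = field(default_factory=lambda: ["relu", "tanh", "sigmoid"])
    optimizer: list = field(default_factory=lambda: ["adam", "sgd"])
    epochs: list = field(default_factory=lambda: [50, 100, 200])
    batch_size: list = field(default_factory=lambda: [32, 64])
    loss: list = field(
        default_factory=lambda: ["mean_squared_error", "mean_absolute_error"]
    )
    metric: list = field(default_factory=lambda: ["mse", "mae"])
    loss_weight: list = field(default_factory=lambda: [1.0, 0.01])

    def __post_init__(self) -> None:
        for name in HYPERPARAMETERS:
            if not getattr(self, name):
                raise ValueError(f"hyperparameter {name!r} needs at least one level")

    @property
    def n_combinations(self) -> int:
        n = 1
        for name in HYPERPARAMETERS:
            n *= len(getattr(self, name))
        return n

    def combinations(self) -> list[ModelConfig]:
        """All configurations in deterministic (itertools.product) order."""
        out = []
        for values in itertools.product(*(getattr(self, n) for n in HYPERPARAMETERS)):
            out.append(ModelConfig(**dict(zip(HYPERPARAMETERS, values))))
        return out


def default_grid() -> HyperGrid:
    """The seven-factor default grid (level counts 3·2·3·2·2·2·2 = 288)."""
    return HyperGrid()


def _evaluate_combination(
    ci: int,
    cfg: ModelConfig,
    X: np.ndarray,
    Y: np.ndarray,
    sample_ids: list[str],
    traits: list[str],
    n_reps: int,
    test_fraction: float,
    base_seed: int,
) -> list[dict]:
    """Score one configuration over all repetitions (one parallel task)."""
    sample_arr = np.asarray(sample_ids)
    rows = []
    for rep in range(n_reps):
        # split seed shared by all combinations within a repetition
        train_ids, test_ids = split_individuals(sample_ids, test_fraction, base_seed, rep)
        tr = np.isin(sample_arr, train_ids)
        te = np.isin(sample_arr, test_ids)
        # seed depends only on training-relevant fields, so combinations
        # differing in the monitoring metric alone train identically
        train_key = zlib.crc32(
            f"{cfg.activation}|{cfg.optimizer}|{cfg.epochs}|{cfg.batch_size}"
            f"|{cfg.loss}|{cfg.loss_weight}".encode()
        )
        train_seed = int(
            np.random.SeedSequence([base_seed, rep, train_key]).generate_state(1)[0] % (2**31)
        )
        run_cfg = replace(cfg, seed=train_seed)
        base = {
            "combination": ci,
            **{name: getattr(cfg, name) for name in HYPERPARAMETERS},
            "repetition": rep,
        }
        try:
            tn = fit_network(X[tr], Y[tr], run_cfg)
            yhat = net_predict(tn, X[te])
        except Exception as exc:
            log.warning("combination %d rep %d failed: %s", ci, rep, exc)
            for trait in traits:
                rows.append({**base, "trait": trait,
                             "prediction_ability": np.nan, "mse": np.nan,
                             "failed": True})
            continue
        for j, trait in enumerate(traits):
            try:
                r = _pearson(Y[te, j], yhat[:, j])
            except ValueError:
                r = np.nan
            rows.append({**base, "trait": trait, "prediction_ability": r,
                         "mse": _mse(Y[te, j], yhat[:, j]), "failed": False})
    return rows


@dataclass
class TuningResult:
    """Long-format scores: one row per (combination, repetition, trait)."""

    table: pd.DataFrame
    grid: HyperGrid | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TuningResult":
        return cls(pd.read_csv(path))


def grid_search(
    ds: PreparedDataset,
    grid: HyperGrid,
    n_reps: int = 5,
    test_fraction: float = 0.2,
    base_seed: int = 0,
    workers: int = 1,
) -> TuningResult:
    """Evaluate every grid combination on shared seeded 80/20 partitions.

    Results are identical for any ``workers`` count: each task's seed is a
    function of (base_seed, repetition, combination index) only.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    traits = ds.trait_names or [f"trait{j + 1}" for j in range(ds.n_traits)]
    combos = grid.combinations()
    tasks = (
        delayed(_evaluate_combination)(
            ci, cfg, ds.X, ds.Y, ds.sample_ids, traits,
            n_reps, test_fraction, base_seed,
        )
        for ci, cfg in enumerate(combos)
    )
    results = Parallel(n_jobs=workers)(tasks)
    table = pd.DataFrame([row for rows in results for row in rows])
    return TuningResult(table, grid)


@dataclass
class HyperSummary:
    """Per-hyperparameter comparisons plus the ranked combination table."""

    per_hyperparameter: dict[str, GroupComparison]
    ranking: pd.DataFrame  # combinations ranked best-first
    n_failed: int = 0
    skipped: list[str] = field(default_factory=list)

    def best(self) -> pd.Series:
        return self.ranking.iloc[0]


def resume_hyperparameters(
    tr: TuningResult, alpha: float = 0.05, chart_path=None
) -> HyperSummary:
    """Summarise a tuning run.

    For each hyperparameter with at least two observed levels, a one-way
    ANOVA of prediction ability on its levels (pooled over all other
    factors, repetitions, and traits), Tukey HSD pairwise tests at
    ``alpha``, and compact letters. Also returns combinations ranked by
    mean prediction ability (descending), then mean MSE (ascending), then
    the configuration string. Optionally writes a bar chart of level means
    ± SE annotated with the letters.
    """
    df = tr.table
    n_failed = int(df["failed"].sum()) if "failed" in df else 0
    ok = df[np.isfinite(df["prediction_ability"])]
    if ok.empty:
        raise ValueError("no successful evaluations to summarise")

    per_hp: dict[str, GroupComparison] = {}
    skipped: list[str] = []
    for name in HYPERPARAMETERS:
        levels = ok[name].unique()
        if len(levels) < 2:
            skipped.append(name)
            log.info("hyperparameter %s has a single level; skipped", name)
            continue
        per_hp[name] = compare_groups(
            ok["prediction_ability"].to_numpy(), ok[name].to_numpy(),
            factor=name, alpha=alpha,
        )
    if not per_hp:
        raise ValueError("no hyperparameter has two or more observed levels")

    agg = (
        ok.groupby(["combination", *HYPERPARAMETERS], as_index=False)
        .agg(mean_prediction_ability=("prediction_ability", "mean"),
             mean_mse=("mse", "mean"), n=("prediction_ability", "size"))
    )
    agg["config"] = [
        "|".join(str(r[h]) for h in HYPERPARAMETERS) for _, r in agg.iterrows()
    ]
    ranking = agg.sort_values(
        by=["mean_prediction_ability", "mean_mse", "config"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    summary = HyperSummary(per_hp, ranking, n_failed, skipped)
    if chart_path is not None:
        plot_hyperparameter_summary(summary, chart_path)
    return summary


def plot_hyperparameter_summary(summary: HyperSummary, path) -> None:
    """Bar chart of level means ± SE per hyperparameter, letters on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(summary.per_hyperparameter)
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3.4), squeeze=False)
    for ax, name in zip(axes[0], names):
        gc = summary.per_hyperparameter[name]
        tbl = gc.level_means
        x = np.arange(len(tbl))
        ax.bar(x, tbl["mean"], yerr=tbl["se"], capsize=3, color="#4878A8")
        for xi, (_, row) in zip(x, tbl.iterrows()):
            ax.annotate(row["letters"], (xi, row["mean"]),
                        ha="center", va="bottom", fontsize=9)
        ax.set_xticks(x)
        ax.set_xticklabels(tbl.index, rotation=30, ha="right", fontsize=8)
        ax.set_title(f"{name}\nF={gc.f_statistic:.2f}, p={gc.p_value:.3g}", fontsize=9)
        ax.set_ylabel("prediction ability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
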