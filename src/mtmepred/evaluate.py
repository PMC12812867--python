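"""Repeated hold-out cross-validation and model comparison.

The evaluation protocol draws, for each cycle, an independent random split
into disjoint training (80%) and testing (20%) subsets, trains the model on
the training subset and scores the held-out predictions with the Pearson
correlation between observed and predicted phenotypes ("prediction
ability") and the mean squared error. For multi-environment data the split
is at the individual level, so all records of an individual travel
together and no genotype leaks between training and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import GroupComparison, compare_groups
from .prepare import PreparedDataset

log = logging.getLogger(__name__)


def pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson product-moment correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("vectors differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(y, yhat)[0, 1])


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error of prediction, (1/n) Σ (y_i - ŷ_i)²."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("vectors differ in length")
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation protocol: repeated random 80/20 hold-out splits."""

    cycles: int = 50
    test_fraction: float = 0.2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


def split_individuals(
    individuals: list[str], test_fraction: float, base_seed: int, cycle: int
) -> tuple[list[str], list[str]]:
    """Deterministic train/test split of individuals for one cycle.

    Membership depends only on the sorted individual ids and the
    (base_seed, cycle) pair, never on record order.
    """
    units = sorted(set(individuals))
    n_test = int(round(test_fraction * len(units)))
    if n_test < 1 or n_test >= len(units):
        raise ValueError(
            f"test fraction {test_fraction} leaves an empty split for {len(units)} individuals"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), int(cycle)]))
    perm = rng.permutation(len(units))
    test = sorted(units[i] for i in perm[:n_test])
    train = sorted(units[i] for i in perm[n_test:])
    return train, test


@dataclass
class CVResult:
    """Per-cycle, per-trait scores for one model label."""

    label: str
    table: pd.DataFrame  # columns: cycle, trait, prediction_ability, mse
    splits: list[tuple[list[str], list[str]]]
    base_seed: int = 0
    n_failed_cycles: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean ± SE of prediction ability and MSE per trait."""
        g = self.table.groupby("trait")
        out = g.agg(
            mean_r=("prediction_ability", "mean"),
            se_r=("prediction_ability", lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum())),
            mean_mse=("mse", "mean"),
            n_cycles=("prediction_ability", lambda v: int(v.notna().sum())),
        )
        return out


def cross_validate(
    model_factory,
    ds: PreparedDataset,
    scheme: CVScheme = CVScheme(),
    label: str = "model",
) -> CVResult:
    """Run the repeated hold-out protocol for one model.

    ``model_factory`` is called as ``model_factory(X_train, Y_train, seed)``
    and must return a callable mapping a covariate matrix to predictions
    (records × traits). Cycles whose training fails or whose correlation is
    undefined are recorded as missing and the run continues.
    """
    traits = ds.trait_names or [f"trait{j + 1}" for j in range(ds.n_traits)]
    sample_arr = np.asarray(ds.sample_ids)
    rows = []
    splits = []
    n_failed = 0
    for cycle in range(scheme.cycles):
        train_ids, test_ids = split_individuals(
            ds.sample_ids, scheme.test_fraction, scheme.base_seed, cycle
        )
        splits.append((train_ids, test_ids))
        tr_mask = np.isin(sample_arr, train_ids)
        te_mask = np.isin(sample_arr, test_ids)
        assert not (tr_mask & te_mask).any()
        seed = int(np.random.SeedSequence([scheme.base_seed, cycle, 7]).generate_state(1)[0] % (2**31))
        try:
            predict_fn = model_factory(ds.X[tr_mask], ds.Y[tr_mask], seed)
            yhat = np.atleast_2d(np.asarray(predict_fn(ds.X[te_mask]), dtype=float))
            if yhat.shape[0] != te_mask.sum():
                yhat = yhat.T
        except Exception as exc:
            log.warning("%s: cycle %d training failed: %s", label, cycle, exc)
            n_failed += 1
            for trait in traits:
                rows.append(
                    {"cycle": cycle, "trait": trait, "prediction_ability": np.nan, "mse": np.nan}
                )
            continue
        for j, trait in enumerate(traits):
            y_obs = ds.Y[te_mask, j]
            y_pred = yhat[:, j]
            try:
                r = pearson(y_obs, y_pred)
            except ValueError as exc:
                log.warning("%s: cycle %d trait %s correlation undefined: %s",
                            label, cycle, trait, exc)
                r = np.nan
            rows.append(
                {
                    "cycle": cycle,
                    "trait": trait,
                    "prediction_ability": r,
                    "mse": mse(y_obs, y_pred),
                }
            )
    return CVResult(label, pd.DataFrame(rows), splits, scheme.base_seed, n_failed)


@dataclass
class ModelComparison:
    """Per-trait ANOVA + Tukey letters across model labels."""

    per_trait: dict[str, GroupComparison] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        frames = []
        for trait, gc in self.per_trait.items():
            df = gc.level_means.reset_index().rename(columns={"level": "model"})
            df.insert(0, "trait", trait)
            df["anova_F"] = gc.f_statistic
            df["anova_p"] = gc.p_value
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def compare_models(results: list[CVResult], alpha: float = 0.05) -> ModelComparison:
    """ANOVA + Tukey HSD of per-cycle prediction abilities across models.

    All results must come from the same split seed and cycle count so that
    every model was scored on identical partitions.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    ref = results[0]
    for r in results[1:]:
        if r.base_seed != ref.base_seed or len(r.splits) != len(ref.splits):
            raise ValueError(
                "cross-validation results use different split seeds or cycle counts; "
                "comparison would not be on identical partitions"
            )
    stacked = pd.concat(
        [r.table.assign(model=r.label) for r in results], ignore_index=True
    )
    comp = ModelComparison()
    for trait, sub in stacked.groupby("trait"):
        comp.per_trait[str(trait)] = compare_groups(
            sub["prediction_ability"].to_numpy(),
            sub["model"].to_numpy(),
            factor=f"model[{trait}]",
            alpha=alpha,
        )
    return comp


def network_model_factory(config):
    """Model factory adapting the feed-forward network to cross_validate."""
    from .deepnet import ModelConfig, fit_network, predict as net_predict
    from dataclasses import replace

    def factory(X_train, Y_train, seed):
        cfg = replace(config, seed=seed) if isinstance(config, ModelConfig) else config
        tn = fit_network(X_train, Y_train, cfg)
        return lambda X_new: net_predict(tn, X_new)

    return factory
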