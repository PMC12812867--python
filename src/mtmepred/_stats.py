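"""One-way ANOVA, Tukey HSD, and compact-letter displays.

Shared by hyperparameter summarisation (per-hyperparameter comparisons) and
final model comparison (per-trait comparisons across models). ANOVA and the
Tukey pairwise tests come from scipy/statsmodels; the compact-letter display
uses the insert-and-absorb algorithm: start from one group holding all
levels, split on every significant pair, drop groups absorbed by supersets,
and letter the surviving groups from the best-performing level down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupComparison:
    """ANOVA + Tukey summary for one factor."""

    factor: str
    f_statistic: float
    p_value: float
    level_means: pd.DataFrame  # index level, columns: mean, se, n, letters
    tukey: pd.DataFrame  # pairwise table: level1, level2, meandiff, p_adj, reject


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """F statistic and p-value of a one-way layout."""
    levels = pd.unique(groups)
    samples = [np.asarray(values)[np.asarray(groups) == lv] for lv in levels]
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def _insert_absorb(levels: list, sig_pairs: set[frozenset]) -> list[set]:
    groups = [set(levels)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb: drop any group contained in another
        groups = [
            g
            for i, g in enumerate(new_groups)
            if g and not any(i != j and g < h for j, h in enumerate(new_groups))
        ]
        # deduplicate
        uniq = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    return groups


def compact_letters(
    levels: list, means: dict, sig_pairs: set[frozenset]
) -> dict:
    """Letter assignment: levels sharing a letter are not significantly different.

    Groups are lettered in descending order of their best member's mean, so
    the labelling is invariant to the input order of levels.
    """
    groups = _insert_absorb(list(levels), sig_pairs)
    groups.sort(key=lambda g: (-max(means[lv] for lv in g), tuple(sorted(str(lv) for lv in g))))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        sym = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for lv in g:
            letters[lv] += sym
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def compare_groups(
    values: np.ndarray, groups: np.ndarray, factor: str = "group", alpha: float = 0.05
) -> GroupComparison:
    """Full one-way comparison: ANOVA, Tukey HSD, letters, and mean ± SE table."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    groups = np.asarray([str(g) for g in groups])
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 observed levels")

    f, p = one_way_anova(values, groups)

    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey = tukey.rename(columns={"group1": "level1", "group2": "level2", "p-adj": "p_adj"})
    tukey["p_adj"] = np.asarray(tk.pvalues, dtype=float)  # unrounded
    tukey["reject"] = np.asarray(tk.reject, dtype=bool)
    sig_pairs = {
        frozenset((r["level1"], r["level2"]))
        for _, r in tukey.iterrows()
        if bool(r["reject"])
    }

    means = {lv: float(values[groups == lv].mean()) for lv in levels}
    letters = compact_letters(levels, means, sig_pairs)
    rows = []
    for lv in sorted(levels, key=lambda x: -means[x]):
        v = values[groups == lv]
        rows.append(
            {
                "level": lv,
                "mean": means[lv],
                "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
                "n": int(len(v)),
                "letters": letters[lv],
            }
        )
    level_means = pd.DataFrame(rows).set_index("level")
    return GroupComparison(factor, f, p, level_means, tukey)
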