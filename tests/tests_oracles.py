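"""Independent from-scratch statistical oracles used by the test suite."""

import numpy as np
from scipy.stats import studentized_range


def anova_f_oracle(values, groups):
    """One-way ANOVA F via explicit between/within sums of squares."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    grand = values.mean()
    ssb = sum(
        (values[groups == lv]).size * (values[groups == lv].mean() - grand) ** 2
        for lv in levels
    )
    ssw = sum(
        ((values[groups == lv] - values[groups == lv].mean()) ** 2).sum()
        for lv in levels
    )
    df_b = len(levels) - 1
    df_w = values.size - len(levels)
    return (ssb / df_b) / (ssw / df_w)


def tukey_sig_pairs_oracle(values, groups, alpha=0.05):
    """Significant Tukey HSD pairs via the studentized-range distribution.

    Balanced design assumed: q = |m_i - m_j| / sqrt(MSW / n_per).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    k = len(levels)
    n_per = {lv: (groups == lv).sum() for lv in levels}
    df_w = values.size - k
    msw = sum(
        ((values[groups == lv] - values[groups == lv].mean()) ** 2).sum()
        for lv in levels
    ) / df_w
    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = abs(values[groups == a].mean() - values[groups == b].mean())
            # Tukey-Kramer standard error for (possibly) unequal n
            se = np.sqrt(msw / 2 * (1 / n_per[a] + 1 / n_per[b]))
            q = diff / se
            p = studentized_range.sf(q, k, df_w)
            if p < alpha:
                sig.add(frozenset((a, b)))
    return sig
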