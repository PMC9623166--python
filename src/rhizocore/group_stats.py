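"""Treatment-level statistics: one-way ANOVA + Tukey HSD with compact
letter display, Bray-Curtis dissimilarity, and PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .community_table import RelativeAbundanceTable

__all__ = [
    "GroupComparison",
    "PermanovaResult",
    "anova_tukey",
    "bray_curtis",
    "permanova",
    "compact_letter_display",
]


@dataclass
class GroupComparison:
    variable: str
    group_stats: pd.DataFrame  # per group: n, mean, sd
    f_statistic: float
    p: float
    tukey_p: pd.DataFrame  # symmetric pairwise p matrix
    letters: dict[str, str]  # compact letter display at alpha=0.05


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p: float
    n_permutations: int
    seed: int


def compact_letter_display(
    groups: list[str], tukey_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one column holding all groups; every significant pair
    splits the columns containing both; subset columns are absorbed.
    Letters are assigned alphabetically in column order.
    """
    columns: list[set[str]] = [set(groups)]
    sig_pairs = [
        (a, b)
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
        if tukey_p.loc[a, b] < alpha
    ]
    for a, b in sig_pairs:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns that are subsets of another
        columns = []
        for col in new_cols:
            if any(col < other for other in new_cols if other is not col):
                continue
            if col not in columns:
                columns.append(col)
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in groups:
            if g in col:
                out[g] += letters[i % len(letters)]
    return out


def anova_tukey(
    values: np.ndarray, groups: list[str], variable: str = "value"
) -> GroupComparison:
    """One-way ANOVA F/p plus Tukey HSD pairwise p matrix and letters."""
    values = np.asarray(values, dtype=float)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    groups = list(groups)
    by_group = {g: values[[i for i, gg in enumerate(groups) if gg == g]] for g in labels}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*[by_group[g] for g in labels])
    hsd = stats.tukey_hsd(*[by_group[g] for g in labels])
    tukey_p = pd.DataFrame(hsd.pvalue, index=labels, columns=labels)
    gstats = pd.DataFrame(
        {
            "n": [len(by_group[g]) for g in labels],
            "mean": [float(np.mean(by_group[g])) for g in labels],
            "sd": [float(np.std(by_group[g], ddof=1)) for g in labels],
        },
        index=labels,
    )
    return GroupComparison(
        variable=variable,
        group_stats=gstats,
        f_statistic=float(f),
        p=float(p),
        tukey_p=tukey_p,
        letters=compact_letter_display(labels, tukey_p),
    )


def bray_curtis(rel: RelativeAbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity: 1 - 2 sum min(p_i, p_j)."""
    df = rel.to_frame() if isinstance(rel, RelativeAbundanceTable) else rel
    d = squareform(pdist(df.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _permanova_f(d2: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float]:
    """Anderson's pseudo-F from squared distances and group index arrays."""
    n = d2.shape[0]
    a = len(group_idx)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for ix in group_idx:
        sub = d2[np.ix_(ix, ix)]
        ss_within += sub[np.triu_indices(len(ix), k=1)].sum() / len(ix)
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total
    return f, r2


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA (ADONIS-style) on a dissimilarity matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under seeded
    label permutation — the add-one estimator, never exactly 0.
    """
    d = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    n = d.shape[0]
    if d.shape != (n, n) or len(groups) != n:
        raise ValueError("distance matrix and labels must agree in size")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    garr = np.asarray(groups)
    for g in labels:
        if (garr == g).sum() < 2:
            raise ValueError(f"group {g!r} is a singleton")
    d2 = d**2
    idx = [np.flatnonzero(garr == g) for g in labels]
    f_obs, r2 = _permanova_f(d2, idx)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(perm)
        shuffled = garr[perm]
        f_p, _ = _permanova_f(d2, [np.flatnonzero(shuffled == g) for g in labels])
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
    )
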