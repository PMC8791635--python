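"""Nonparametric group comparisons for per-cell summary tables.

Mobility and clustering-index distributions are heavy-tailed and bounded, so
group comparisons are rank-based throughout: the two-tailed Mann-Whitney U
test for two groups and the tie-corrected Kruskal-Wallis omnibus followed by
Dunn's pairwise z-tests (Bonferroni-adjusted, the behaviour of mainstream
statistics packages) for three or more. The pairwise outcome is condensed
into a compact letter display: conditions that do not share a letter differ
significantly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Uses the exact null distribution when the pooled sample has at most 20
    observations and no ties; otherwise the normal approximation with tie and
    continuity corrections. Returns ``(U, p)`` with U computed for ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KruskalDunnResult:
    """Omnibus Kruskal-Wallis result plus Dunn pairwise comparisons.

    ``pairwise`` has one row per group pair with the Dunn z statistic, the
    unadjusted two-sided p and the multiplicity-adjusted p. ``letters`` maps
    each group to its compact-letter-display string.
    """

    H: float
    p: float
    pairwise: pd.DataFrame
    letters: dict[str, str]


def _dunn_pairwise(samples: dict[str, np.ndarray], adjust: str) -> pd.DataFrame:
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction term of the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        n_g = samples[g].size
        mean_rank[g] = float(ranks[start : start + n_g].mean())
        start += n_g

    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(base_var * (1.0 / samples[g1].size + 1.0 / samples[g2].size))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p_unadj = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_unadj * len(pairs))
        elif adjust == "sidak":
            p_adj = 1.0 - (1.0 - p_unadj) ** len(pairs)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append((g1, g2, float(z), float(p_unadj), float(p_adj)))
    return pd.DataFrame(rows, columns=["group1", "group2", "z", "p_unadj", "p_adj"])


def compact_letter_display(
    labels: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign letters so that two groups share one iff not significantly different.

    Insert-and-absorb: start from a single letter covering all groups; each
    significant pair splits every letter set containing both; subset sets are
    absorbed. Deterministic for a fixed label order.
    """
    sets: list[set[str]] = [set(labels)]
    for g1, g2 in sorted(significant):
        new_sets: list[set[str]] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb: drop empties, proper subsets and duplicates (keep first)
        sets = []
        for s in new_sets:
            if not s or any(s < t for t in new_sets) or s in sets:
                continue
            sets.append(s)
    order = {g: i for i, g in enumerate(labels)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for i, s in enumerate(sets):
        for g in labels:
            if g in s:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def kruskal_dunn(
    table: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc pairwise comparisons.

    Parameters
    ----------
    table
        Tidy table with one row per measurement.
    alpha
        Significance level used only to build the compact letter display.
    adjust
        ``"bonferroni"`` (default) or ``"sidak"`` correction over all pairs.
    """
    groups = {str(g): np.asarray(v[value_col], dtype=float)
              for g, v in table.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has < 2 values")
        if not np.isfinite(v).all():
            raise ValueError(f"group {g!r} contains non-finite values")

    H, p = sps.kruskal(*groups.values())
    pairwise = _dunn_pairwise(groups, adjust)
    significant = {
        (r.group1, r.group2)
        for r in pairwise.itertuples()
        if r.p_adj < alpha
    }
    letters = compact_letter_display(list(groups), significant)
    return KruskalDunnResult(H=float(H), p=float(p), pairwise=pairwise, letters=letters)


def compare_two_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
) -> pd.DataFrame:
    """Mann-Whitney comparison of every metric column between two groups.

    Convenience for pipeline summary tables; returns one tidy row per value
    column with the U statistic and two-sided p.
    """
    labels = sorted(table[group_col].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    a = table[table[group_col] == labels[0]]
    b = table[table[group_col] == labels[1]]
    value_cols = [value_col] if value_col in table else [
        c for c in table.columns if c != group_col and np.issubdtype(table[c].dtype, np.number)
    ]
    rows = []
    for col in value_cols:
        u, p = mann_whitney(a[col].dropna(), b[col].dropna())
        rows.append(("mann_whitney", f"{labels[0]} vs {labels[1]}", col, u, p))
    return pd.DataFrame(rows, columns=["test", "groups", "metric", "statistic", "p"])
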