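"""Group-comparison statistics for morphometry tables.

Test choice follows the conventional gate: Shapiro-Wilk normality per group
(alpha = 0.05, all groups must pass for the parametric branch); two groups ->
Student t or Mann-Whitney U; more -> one-way ANOVA + Tukey HSD or
Kruskal-Wallis + Dunn; categorical outcomes -> Pearson chi-square. All tests
are two-sided. Significance stars: * p < 0.05, ** p < 0.01, *** p < 0.001.

The Mann-Whitney implementation switches to exhaustive enumeration of group
assignments for small samples (n_a + n_b <= 14), which remains exact in the
presence of ties (midranks are enumerated as-is); larger samples use the
normal approximation with tie correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05
EXACT_MW_MAX_N = 14


def stars(p_value: float) -> str:
    """Significance code for a p value (ns / * / ** / ***)."""
    if not 0 <= p_value <= 1:
        raise ValueError(f"p value {p_value} outside [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def _describe(sample) -> dict:
    a = np.asarray(sample, dtype=float)
    return {
        "n": int(a.size),
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "median": float(np.median(a)),
        "q1": float(np.percentile(a, 25)),
        "q3": float(np.percentile(a, 75)),
    }


@dataclass
class GroupComparison:
    measure: str
    groups: tuple
    test: str
    statistic: float
    p_value: float
    stars: str = field(init=False)
    descriptives: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stars = stars(self.p_value)


def _check_groups(groups: dict, min_n: int = 3) -> dict:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in out.items():
        if v.size < min_n:
            raise ValueError(f"group {k!r} has n={v.size} < {min_n}")
    return out


def choose_test(samples: dict, design: str = "continuous") -> str:
    """Name of the appropriate test for a design.

    ``samples`` maps group -> observations (or, for ``design="categorical"``,
    group -> (successes, total)). Continuous data are gated by per-group
    Shapiro-Wilk normality at alpha = 0.05.
    """
    if design == "categorical":
        return "chi_square"
    groups = _check_groups(samples)
    normal = all(
        sps.shapiro(v).pvalue > SHAPIRO_ALPHA if np.ptp(v) > 0 else False
        for v in groups.values()
    )
    if len(groups) == 2:
        return "t" if normal else "mann_whitney"
    return "anova_tukey" if normal else "kruskal_dunn"


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _exact_mw_pvalue(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of n_a ranks."""
    n = pooled_ranks.size
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    offset = n_a * (n_a + 1) / 2.0
    count = 0
    for idx in combinations(range(n), n_a):
        u = pooled_ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-9:
            count += 1
    return count / comb(n, n_a)


def mann_whitney(a, b, measure: str = "", groups: tuple = ("a", "b")) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    Exact by enumeration when n_a + n_b <= 14 (ties handled via midranks);
    otherwise the normal approximation with tie correction. Two identical
    constant samples yield p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    desc = {groups[0]: _describe(a), groups[1]: _describe(b)}
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    if np.ptp(pooled) == 0:
        logger.info("identical constant samples: p = 1 by convention")
        return GroupComparison(measure, groups, "mann_whitney", float(u_a), 1.0, desc)
    if a.size + b.size <= EXACT_MW_MAX_N:
        p = _exact_mw_pvalue(ranks, a.size, u_a)
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return GroupComparison(measure, groups, "mann_whitney", float(u_a), min(p, 1.0), desc)


def t_test(a, b, measure: str = "", groups: tuple = ("a", "b")) -> GroupComparison:
    """Two-sided Student t test (the parametric two-group branch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    t, p = sps.ttest_ind(a, b)
    return GroupComparison(measure, groups, "t", float(t), float(p),
                           {groups[0]: _describe(a), groups[1]: _describe(b)})


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _dunn_pairwise(groups: dict, adjust: str = "bonferroni") -> list[GroupComparison]:
    names = list(groups)
    sizes = {k: v.size for k, v in groups.items()}
    pooled = np.concatenate([groups[k] for k in names])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, start = {}, 0
    for k in names:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, j in combinations(range(len(names)), 2):
        gi, gj = names[i], names[j]
        se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        elif adjust not in (None, "none"):
            raise ValueError(f"unknown adjustment {adjust!r}")
        out.append(
            GroupComparison("", (gi, gj), "dunn", float(z), float(p),
                            {gi: _describe(groups[gi]), gj: _describe(groups[gj])})
        )
    return out


def kruskal_dunn(groups: dict, adjust: str = "bonferroni") -> list[GroupComparison]:
    """Kruskal-Wallis omnibus (tie-corrected H) followed by Dunn's pairwise
    z-tests with Bonferroni adjustment by default.

    Returns the omnibus comparison first, then one comparison per pair.
    """
    groups = _check_groups(groups)
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use mann_whitney for 2)")
    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0  # identical constant groups
    else:
        h, p = sps.kruskal(*samples)
    omnibus = GroupComparison(
        "", tuple(groups), "kruskal_wallis", float(h), float(p),
        {k: _describe(v) for k, v in groups.items()},
    )
    return [omnibus] + _dunn_pairwise(groups, adjust=adjust)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def anova_tukey(groups: dict) -> list[GroupComparison]:
    """One-way ANOVA omnibus F followed by Tukey HSD pairwise comparisons."""
    groups = _check_groups(groups)
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    samples = list(groups.values())
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    f, p = sps.f_oneway(*samples)
    desc = {k: _describe(v) for k, v in groups.items()}
    out = [GroupComparison("", tuple(groups), "anova", float(f), float(p), desc)]
    res = sps.tukey_hsd(*samples)
    names = list(groups)
    for i, j in combinations(range(len(names)), 2):
        out.append(
            GroupComparison(
                "", (names[i], names[j]), "tukey_hsd",
                float(res.statistic[i, j]), float(res.pvalue[i, j]),
                {names[i]: desc[names[i]], names[j]: desc[names[j]]},
            )
        )
    return out


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square_proportions(counts_2x2, correction: bool = False) -> GroupComparison:
    """Pearson chi-square on a 2x2 count table (no continuity correction by
    default, toggleable)."""
    table = np.asarray(counts_2x2)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return GroupComparison("", ("row0", "row1"), "chi_square", float(chi2), float(p))


def comparisons_to_frame(comparisons) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for c in comparisons:
        rows.append(
            {
                "measure": c.measure,
                "groups": "|".join(map(str, c.groups)),
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "stars": c.stars,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "GroupComparison",
    "stars",
    "choose_test",
    "mann_whitney",
    "kruskal_dunn",
    "anova_tukey",
    "chi_square_proportions",
    "comparisons_to_frame",
]
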