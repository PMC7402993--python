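"""Decision-tree group comparisons with Bonferroni-Holm correction.

Groups (age groups, sexes, FMI strata, BMI categories) are compared with a
test chosen by two gate checks: per-group normality (Shapiro-Wilk) and
homogeneity of variance (Levene, median-centred).  The mapping, for three or
more groups / exactly two groups:

* normal and equal variance     -> one-way ANOVA with Scheffe post-hoc
                                   / equal-variance t-test
* normal, unequal variance      -> Kruskal-Wallis with Welch t post-hoc (Holm)
                                   / Welch t-test
* not normal                    -> Kruskal-Wallis with Mann-Whitney post-hoc
                                   (Holm) / Mann-Whitney U

Significance is declared at alpha = 0.01, and the gate tests also use 0.01
(per-group Shapiro-Wilk gates at a looser level would misroute an
unacceptable share of genuinely normal samples).  Holm correction is applied
to the post-hoc t / Mann-Whitney families; Scheffe is simultaneous by
construction and receives no further correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "holm_adjust",
    "choose_branch",
    "compare_groups",
    "ComparisonResult",
]

GATE_ALPHA = 0.01
ALPHA = 0.01

_THREE_GROUP_BRANCHES = {
    (True, True): "anova_scheffe",
    (True, False): "kruskal_t_unequal",
    (False, True): "kruskal_mannwhitney",
    (False, False): "kruskal_mannwhitney",
}
_TWO_GROUP_BRANCHES = {
    (True, True): "t_equal",
    (True, False): "t_unequal",
    (False, True): "mannwhitney",
    (False, False): "mannwhitney",
}


def holm_adjust(pvalues):
    """Step-down Holm adjustment.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce
    monotone non-decrease, cap at 1, and restore the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _validate_groups(groups):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 3:
            raise ValueError("every group needs at least 3 observations")
        if np.any(~np.isfinite(g)):
            raise ValueError("group values must be finite")
    return arrays


def _gates(arrays, gate_alpha):
    normal = all(stats.shapiro(g).pvalue >= gate_alpha for g in arrays)
    ev = stats.levene(*arrays, center="median").pvalue >= gate_alpha
    return normal, ev


def choose_branch(groups, gate_alpha: float = GATE_ALPHA) -> str:
    """Pick the comparison branch from the normality / equal-variance gates."""
    arrays = _validate_groups(groups)
    normal, ev = _gates(arrays, gate_alpha)
    table = _TWO_GROUP_BRANCHES if len(arrays) == 2 else _THREE_GROUP_BRANCHES
    return table[(normal, ev)]


def _scheffe_pairwise(arrays):
    """Scheffe simultaneous p-values for all pairwise mean contrasts."""
    k = len(arrays)
    ns = np.array([g.size for g in arrays])
    means = np.array([g.mean() for g in arrays])
    N = int(ns.sum())
    mse = sum(((g - g.mean()) ** 2).sum() for g in arrays) / (N - k)
    rows = []
    for i, j in combinations(range(k), 2):
        f = (means[i] - means[j]) ** 2 / (mse * (1 / ns[i] + 1 / ns[j])) / (k - 1)
        p = float(stats.f.sf(f, k - 1, N - k))
        rows.append(((i, j), p))
    return rows


@dataclass
class ComparisonResult:
    """Outcome of one decision-tree group comparison."""

    grouping: str
    labels: list[str]
    branch: str
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, test, p_raw, p_adjusted, significant
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        """Omnibus rejection at alpha (for two groups: the single test)."""
        return bool(self.omnibus_p < self.alpha)

    @property
    def any_pairwise_significant(self) -> bool:
        return bool(self.pairwise["significant"].any())


def compare_groups(
    groups,
    labels=None,
    grouping: str = "",
    alpha: float = ALPHA,
    gate_alpha: float = GATE_ALPHA,
) -> ComparisonResult:
    """Run the decision-tree comparison across the given groups."""
    arrays = _validate_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    labels = [str(x) for x in labels]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    branch = choose_branch(arrays, gate_alpha)

    if k == 2:
        a, b = arrays
        if branch == "t_equal":
            res = stats.ttest_ind(a, b, equal_var=True)
            test = "t_equal"
        elif branch == "t_unequal":
            res = stats.ttest_ind(a, b, equal_var=False)
            test = "t_unequal"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mannwhitney"
        p_raw = float(res.pvalue)
        p_adj = float(holm_adjust([p_raw])[0])
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": labels[0],
                    "group_b": labels[1],
                    "test": test,
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                }
            ]
        )
        return ComparisonResult(
            grouping, labels, branch, test, float(res.statistic), p_raw, pairwise, alpha
        )

    # omnibus
    if branch == "anova_scheffe":
        omni = stats.f_oneway(*arrays)
        omni_name = "anova"
    else:
        omni = stats.kruskal(*arrays)
        omni_name = "kruskal"

    rows = []
    if branch == "anova_scheffe":
        for (i, j), p in _scheffe_pairwise(arrays):
            rows.append((labels[i], labels[j], "scheffe", p, p))
    else:
        raw = []
        pairs = list(combinations(range(k), 2))
        for i, j in pairs:
            if branch == "kruskal_t_unequal":
                p = float(stats.ttest_ind(arrays[i], arrays[j], equal_var=False).pvalue)
                test = "t_unequal"
            else:
                p = float(
                    stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided").pvalue
                )
                test = "mannwhitney"
            raw.append((i, j, test, p))
        adj = holm_adjust([r[3] for r in raw])
        for (i, j, test, p), pa in zip(raw, adj):
            rows.append((labels[i], labels[j], test, p, float(pa)))
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "test", "p_raw", "p_adjusted"]
    )
    pairwise["significant"] = pairwise["p_adjusted"] < alpha
    return ComparisonResult(
        grouping,
        labels,
        branch,
        omni_name,
        float(omni.statistic),
        float(omni.pvalue),
        pairwise,
        alpha,
    )
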