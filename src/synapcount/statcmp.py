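"""Group-comparison statistics with a normality/homoscedasticity gate.

Layer comparisons use ANOVA when every group passes Shapiro-Wilk normality
and the set passes Levene homoscedasticity at alpha = 0.05; otherwise the
Kruskal-Wallis test, followed by Dunn's pairwise test (Holm-adjusted) for
three or more groups or the Mann-Whitney U test for two.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_GATE = 0.05


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class GroupComparison:
    groups: list[str]
    test: str                      # "ANOVA" | "KW" | "MW"
    statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _validate(groups: dict) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size < 3:
            raise ValueError(f"group {name!r} has n < 3")
        out[str(name)] = arr
    return out


def choose_test(groups: dict, alpha: float = ALPHA_GATE,
                normality="shapiro", homoscedasticity="levene") -> str:
    """Return "ANOVA" if all groups look normal with equal variances,
    else "KW".

    A zero-variance (constant) group cannot pass a normality test and is
    routed to the nonparametric branch.
    """
    groups = _validate(groups)
    if normality != "shapiro" or homoscedasticity != "levene":
        raise ValueError("only shapiro + levene gates are implemented")
    for vals in groups.values():
        if np.ptp(vals) == 0:
            return "KW"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(vals).pvalue <= alpha:
                return "KW"
    if stats.levene(*groups.values()).pvalue <= alpha:
        return "KW"
    return "ANOVA"


def dunn_test(groups: dict, adjust="holm"):
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z_ij = (mean_rank_i - mean_rank_j) / sqrt(V (1/n_i + 1/n_j)) with
    V = N(N+1)/12 corrected for ties; two-sided normal p-values, adjusted
    with Holm by default (``adjust=None`` for unadjusted).
    """
    groups = _validate(groups)
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = all_vals.size
    ranks = stats.rankdata(all_vals)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_corr = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_corr

    results, raw_ps = [], []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(variance * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        results.append([a, b, float(z), float(p)])
        raw_ps.append(p)
    if adjust is None:
        adj = raw_ps
    else:
        adj = multipletests(raw_ps, method=adjust)[1]
    return [PairwiseResult(a, b, z, p, float(pa))
            for (a, b, z, p), pa in zip(results, adj)]


def compare_groups(groups: dict, alpha: float = ALPHA_GATE,
                   adjust="holm") -> GroupComparison:
    """Omnibus comparison with the gate, plus pairwise tests when applicable.

    Parametric branch: one-way ANOVA (no pairwise follow-up is attached).
    Nonparametric branch: Kruskal-Wallis with Holm-adjusted Dunn pairwise
    tests for >= 3 groups, or the Mann-Whitney U test for exactly two.
    """
    groups = _validate(groups)
    names = list(groups)
    chosen = choose_test(groups, alpha=alpha)
    if chosen == "ANOVA":
        res = stats.f_oneway(*groups.values())
        return GroupComparison(groups=names, test="ANOVA",
                               statistic=float(res.statistic),
                               p_value=float(min(res.pvalue, 1.0)))
    if len(groups) == 2:
        a, b = groups.values()
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        pair = PairwiseResult(names[0], names[1], float(res.statistic),
                              float(res.pvalue), float(res.pvalue))
        return GroupComparison(groups=names, test="MW",
                               statistic=float(res.statistic),
                               p_value=float(res.pvalue), pairwise=[pair])
    try:
        res = stats.kruskal(*groups.values())
        stat, p = float(res.statistic), float(res.pvalue)
    except ValueError:          # all values identical across all groups
        stat, p = 0.0, 1.0
    return GroupComparison(groups=names, test="KW", statistic=stat,
                           p_value=p,
                           pairwise=dunn_test(groups, adjust=adjust))


def comparison_from_frame(df, group_col="group", value_col="value",
                          **kw) -> GroupComparison:
    """Long-format DataFrame (unit, group, value) -> GroupComparison."""
    groups = {g: sub[value_col].to_numpy()
              for g, sub in df.groupby(group_col, sort=False)}
    return compare_groups(groups, **kw)


def comparison_to_dict(comp: GroupComparison) -> dict:
    return {
        "groups": comp.groups,
        "test": comp.test,
        "statistic": comp.statistic,
        "p_value": comp.p_value,
        "pairwise": [
            {"a": p.group_a, "b": p.group_b, "statistic": p.statistic,
             "p": p.p_unadjusted, "p_adjusted": p.p_adjusted}
            for p in comp.pairwise],
    }
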