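"""Nonparametric group comparison of normalized responses.

Normalized spike-rate responses across stimulation-parameter groups are
not normally distributed (checked with Shapiro-Wilk), so group effects are
tested with the Kruskal-Wallis H test and characterized post hoc with
two-sided Wilcoxon rank-sum (Mann-Whitney) tests under Bonferroni
correction. "Wilcoxon" here is always the two-sample rank-sum test: every
comparison is between independent unit populations, so the signed-rank
variant does not apply. A two-way ANOVA on the raw normalized responses
tests condition x parameter designs (a rank-transform switch is provided
for a robust variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols


@dataclass
class GroupResult:
    """Omnibus + post-hoc summary for one grouping factor."""

    group_names: list[str]
    n_per_group: list[int]
    h_statistic: float
    p_omnibus: float
    normality_p: dict[str, float]
    pairwise_p: np.ndarray  # Bonferroni-corrected, symmetric, diag = nan
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_comparisons: int = 0


def normality(groups: dict[str, np.ndarray]) -> dict[str, float]:
    """Shapiro-Wilk p-value per group. Groups need n >= 3 and variation."""
    out: dict[str, float] = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has n < 3; Shapiro-Wilk undefined")
        if np.ptp(vals) == 0:
            raise ValueError(f"group {name!r} is constant; Shapiro-Wilk undefined")
        out[name] = float(sps.shapiro(vals).pvalue)
    return out


def omnibus(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        raise ValueError("all observations identical; H undefined")
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact null enumeration when both samples have n <= 10 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """All-pairs rank-sum tests with Bonferroni correction.

    Returns the symmetric matrix of corrected p-values (diagonal NaN) and
    the list of pairs significant at ``alpha`` after correction.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    m = k * (k - 1) // 2
    pmat = np.full((k, k), np.nan)
    sig: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = np.asarray(groups[names[i]]), np.asarray(groups[names[j]])
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            else:
                _, p = rank_sum(a, b)
            p_corr = min(1.0, p * m)
            pmat[i, j] = pmat[j, i] = p_corr
            if p_corr < alpha:
                sig.append((names[i], names[j]))
    return pmat, sig


def group_comparison(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> GroupResult:
    """Full comparison: normality screen, omnibus H, corrected post hocs."""
    h, p = omnibus(groups)
    try:
        norm_p = normality(groups)
    except ValueError:
        norm_p = {}
    pmat, sig = pairwise(groups, alpha=alpha)
    k = len(groups)
    return GroupResult(
        group_names=list(groups),
        n_per_group=[len(v) for v in groups.values()],
        h_statistic=h,
        p_omnibus=p,
        normality_p=norm_p,
        pairwise_p=pmat,
        significant_pairs=sig,
        n_comparisons=k * (k - 1) // 2,
    )


def two_factor(
    responses: np.ndarray | list[float],
    factor_a: list[str],
    factor_b: list[str],
    on_ranks: bool = False,
) -> dict[str, float]:
    """Two-way ANOVA p-values for main effects and interaction.

    ``factor_a`` is typically the condition (awake vs anesthetized) and
    ``factor_b`` the stimulation-parameter level. With ``on_ranks`` the
    responses are rank-transformed first (a robust variant).
    """
    df = pd.DataFrame(
        {
            "response": np.asarray(responses, dtype=float),
            "a": list(factor_a),
            "b": list(factor_b),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    cells = df.groupby(["a", "b"], observed=True).size()
    full = pd.MultiIndex.from_product([df["a"].unique(), df["b"].unique()])
    missing = full.difference(cells.index)
    if len(missing) > 0:
        raise ValueError(f"empty design cell(s): {list(missing)}")
    if on_ranks:
        df["response"] = sps.rankdata(df["response"])
    model = ols("response ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "a": float(table.loc["C(a)", "PR(>F)"]),
        "b": float(table.loc["C(b)", "PR(>F)"]),
        "interaction": float(table.loc["C(a):C(b)", "PR(>F)"]),
    }


def compare_latencies(
    latencies_a: np.ndarray | list[float],
    latencies_b: np.ndarray | list[float],
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of two unit-latency distributions."""
    return rank_sum(np.asarray(latencies_a), np.asarray(latencies_b))
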