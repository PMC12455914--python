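"""Alpha-diversity estimators and univariate group statistics.

Per-sample indices: bias-corrected Chao1 richness, Shannon entropy in nats,
and the Gini-Simpson index (1 - sum p_i^2).  Group comparisons use the
Wilcoxon rank-sum (Mann-Whitney) test for two groups, Kruskal-Wallis for
several, ANOVA eta-squared for effect sizes, and Benjamini-Hochberg step-up
adjustment across each test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AbundanceTable, DataError

#: below this combined sample size (and with no ties) the rank-sum test uses
#: exact enumeration of the U distribution rather than the normal
#: approximation
EXACT_RANKSUM_MAX_N = 12


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _as_counts(row) -> np.ndarray:
    x = np.asarray(row, dtype=float).ravel()
    if x.size == 0 or x.sum() <= 0:
        raise DataError("alpha diversity needs a row with positive total")
    if x.min() < 0:
        raise DataError("negative count in abundance row")
    return x


def shannon(counts_row) -> float:
    """Shannon entropy H = -sum p_i ln p_i over nonzero p_i (nats)."""
    x = _as_counts(counts_row)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts_row) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    x = _as_counts(counts_row)
    p = x / x.sum()
    return float(1.0 - (p ** 2).sum())


def chao1(counts_row) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the singleton and doubleton counts; with no singletons the
    estimate equals the observed richness.
    """
    x = _as_counts(counts_row)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Chao1 / Shannon / Simpson table (index sample_id)."""
    rows = {
        sid: (chao1(row), shannon(row), simpson(row))
        for sid, row in table.counts.iterrows()
    }
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chao1", "shannon", "simpson"]
    )
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """One hypothesis test over a metadata grouping."""

    grouping: str
    test: str
    statistic: float
    p_value: float
    q_value: float = float("nan")
    effect_size: float = float("nan")
    detail: dict = field(default_factory=dict)


def wilcoxon_rank_sum(x_values, y_values, grouping: str = "") -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when n1 + n2 <= EXACT_RANKSUM_MAX_N and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.  The method used is recorded in ``detail``.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("wilcoxon_rank_sum: both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult(
        grouping=grouping, test="wilcoxon_rank_sum",
        statistic=float(u), p_value=float(min(p, 1.0)),
        detail={"method": method, "n": (int(x.size), int(y.size))},
    )


def kruskal_wallis(groups, grouping: str = "") -> GroupTestResult:
    """Kruskal-Wallis H test with tie correction (chi-square, k-1 df).

    When every observation is identical the tie correction degenerates; by
    convention H = 0 and p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise DataError("kruskal_wallis: need >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return GroupTestResult(
            grouping=grouping, test="kruskal_wallis", statistic=0.0, p_value=1.0,
            detail={"degenerate": "all values identical"},
        )
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(
        grouping=grouping, test="kruskal_wallis",
        statistic=float(h), p_value=float(p),
        detail={"k": len(arrays)},
    )


def eta_squared_anova(values, factor_a, factor_b=None, grouping: str = "") -> list[GroupTestResult]:
    """ANOVA effect sizes (eta-squared) for one or two crossed factors.

    One factor: classical eta^2 = SS_between / SS_total with the one-way F
    test.  Two factors: a type-II two-way ANOVA with interaction; each term
    is reported with both classical eta^2 (SS_term / SS_total) and partial
    eta^2 (SS_term / (SS_term + SS_resid)), labeled in ``detail``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(values, dtype=float)
    a = pd.Series(factor_a).astype(str).to_numpy()
    if y.size != a.size:
        raise DataError("values and factor_a must have equal length")
    if pd.unique(a).size < 2:
        raise DataError("factor_a has a single level")

    if factor_b is None:
        groups = [y[a == lvl] for lvl in pd.unique(a)]
        grand = y.mean()
        ss_total = float(((y - grand) ** 2).sum())
        ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
        if ss_total == 0:
            return [GroupTestResult(grouping, "anova_one_way", 0.0, 1.0,
                                    effect_size=0.0, detail={"term": "factor_a"})]
        f_stat, p = stats.f_oneway(*groups)
        return [GroupTestResult(
            grouping=grouping, test="anova_one_way",
            statistic=float(f_stat), p_value=float(p),
            effect_size=ss_between / ss_total,
            detail={"term": "factor_a", "eta_sq": ss_between / ss_total},
        )]

    b = pd.Series(factor_b).astype(str).to_numpy()
    if pd.unique(b).size < 2:
        raise DataError("factor_b has a single level")
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    ss_total = float(tab["sum_sq"].sum())
    results = []
    for term in [t for t in tab.index if t != "Residual"]:
        ss = float(tab.loc[term, "sum_sq"])
        partial = ss / (ss + ss_resid) if (ss + ss_resid) > 0 else 0.0
        results.append(GroupTestResult(
            grouping=grouping, test="anova_two_way",
            statistic=float(tab.loc[term, "F"]),
            p_value=float(tab.loc[term, "PR(>F)"]),
            effect_size=partial,
            detail={"term": term,
                    "eta_sq": ss / ss_total if ss_total > 0 else 0.0,
                    "partial_eta_sq": partial},
        ))
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    NaN entries (untestable hypotheses) are passed through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def attach_q_values(results: list[GroupTestResult]) -> list[GroupTestResult]:
    """BH-adjust across one family of GroupTestResults, in place."""
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def compare_alpha(
    alpha: pd.DataFrame, metadata, index: str
) -> list[GroupTestResult]:
    """The standard alpha-diversity contrasts for one index.

    Oral vs nasopharyngeal (rank-sum), across seasons within each site
    (Kruskal-Wallis plus pairwise rank-sum), and age/season eta-squared;
    BH-adjusted as one family per index.
    """
    from .core import SEASONS, SITES

    meta = metadata.table.loc[alpha.index]
    vals = alpha[index]
    results: list[GroupTestResult] = []
    o = vals[meta["site"] == "oral"]
    n = vals[meta["site"] == "nasopharyngeal"]
    if len(o) and len(n):
        results.append(wilcoxon_rank_sum(o, n, grouping=f"{index}: oral vs nasopharyngeal"))
    for site in SITES:
        sub = meta["site"] == site
        groups = [vals[sub & (meta["season"] == s)] for s in SEASONS]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 2:
            results.append(kruskal_wallis(groups, grouping=f"{index}: {site} across seasons"))
        for i in range(len(SEASONS)):
            for j in range(i + 1, len(SEASONS)):
                gi = vals[sub & (meta["season"] == SEASONS[i])]
                gj = vals[sub & (meta["season"] == SEASONS[j])]
                if len(gi) and len(gj):
                    results.append(wilcoxon_rank_sum(
                        gi, gj,
                        grouping=f"{index}: {site} {SEASONS[i]} vs {SEASONS[j]}",
                    ))
    if meta["age"].nunique() >= 2 and meta["season"].nunique() >= 2:
        results.extend(eta_squared_anova(
            vals, meta["age"], meta["season"],
            grouping=f"{index}: age x season",
        ))
    return attach_q_values(results)


def results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Flatten GroupTestResults to a writable table."""
    return pd.DataFrame([
        {
            "grouping": r.grouping, "test": r.test,
            "term": r.detail.get("term", ""),
            "statistic": r.statistic, "p_value": r.p_value,
            "q_value": r.q_value, "effect_size": r.effect_size,
            "method": r.detail.get("method", ""),
        }
        for r in results
    ])
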