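"""Subject movement between community states across adjacent seasons.

Subjects sampled at both seasons of a (site, season-pair) contribute one
count to the cluster-to-cluster transition matrix.  Each ordered cluster
pair (i, j) is tested with a two-sided Fisher exact test on the 2x2 table

    [[ n(i -> j),      n(i -> not j) ],
     [ n(not i -> j),  n(not i -> not j) ]]

with the sample odds ratio (Haldane-Anscombe +0.5 on zero cells) and
Benjamini-Hochberg adjustment within the season-pair family.  The module
also builds the directed transition network and a genus co-occurrence
(association) network from CLR-transformed abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSolution
from .core import OTHER, UNASSIGNED, DataError, RelativeAbundanceTable, SampleMetadata, logger
from .diversity import bh_adjust

SEASON_INDEX = {"autumn": 0, "winter": 1, "spring": 2}


# ---------------------------------------------------------------------------
# Fisher exact test (hypergeometric enumeration)
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> tuple[float, float]:
    """(odds_ratio, two-sided p) for a 2x2 contingency table.

    p sums every hypergeometric outcome (margins fixed) whose probability
    does not exceed the observed one; the odds ratio is ad/bc, computed
    with the Haldane-Anscombe +0.5 correction when any cell is zero.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or t.min() < 0:
        raise DataError("fisher_exact_2x2 needs a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return float("nan"), 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def conditional_mle_odds_ratio(table) -> float:
    """Conditional maximum-likelihood odds ratio (Fisher's noncentral
    hypergeometric); configurable alternative to the sample estimator."""
    res = stats.contingency.odds_ratio(np.asarray(table, dtype=np.int64),
                                       kind="conditional")
    return float(res.statistic)


# ---------------------------------------------------------------------------
# Transition tables
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """Counts of subjects moving between clusters across one season pair."""

    site: str
    season_pair: tuple[str, str]
    matrix: pd.DataFrame  # from clusters (rows) x to clusters (cols)
    subjects: list[str]
    attrition: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return int(self.matrix.to_numpy().sum())


def build_transition_table(
    solution_t: ClusterSolution,
    solution_t1: ClusterSolution,
    metadata: SampleMetadata,
) -> TransitionTable:
    """Match subjects across two adjacent-season cluster solutions.

    Subjects present at both seasons contribute one increment; subjects
    present at only one are excluded and counted in the attrition summary.
    """
    if solution_t.site != solution_t1.site:
        raise DataError("transition table needs solutions from the same site")
    s_from, s_to = solution_t.season, solution_t1.season
    if SEASON_INDEX.get(s_to, -1) - SEASON_INDEX.get(s_from, -1) != 1:
        raise DataError(f"seasons {s_from!r} -> {s_to!r} are not adjacent")
    subj = metadata.subject_of()

    def subject_map(sol: ClusterSolution) -> dict[str, str]:
        out: dict[str, str] = {}
        for sid, cluster in sol.labels.items():
            s = subj.get(sid)
            if s is None:
                raise DataError(f"sample {sid!r} missing from metadata")
            if s in out:
                raise DataError(
                    f"subject {s!r} has duplicate samples in stratum "
                    f"{sol.stratum}"
                )
            out[s] = cluster
        return out

    at_t = subject_map(solution_t)
    at_t1 = subject_map(solution_t1)
    shared = sorted(set(at_t) & set(at_t1))
    rows = sorted(solution_t.labels.unique())
    cols = sorted(solution_t1.labels.unique())
    matrix = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int64)
    for s in shared:
        matrix.loc[at_t[s], at_t1[s]] += 1
    attrition = {
        "only_first_season": len(set(at_t) - set(at_t1)),
        "only_second_season": len(set(at_t1) - set(at_t)),
        "paired": len(shared),
    }
    logger.info("transitions %s %s->%s: %d paired subjects, attrition %s",
                solution_t.site, s_from, s_to, len(shared), attrition)
    matrix.index.name = "from_cluster"
    matrix.columns.name = "to_cluster"
    return TransitionTable(
        site=solution_t.site, season_pair=(s_from, s_to),
        matrix=matrix, subjects=shared, attrition=attrition,
    )


def test_transitions(
    table: TransitionTable,
    alpha: float = 0.05,
    odds_estimator: str = "sample",
) -> pd.DataFrame:
    """Fisher exact test for every ordered (from, to) cluster pair.

    The 2x2 contrasts subjects leaving cluster i for j against all other
    subjects' destinations; BH runs within this (site, season-pair) family.
    A pair whose row and column are both empty is untestable.
    """
    if odds_estimator not in ("sample", "conditional_mle"):
        raise DataError("odds_estimator must be 'sample' or 'conditional_mle'")
    m = table.matrix.to_numpy()
    total = m.sum()
    rows = []
    for i, fc in enumerate(table.matrix.index):
        for j, tc in enumerate(table.matrix.columns):
            a = int(m[i, j])
            b = int(m[i, :].sum() - a)
            c = int(m[:, j].sum() - a)
            d = int(total - a - b - c)
            untestable = (a + b == 0) and (a + c == 0)
            if untestable:
                odds, p = float("nan"), float("nan")
            else:
                odds, p = fisher_exact_2x2([[a, b], [c, d]])
                if odds_estimator == "conditional_mle":
                    odds = conditional_mle_odds_ratio([[a, b], [c, d]])
            rows.append({
                "from_cluster": fc, "to_cluster": tc, "count": a,
                "n11": a, "n12": b, "n21": c, "n22": d,
                "odds_ratio": odds, "fisher_p": p, "untestable": untestable,
            })
    out = pd.DataFrame(rows)
    out["bh_q"] = bh_adjust(out["fisher_p"].where(~out["untestable"]))
    out["significant"] = (out["bh_q"] < alpha) & ~out["untestable"]
    return out


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def build_transition_network(
    table: TransitionTable, results: pd.DataFrame | None = None
) -> nx.DiGraph:
    """Directed cluster-to-cluster graph for one season pair.

    Node size = stratum membership count (row total at the first season,
    column total at the second for new clusters); edge weight = transition
    count with a significance flag carried over from ``results``.  Node and
    edge insertion order is deterministic (sorted names).
    """
    g = nx.DiGraph(site=table.site,
                   season_pair="->".join(table.season_pair))
    row_tot = table.matrix.sum(axis=1)
    col_tot = table.matrix.sum(axis=0)
    nodes = sorted(set(table.matrix.index) | set(table.matrix.columns))
    for node in nodes:
        size = int(row_tot.get(node, 0) + col_tot.get(node, 0))
        g.add_node(node, size=size)
    sig = {}
    if results is not None:
        for _, r in results.iterrows():
            sig[(r["from_cluster"], r["to_cluster"])] = bool(r["significant"])
    for fc in sorted(table.matrix.index):
        for tc in sorted(table.matrix.columns):
            w = int(table.matrix.loc[fc, tc])
            if w > 0:
                g.add_edge(fc, tc, weight=w,
                           significant=sig.get((fc, tc), False))
    return g


def write_network(g: nx.DiGraph | nx.Graph, gexf_path=None, graphml_path=None) -> None:
    """Export a network for external viewers (Gephi-readable GEXF, GraphML)."""
    if gexf_path is not None:
        nx.write_gexf(g, gexf_path)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)


# ---------------------------------------------------------------------------
# Taxon association network (CLR + Spearman)
# ---------------------------------------------------------------------------

def clr_transform(rel: RelativeAbundanceTable) -> pd.DataFrame:
    """Centered log-ratio transform with zero replacement.

    Zeros become half the smallest nonzero fraction in the table; rows are
    re-closed before taking logs.
    """
    x = rel.fractions.to_numpy(dtype=float).copy()
    nonzero = x[x > 0]
    if nonzero.size == 0:
        raise DataError("cannot CLR-transform an all-zero table")
    x[x == 0] = nonzero.min() / 2.0
    x = x / x.sum(axis=1, keepdims=True)
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=rel.sample_ids, columns=rel.taxon_ids)


def taxon_association_network(
    rel: RelativeAbundanceTable,
    site: str = "",
    q_threshold: float = 0.05,
    rho_threshold: float = 0.3,
    min_samples: int = 10,
    exclude: tuple[str, ...] = (UNASSIGNED, OTHER),
) -> tuple[pd.DataFrame, nx.Graph, str | None]:
    """Genus-genus association edges from CLR abundances.

    Spearman rank correlation per genus pair, BH-adjusted; edges kept at
    q < q_threshold and |rho| >= rho_threshold.  Returns (edge table,
    undirected graph, hub genus).  The hub is the maximum-degree node, ties
    broken by summed |rho|.  This association measure is a reconstruction
    with configurable thresholds (see column header note in the output).
    """
    if len(rel.sample_ids) < min_samples:
        raise DataError(
            f"association network needs >= {min_samples} samples "
            f"(got {len(rel.sample_ids)}): correlation would be unstable"
        )
    clr = clr_transform(rel)
    genera = [g for g in clr.columns if g not in exclude]
    pairs, rhos, ps = [], [], []
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            a, b = clr[genera[i]], clr[genera[j]]
            if a.nunique() < 2 or b.nunique() < 2:
                continue
            rho, p = stats.spearmanr(a, b)
            pairs.append((genera[i], genera[j]))
            rhos.append(float(rho))
            ps.append(float(p))
    edges = pd.DataFrame({
        "genus_a": [p[0] for p in pairs],
        "genus_b": [p[1] for p in pairs],
        "rho": rhos,
        "p_value": ps,
    })
    edges["q_value"] = bh_adjust(edges["p_value"])
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    edges["kept"] = (edges["q_value"] < q_threshold) & (edges["rho"].abs() >= rho_threshold)
    kept = edges[edges["kept"]]

    g = nx.Graph(site=site, measure="CLR+Spearman (reconstruction)",
                 q_threshold=q_threshold, rho_threshold=rho_threshold)
    g.add_nodes_from(sorted(set(kept["genus_a"]) | set(kept["genus_b"])))
    for _, r in kept.sort_values(["genus_a", "genus_b"]).iterrows():
        g.add_edge(r["genus_a"], r["genus_b"], rho=float(r["rho"]),
                   sign=r["sign"], q_value=float(r["q_value"]))
    hub = None
    if g.number_of_nodes():
        strength = {
            node: sum(abs(d["rho"]) for _, _, d in g.edges(node, data=True))
            for node in g.nodes
        }
        hub = max(sorted(g.nodes), key=lambda v: (g.degree(v), strength[v]))
    return edges, g, hub
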