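"""Community state typing: Ward clustering per (site, season) stratum.

Samples are clustered on their genus-level relative-abundance profiles with
Ward's minimum-variance agglomeration; the number of clusters is chosen by
mean silhouette over a candidate range (with a manual override for the
"inspect the dendrogram" step), cluster stability is scored by a plain
column bootstrap, and per-cluster dominant genera are identified by Welch
t-tests of inside- vs outside-cluster abundance with Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, leaves_list
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .core import OTHER, UNASSIGNED, DataError, RelativeAbundanceTable, logger
from .diversity import bh_adjust

DISTANCE_KINDS = ("euclidean", "correlation")


@dataclass
class Dendrogram:
    """Ward merge tree in scipy linkage form.

    ``linkage`` rows are (cluster_a, cluster_b, height, size) in merge
    order; leaves are numbered 0..n-1 in ``leaf_ids`` order and internal
    node i gets id n+i.  Heights are non-decreasing (Ward reducibility).
    """

    linkage: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        z = np.asarray(self.linkage, dtype=float)
        if z.shape != (n - 1, 4):
            raise DataError("linkage must have n-1 merges for n leaves")
        if np.any(np.diff(z[:, 2]) < -1e-9):
            raise DataError("merge heights must be non-decreasing")
        self.linkage = z

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def merges(self) -> np.ndarray:
        """(n-1, 2) int array of merged node ids, in merge order."""
        return self.linkage[:, :2].astype(int)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in leaves_list(self.linkage)]

    def node_leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-id set below each internal node, in merge order."""
        sets: dict[int, frozenset[str]] = {
            i: frozenset([s]) for i, s in enumerate(self.leaf_ids)
        }
        out = []
        n = self.n_leaves
        for step, (a, b) in enumerate(self.merges):
            merged = sets[a] | sets[b]
            sets[n + step] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences so each
        internal node sits at its merge height."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        reps: dict[int, str] = {
            i: _quote_newick(s) for i, s in enumerate(self.leaf_ids)
        }
        for step, (a, b) in enumerate(self.merges):
            h = self.heights[step]
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            reps[n + step] = f"({reps[a]}:{la:.10g},{reps[b]}:{lb:.10g})"
            heights[n + step] = h
        return reps[n + self.n_leaves - 2] + ";"


def _quote_newick(name: str) -> str:
    if any(c in name for c in " ():;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass
class ClusterSolution:
    """Cluster labels for one (site, season) stratum."""

    stratum: tuple[str, str]  # (site, season)
    labels: pd.Series  # sample_id -> cluster name
    k: int
    silhouette_by_k: dict[int, float]
    dendrogram: Dendrogram
    distance_kind: str = "euclidean"
    bootstrap_support: dict[int, float] | None = None

    @property
    def site(self) -> str:
        return self.stratum[0]

    @property
    def season(self) -> str:
        return self.stratum[1]

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts()


# ---------------------------------------------------------------------------
# Ward linkage (Lance-Williams on squared distances)
# ---------------------------------------------------------------------------

def _pair_distances(x: np.ndarray, distance_kind: str) -> np.ndarray:
    if distance_kind == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if distance_kind == "correlation":
        return squareform(pdist(x, metric="correlation"))
    raise DataError(f"distance_kind must be one of {DISTANCE_KINDS}")


def ward_cluster(
    rel: RelativeAbundanceTable, distance_kind: str = "euclidean"
) -> Dendrogram:
    """Agglomerative Ward linkage over sample profiles.

    Successive merges minimize the Ward criterion (the squared
    cluster-to-cluster distance under the Lance-Williams update); ties are
    broken deterministically by the lowest-numbered cluster pair.  Reported
    heights are the square roots of the Ward criterion, matching the usual
    "ward.D2" convention, so two identical samples merge at height 0.
    """
    x = rel.fractions.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise DataError("ward_cluster needs at least 2 samples")
    d2 = _pair_distances(x, distance_kind) ** 2

    big = np.inf
    m = d2.copy().astype(float)
    np.fill_diagonal(m, big)
    ids = list(range(n))  # positions ordered by cluster id throughout
    sizes = [1.0] * n
    z = np.zeros((n - 1, 4))
    last_h = 0.0
    for step in range(n - 1):
        tri = np.triu(np.ones_like(m, dtype=bool), 1)
        masked = np.where(tri, m, big)
        flat = int(np.argmin(masked))  # row-major => lowest-numbered pair on ties
        i, j = divmod(flat, m.shape[0])
        h = float(np.sqrt(max(masked[i, j], 0.0)))
        h = max(h, last_h)  # guard against 1e-16 float noise only
        last_h = h
        ni, nj = sizes[i], sizes[j]
        z[step] = (min(ids[i], ids[j]), max(ids[i], ids[j]), h, ni + nj)
        # Lance-Williams (Ward): new squared distance to every other cluster
        keep = [p for p in range(len(ids)) if p not in (i, j)]
        nk = np.array([sizes[p] for p in keep])
        new_row = (
            (ni + nk) * m[i, keep] + (nj + nk) * m[j, keep] - nk * m[i, j]
        ) / (ni + nj + nk)
        m = m[np.ix_(keep, keep)]
        m = np.pad(m, ((0, 1), (0, 1)), constant_values=big)
        m[-1, :-1] = new_row
        m[:-1, -1] = new_row
        ids = [ids[p] for p in keep] + [n + step]
        sizes = [sizes[p] for p in keep] + [ni + nj]
    return Dendrogram(z, list(rel.sample_ids))


def cut_dendrogram(dend: Dendrogram, k: int) -> pd.Series:
    """Flat clustering with exactly ``k`` clusters (integer labels 0..k-1,
    numbered by first appearance in leaf-id order)."""
    if not 1 <= k <= dend.n_leaves:
        raise DataError(f"k={k} out of range for {dend.n_leaves} leaves")
    flat = cut_tree(dend.linkage, n_clusters=k).ravel()
    return pd.Series(flat, index=dend.leaf_ids)


def _mean_silhouette(x: np.ndarray, dist: np.ndarray, labels: np.ndarray,
                     distance_kind: str) -> float:
    if len(np.unique(labels)) < 2:
        return float("nan")
    if distance_kind == "euclidean":
        return float(silhouette_score(x, labels, metric="euclidean"))
    return float(silhouette_score(dist, labels, metric="precomputed"))


def select_k(
    dend: Dendrogram,
    rel: RelativeAbundanceTable,
    k_min: int = 2,
    k_max: int = 10,
    distance_kind: str = "euclidean",
    k_override: int | None = None,
    stratum: tuple[str, str] = ("", ""),
) -> ClusterSolution:
    """Choose the cluster count by mean silhouette over [k_min, k_max].

    The full silhouette trace is retained; ``k_override`` (the manual
    dendrogram-inspection route) bypasses the argmax, including k=1 for
    which the silhouette is undefined and recorded as NaN.  Clusters are
    named C1, C2, ... by decreasing size (ties by smallest member id).
    """
    n = dend.n_leaves
    if k_max >= n:
        raise DataError(f"k_max={k_max} must be < number of samples ({n})")
    if k_min < 2:
        raise DataError("k_min must be >= 2")
    x = rel.fractions.loc[dend.leaf_ids].to_numpy(dtype=float)
    dist = _pair_distances(x, distance_kind)
    trace: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels = cut_dendrogram(dend, k).to_numpy()
        trace[k] = _mean_silhouette(x, dist, labels, distance_kind)
    if k_override is not None:
        if not 1 <= k_override <= n:
            raise DataError(f"k_override={k_override} out of range")
        k_star = k_override
    else:
        k_star = max(trace, key=lambda k: (trace[k], -k))
    flat = cut_dendrogram(dend, k_star)
    named = _name_clusters(flat)
    chosen_sil = trace.get(k_star, float("nan"))
    if k_star == 1:
        chosen_sil = float("nan")
        logger.info("select_k%s: k=1 override, silhouette undefined", stratum)
    return ClusterSolution(
        stratum=stratum, labels=named, k=k_star, silhouette_by_k=trace,
        dendrogram=dend, distance_kind=distance_kind,
    )


def _name_clusters(flat: pd.Series) -> pd.Series:
    """Deterministic names C1..Ck by decreasing size, ties by first member."""
    order = sorted(
        flat.unique(),
        key=lambda c: (-(flat == c).sum(), min(flat.index[flat == c])),
    )
    mapping = {c: f"C{i + 1}" for i, c in enumerate(order)}
    return flat.map(mapping)


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------

def bootstrap_support(
    rel: RelativeAbundanceTable,
    dend: Dendrogram,
    n_boot: int = 100,
    seed: int | None = None,
    distance_kind: str = "euclidean",
) -> dict[int, float] | None:
    """Plain bootstrap proportion per internal node.

    Taxa columns are resampled with replacement ``n_boot`` times, the
    stratum is re-clustered, and each original internal node is scored by
    the fraction of replicates whose tree contains the same leaf set.
    Returns None (supports absent) when n_boot == 0.
    """
    if n_boot == 0:
        logger.info("bootstrap_support: n_boot=0, supports absent")
        return None
    rng = np.random.default_rng(seed)
    original = dend.node_leaf_sets()
    hits = np.zeros(len(original))
    frame = rel.fractions.loc[dend.leaf_ids]
    p = frame.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        resampled = frame.iloc[:, cols]
        resampled.columns = [f"b{i}" for i in range(p)]
        boot = _ward_on_matrix(resampled.to_numpy(dtype=float),
                               dend.leaf_ids, distance_kind)
        boot_sets = set(boot.node_leaf_sets())
        for idx, s in enumerate(original):
            if s in boot_sets:
                hits[idx] += 1
    return {i: float(h / n_boot) for i, h in enumerate(hits)}


def _ward_on_matrix(x: np.ndarray, ids: list[str], distance_kind: str) -> Dendrogram:
    fake = RelativeAbundanceTable.__new__(RelativeAbundanceTable)
    fake.fractions = pd.DataFrame(x, index=ids)
    return ward_cluster(fake, distance_kind)


# ---------------------------------------------------------------------------
# Cluster enrichment
# ---------------------------------------------------------------------------

def enrich_clusters(
    rel: RelativeAbundanceTable,
    solution: ClusterSolution,
    alpha: float = 0.05,
    exclude: tuple[str, ...] = (UNASSIGNED, OTHER),
) -> pd.DataFrame:
    """Welch t-test of each genus inside vs outside each cluster.

    BH adjustment runs across the full (cluster, genus) family of the
    stratum; a genus is flagged enriched when q < alpha and the inside mean
    exceeds the outside mean.  Size-one clusters and zero-variance genera
    are marked untestable rather than dropped.
    """
    frame = rel.fractions.loc[solution.labels.index]
    genera = [g for g in frame.columns if g not in exclude]
    rows = []
    for cluster in sorted(solution.labels.unique()):
        inside_idx = solution.labels.index[solution.labels == cluster]
        outside_idx = solution.labels.index[solution.labels != cluster]
        for genus in genera:
            a = frame.loc[inside_idx, genus].to_numpy()
            b = frame.loc[outside_idx, genus].to_numpy()
            mean_in = float(a.mean()) if a.size else float("nan")
            mean_out = float(b.mean()) if b.size else float("nan")
            untestable = a.size < 2 or b.size < 2
            t_stat = p = float("nan")
            if not untestable:
                if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                    untestable = True
                else:
                    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
                    if np.isnan(p):
                        untestable, t_stat, p = True, float("nan"), float("nan")
            rows.append({
                "cluster": cluster, "genus": genus,
                "mean_inside": mean_in, "mean_outside": mean_out,
                "t": float(t_stat), "p_value": float(p),
                "untestable": untestable,
            })
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].where(~out["untestable"]))
    out["enriched"] = (
        (out["q_value"] < alpha)
        & (out["mean_inside"] > out["mean_outside"])
        & ~out["untestable"]
    )
    return out


def dominant_genus(enrichment: pd.DataFrame, cluster: str) -> str:
    """Top genus of a cluster: the enriched genus of highest inside mean,
    falling back to the highest inside mean overall."""
    sub = enrichment[enrichment["cluster"] == cluster]
    enr = sub[sub["enriched"]]
    pick = enr if len(enr) else sub
    return str(pick.sort_values("mean_inside", ascending=False).iloc[0]["genus"])


def assign_family_names(
    solutions: list[ClusterSolution],
    enrichments: list[pd.DataFrame],
) -> dict[tuple[str, str, str], str]:
    """Cross-season community state identity by dominant-genus matching.

    Clusters from different seasons of one site that share the same
    dominant genus receive the same family name ``<genus>-type``; the
    mapping (site, season, cluster) -> family is returned and logged.
    """
    mapping: dict[tuple[str, str, str], str] = {}
    for sol, enr in zip(solutions, enrichments):
        for cluster in sorted(sol.labels.unique()):
            fam = f"{dominant_genus(enr, cluster)}-type"
            mapping[(sol.site, sol.season, cluster)] = fam
            logger.info("family naming: %s/%s %s -> %s",
                        sol.site, sol.season, cluster, fam)
    return mapping
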