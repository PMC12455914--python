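"""Beta diversity: Bray-Curtis dissimilarity, PCoA, PERMANOVA, tight clusters.

Bray-Curtis between two abundance rows x, y is sum|x_i - y_i| / sum(x_i + y_i),
which for relative abundances lies in [0, 1].  Ordination is classical
metric scaling (PCoA): eigendecomposition of the double-centered -0.5 D^2
matrix, coordinates scaled by the square root of each positive eigenvalue.
Group effects on the distance matrix are tested with one-way PERMANOVA
(distance-based pseudo-F with a seeded permutation p-value).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .core import DataError, RelativeAbundanceTable, logger


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix over sample ids."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise DataError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix diagonal must be exactly zero")
        if v.min() < 0:
            raise DataError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


@dataclass
class OrdinationResult:
    """PCoA coordinates with the eigenvalue spectrum.

    ``coordinates`` keeps only positive-eigenvalue axes, ordered by
    descending eigenvalue; the full spectrum (including any negative
    eigenvalues) is retained in ``eigenvalues``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int
    detail: dict = field(default_factory=dict)


@dataclass
class TightCluster:
    """Largest dense connected set of samples in ordination space."""

    site: str
    members: list[str]
    params: dict


def bray_curtis_vectors(x, y) -> float:
    """Bray-Curtis between two abundance vectors: sum|x-y| / sum(x+y).

    Works on raw counts as well as relative abundances.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    tot = float((a + b).sum())
    if tot == 0:
        return 0.0
    return float(np.abs(a - b).sum() / tot)


def bray_curtis(rel: RelativeAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows."""
    x = rel.fractions.to_numpy(dtype=float)
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / tot, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(rel.sample_ids, (d + d.T) / 2.0)


def pcoa(d: DistanceMatrix, correction: str | None = None) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Negative eigenvalues (from non-Euclidean dissimilarities) are reported
    in the spectrum but their axes are dropped; ``correction="cailliez"``
    adds the Cailliez constant to off-diagonal distances first.
    """
    dm = d.values
    if correction == "cailliez":
        dm = _cailliez(dm)
    elif correction is not None:
        raise DataError(f"unknown correction {correction!r}")
    n = dm.shape[0]
    a = -0.5 * dm ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval[np.abs(eigval) < 1e-10] = 0.0
    pos = eigval > 0
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    if coords.shape[1] == 0:
        coords = np.zeros((n, 1))
        prop = np.zeros(1)
    frame = pd.DataFrame(
        coords, index=d.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    frame.index.name = "sample_id"
    return OrdinationResult(frame, eigval, prop)


def _cailliez(dm: np.ndarray) -> np.ndarray:
    n = dm.shape[0]
    zero = np.zeros((n, n))
    eye = np.eye(n)
    centering = eye - np.ones((n, n)) / n
    d1 = centering @ (-0.5 * dm ** 2) @ centering
    d2 = centering @ (-0.5 * dm) @ centering
    block = np.block([[zero, 2 * d1], [-eye, -4 * d2]])
    c = float(np.max(np.real(np.linalg.eigvals(block))))
    if c <= 0:
        return dm
    out = dm + c
    np.fill_diagonal(out, 0.0)
    return out


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo_F, R2) from squared distances for one labeling."""
    n = d2.shape[0]
    groups = pd.unique(labels)
    k = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size >= 2:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    d: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    factor: str = "group",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (distance-based pseudo-F, permutation p-value).

    SS_total = sum_{i<j} d_ij^2 / n; SS_within analogously per group;
    pseudo-F = (SS_b/(k-1)) / (SS_w/(n-k)).  p = (1 + #{permuted F >=
    observed}) / (1 + n_permutations) under seeded label shuffling, or the
    exact proportion over every distinct labeling when ``exhaustive``.
    """
    lab = np.asarray(pd.Series(labels).astype(str))
    if lab.size != len(d.sample_ids):
        raise DataError("labels length does not match distance matrix")
    groups, counts = np.unique(lab, return_counts=True)
    if len(groups) < 2:
        raise DataError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise DataError("every group needs at least two members")
    d2 = d.values ** 2
    f_obs, r2 = _permanova_stats(d2, lab)

    if exhaustive:
        perms = set(itertools.permutations(lab))
        hits = sum(1 for p in perms if _permanova_stats(d2, np.array(p))[0] >= f_obs - 1e-12)
        p_value = hits / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        work = lab.copy()
        for _ in range(n_permutations):
            rng.shuffle(work)
            if _permanova_stats(d2, work)[0] >= f_obs - 1e-12:
                hits += 1
        p_value = (1 + hits) / (1 + n_permutations)
        n_used = n_permutations
    return PermanovaResult(
        factor=factor, pseudo_F=float(f_obs), R_squared=float(r2),
        p_value=float(p_value), n_permutations=n_used,
        detail={"k": len(groups), "n": int(lab.size), "exhaustive": exhaustive},
    )


def extract_tight_clusters(
    ordination: OrdinationResult,
    k_neighbors: int = 5,
    density_quantile: float = 0.6,
    linking_radius_quantile: float = 0.25,
    n_axes: int = 2,
    site: str = "",
) -> TightCluster:
    """Densest connected sample set in the leading ordination axes.

    Each sample is scored by its mean distance to its ``k_neighbors``
    nearest neighbors; samples below the ``density_quantile`` of that score
    are kept; kept samples are linked when closer than the
    ``linking_radius_quantile`` of kept pairwise distances and the largest
    connected component is returned (ties broken by smallest sample id).
    Deterministic given its parameters, which are logged with the result.
    """
    for name, v in [("density_quantile", density_quantile),
                    ("linking_radius_quantile", linking_radius_quantile)]:
        if not 0 < v < 1:
            raise DataError(f"{name} must lie in (0, 1)")
    coords = ordination.coordinates.to_numpy()
    if coords.shape[1] < 2:
        raise DataError("ordination must retain at least 2 axes")
    x = coords[:, : min(n_axes, coords.shape[1])]
    ids = ordination.sample_ids
    n = len(ids)
    k = min(k_neighbors, n - 1)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    knn_score = np.sort(dist, axis=1)[:, 1 : k + 1].mean(axis=1)
    # "higher" interpolation keeps the cutoffs attained data values, so the
    # quantile -> 1 limit degenerates to keeping every sample
    cutoff = np.quantile(knn_score, density_quantile, method="higher")
    kept = np.flatnonzero(knn_score <= cutoff)
    sub = dist[np.ix_(kept, kept)]
    if kept.size < 2:
        members = [ids[i] for i in kept]
    else:
        pair = squareform(sub, checks=False)
        radius = (np.quantile(pair, linking_radius_quantile, method="higher")
                  if pair.size else 0.0)
        adj = csr_matrix(sub <= radius)
        n_comp, comp = connected_components(adj, directed=False)
        sizes = np.bincount(comp)
        best = min(
            np.flatnonzero(sizes == sizes.max()),
            key=lambda c: min(ids[kept[i]] for i in np.flatnonzero(comp == c)),
        )
        members = sorted(ids[kept[i]] for i in np.flatnonzero(comp == best))
    params = {
        "k_neighbors": k_neighbors, "density_quantile": density_quantile,
        "linking_radius_quantile": linking_radius_quantile, "n_axes": n_axes,
    }
    logger.info("tight cluster (%s): %d members, params=%s", site, len(members), params)
    return TightCluster(site=site, members=members, params=params)
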