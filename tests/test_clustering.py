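"""Ward linkage, silhouette selection, bootstrap support, enrichment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import commstate as cs
from commstate.core import DataError
from conftest import geometry_table, rel_from_array


def brute_force_ward(points):
    """Greedy Ward oracle on raw points: at each step merge the pair whose
    within-cluster SSE increase is smallest, computed from scratch.

    Returns linkage-style rows (id_a, id_b, height) with the scipy height
    convention height = sqrt(2 * delta_SSE)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    clusters = {i: [i] for i in range(n)}
    rows = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                merged = clusters[a] + clusters[b]
                delta = (_sse(pts[merged]) - _sse(pts[clusters[a]])
                         - _sse(pts[clusters[b]]))
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, a, b)
        delta, a, b = best
        rows.append((a, b, np.sqrt(max(2 * delta, 0.0))))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(rows)


def _sse(x):
    return float(((x - x.mean(axis=0)) ** 2).sum())


class TestWardCluster:
    def test_toy_merge_order(self):
        dend = cs.ward_cluster(geometry_table([0.0, 1.0, 10.0, 11.0],
                                              ids=list("abcd")))
        assert dend.merges[0].tolist() == [0, 1]
        assert dend.merges[1].tolist() == [2, 3]
        assert dend.heights[0] == pytest.approx(1.0)

    def test_identical_samples_merge_first_at_zero(self):
        dend = cs.ward_cluster(geometry_table([[5.0, 1.0], [0.0, 0.0],
                                               [5.0, 1.0]]))
        assert dend.merges[0].tolist() == [0, 2]
        assert dend.heights[0] == 0.0

    def test_heights_non_decreasing_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            rel = rel_from_array(rng.dirichlet(np.ones(4), size=5))
            dend = cs.ward_cluster(rel)
            assert np.all(np.diff(dend.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_sequence_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        pts = rng.normal(size=(n, 3))
        mine = cs.ward_cluster(geometry_table(pts)).linkage
        oracle = brute_force_ward(pts)
        np.testing.assert_array_equal(mine[:, :2], oracle[:, :2])
        np.testing.assert_allclose(mine[:, 2], oracle[:, 2], atol=1e-9)

    def test_matches_scipy_linkage(self):
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 4))
        mine = cs.ward_cluster(geometry_table(x)).linkage
        ref = linkage(x, method="ward")
        np.testing.assert_allclose(mine[:, :3], ref[:, :3], atol=1e-8)

    def test_permutation_equivariant_partitions(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 3))
        ids = [f"s{i}" for i in range(12)]
        perm = rng.permutation(12)
        lab1 = cs.cut_dendrogram(cs.ward_cluster(geometry_table(x, ids)), 3)
        lab2 = cs.cut_dendrogram(
            cs.ward_cluster(geometry_table(x[perm], [ids[i] for i in perm])), 3)
        joined = pd.concat([lab1.rename("a"), lab2.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_unknown_distance_kind_rejected(self):
        with pytest.raises(DataError):
            cs.ward_cluster(geometry_table([[0.0], [1.0]]), "cosine")

    def test_correlation_distance_supported(self):
        rng = np.random.default_rng(3)
        rel = rel_from_array(rng.dirichlet(np.ones(5), size=8))
        dend = cs.ward_cluster(rel, "correlation")
        assert dend.n_leaves == 8


class TestCutAndSelectK:
    def test_cut_consistency_extremes(self):
        rng = np.random.default_rng(4)
        rel = rel_from_array(rng.dirichlet(np.ones(4), size=7))
        dend = cs.ward_cluster(rel)
        assert cs.cut_dendrogram(dend, 1).nunique() == 1
        assert cs.cut_dendrogram(dend, 7).nunique() == 7

    def test_toy_silhouette_hand_value_and_k_choice(self):
        # clusters {0,1} vs {10,11}: s = ((10.5-1)/10.5 + (9.5-1)/9.5)/2
        rel = geometry_table([0.0, 1.0, 10.0, 11.0], ids=list("abcd"))
        dend = cs.ward_cluster(rel)
        sol = cs.select_k(dend, rel, k_min=2, k_max=3)
        assert sol.k == 2
        hand = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert sol.silhouette_by_k[2] == pytest.approx(hand, abs=1e-9)
        assert sol.silhouette_by_k[2] == pytest.approx(0.900, abs=5e-4)

    def test_recovers_planted_archetype_count(self):
        spec = cs.reseed(cs.study_like_spec(), 3)
        table, tax, meta, truth = cs.simulate_cohort(spec)
        rel = cs.to_relative(cs.aggregate_by_rank(table, tax, "genus"))
        ids = sorted(meta.stratum("nasopharyngeal", "winter"))
        sub = rel.subset(ids)
        sol = cs.select_k(cs.ward_cluster(sub), sub, 2, 8,
                          stratum=("nasopharyngeal", "winter"))
        planted = truth.archetype_of().loc[ids]
        assert sol.k == planted.nunique()
        assert adjusted_rand_score(planted, sol.labels.loc[ids]) > 0.9

    def test_k_override_one_records_undefined_silhouette(self):
        rel = geometry_table([0.0, 1.0, 10.0, 11.0])
        dend = cs.ward_cluster(rel)
        sol = cs.select_k(dend, rel, 2, 3, k_override=1)
        assert sol.k == 1
        assert sol.labels.nunique() == 1

    def test_k_max_at_or_above_n_rejected(self):
        rel = geometry_table([0.0, 1.0, 2.0])
        dend = cs.ward_cluster(rel)
        with pytest.raises(DataError, match="k_max"):
            cs.select_k(dend, rel, 2, 3)

    def test_cluster_names_ordered_by_size(self):
        rel = geometry_table([0.0, 0.1, 0.2, 10.0], ids=list("abcd"))
        dend = cs.ward_cluster(rel)
        sol = cs.select_k(dend, rel, 2, 3, k_override=2)
        assert sol.labels.loc["a"] == "C1"  # bigger cluster first
        assert sol.labels.loc["d"] == "C2"


class TestBootstrapSupport:
    def test_separated_blobs_have_full_top_split_support(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 0.05, size=(6, 8)),
                       rng.normal(5, 0.05, size=(6, 8))])
        rel = geometry_table(x)
        dend = cs.ward_cluster(rel)
        support = cs.bootstrap_support(rel, dend, n_boot=30, seed=0)
        # the two blob nodes are the last merges before the root
        sets = dend.node_leaf_sets()
        blob_a = frozenset(f"s{i}" for i in range(6))
        blob_b = frozenset(f"s{i}" for i in range(6, 12))
        for idx, s in enumerate(sets):
            if s in (blob_a, blob_b):
                assert support[idx] >= 0.95

    def test_zero_replicates_flagged_absent(self):
        rel = geometry_table([0.0, 1.0, 2.0])
        dend = cs.ward_cluster(rel)
        assert cs.bootstrap_support(rel, dend, n_boot=0) is None

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        rel = rel_from_array(rng.dirichlet(np.ones(6), size=8))
        dend = cs.ward_cluster(rel)
        s1 = cs.bootstrap_support(rel, dend, n_boot=10, seed=42)
        s2 = cs.bootstrap_support(rel, dend, n_boot=10, seed=42)
        assert s1 == s2


class TestEnrichClusters:
    def test_planted_dominant_genus_flagged_enriched(self):
        spec = cs.reseed(cs.study_like_spec(), 8)
        table, tax, meta, truth = cs.simulate_cohort(spec)
        rel = cs.to_relative(cs.aggregate_by_rank(table, tax, "genus"))
        ids = sorted(meta.stratum("nasopharyngeal", "autumn"))
        sub = rel.subset(ids)
        sol = cs.select_k(cs.ward_cluster(sub), sub, 2, 8,
                          stratum=("nasopharyngeal", "autumn"))
        enr = cs.enrich_clusters(sub, sol)
        planted = truth.archetype_of().loc[ids]
        # the cluster aligned with the Streptococcus state must flag it
        strep_cluster = sol.labels.loc[planted == "Streptococcus"].mode()[0]
        row = enr[(enr["cluster"] == strep_cluster)
                  & (enr["genus"] == "Streptococcus")].iloc[0]
        assert bool(row["enriched"])
        assert cs.UNASSIGNED not in set(enr["genus"])

    def test_constant_genus_marked_untestable(self):
        frame = pd.DataFrame({
            "g1": [0.5, 0.6, 0.4, 0.5],
            "g2": [0.2, 0.2, 0.2, 0.2],  # zero variance everywhere
        })
        frame["g3"] = 1 - frame.sum(axis=1)
        rel = rel_from_array(frame.to_numpy(), ids=list("abcd"))
        rel.fractions.columns = ["g1", "g2", "g3"]
        labels = pd.Series(["C1", "C1", "C2", "C2"], index=list("abcd"))
        sol = cs.ClusterSolution(("oral", "autumn"), labels, 2, {}, None)
        enr = cs.enrich_clusters(rel, sol)
        g2 = enr[enr["genus"] == "g2"]
        assert g2["untestable"].all()

    def test_size_one_cluster_untestable_not_dropped(self):
        rng = np.random.default_rng(9)
        rel = rel_from_array(rng.dirichlet(np.ones(3), size=5), ids=list("abcde"))
        labels = pd.Series(["C1"] * 4 + ["C2"], index=list("abcde"))
        sol = cs.ClusterSolution(("oral", "autumn"), labels, 2, {}, None)
        enr = cs.enrich_clusters(rel, sol)
        assert enr[enr["cluster"] == "C2"]["untestable"].all()
        assert len(enr[enr["cluster"] == "C2"]) == 3

    def test_label_shuffle_controls_false_enrichment(self):
        rng = np.random.default_rng(10)
        flags = []
        for seed in range(15):
            rng2 = np.random.default_rng(seed)
            rel = rel_from_array(rng2.dirichlet(np.ones(8), size=40))
            labels = pd.Series(rng2.permutation(["C1"] * 20 + ["C2"] * 20),
                               index=rel.sample_ids)
            sol = cs.ClusterSolution(("oral", "autumn"), labels, 2, {}, None)
            enr = cs.enrich_clusters(rel, sol)
            flags.append(enr["enriched"].mean())
        assert np.mean(flags) < 0.05  # BH keeps the null flag rate at bay


class TestDendrogramExport:
    def test_newick_round_trips_through_reference_parser(self):
        Phylo = pytest.importorskip("Bio.Phylo")
        import io
        rng = np.random.default_rng(11)
        rel = rel_from_array(rng.dirichlet(np.ones(4), size=6),
                             ids=[f"leaf{i}" for i in range(6)])
        dend = cs.ward_cluster(rel)
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(rel.sample_ids)
        depths = tree.depths()
        root_height = max(depths.values())
        assert root_height == pytest.approx(dend.heights[-1], rel=1e-6)

    def test_family_naming_links_seasons_by_dominant_genus(self):
        spec = cs.reseed(cs.study_like_spec(), 12)
        table, tax, meta, _ = cs.simulate_cohort(spec)
        rel = cs.to_relative(cs.aggregate_by_rank(table, tax, "genus"))
        sols, enrs = [], []
        for season in ("winter", "spring"):
            ids = sorted(meta.stratum("oral", season))
            sub = rel.subset(ids)
            sol = cs.select_k(cs.ward_cluster(sub), sub, 2, 8,
                              stratum=("oral", season))
            sols.append(sol)
            enrs.append(cs.enrich_clusters(sub, sol))
        fams = cs.clustering.assign_family_names(sols, enrs)
        winter_fams = {v for k, v in fams.items() if k[1] == "winter"}
        spring_fams = {v for k, v in fams.items() if k[1] == "spring"}
        assert "Streptococcus-type" in winter_fams & spring_fams
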