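"""Transition tables, Fisher exact testing, and network construction."""

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import commstate as cs
from commstate.core import DataError
from conftest import rel_from_array


def exact_fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher p by exact rational enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(total)


def _solution(site, season, mapping):
    sol = cs.ClusterSolution.__new__(cs.ClusterSolution)
    sol.stratum = (site, season)
    sol.labels = pd.Series(mapping)
    sol.k = sol.labels.nunique()
    sol.silhouette_by_k = {}
    sol.dendrogram = None
    sol.distance_kind = "euclidean"
    sol.bootstrap_support = None
    return sol


def _metadata_for(samples):
    """samples: list of (sample_id, subject_id, site, season)."""
    frame = pd.DataFrame(
        [(sid, subj, site, season, 8, "female", "3rd grade")
         for sid, subj, site, season in samples],
        columns=["sample_id", "subject_id", "site", "season", "age", "sex",
                 "grade"]).set_index("sample_id")
    return cs.SampleMetadata(frame)


class TestFisherExact:
    def test_hand_example_enrichment_table(self):
        odds, p = cs.fisher_exact_2x2([[3, 1], [1, 3]])
        assert odds == pytest.approx(9.0)
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_balanced_table_null(self):
        odds, p = cs.fisher_exact_2x2([[2, 2], [2, 2]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_haldane_anscombe_on_zero_cells(self):
        odds, _ = cs.fisher_exact_2x2([[5, 0], [0, 5]])
        assert odds == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_rational_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 10, size=4)
            _, p = cs.fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(exact_fisher_oracle(a, b, c, d), abs=1e-10)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 15, size=(2, 2))
            _, p_mine = cs.fisher_exact_2x2(t)
            assert p_mine == pytest.approx(fisher_exact(t)[1], abs=1e-10)

    def test_conditional_mle_option(self):
        res = cs.transitions.conditional_mle_odds_ratio([[6, 1], [2, 7]])
        assert res > 1


class TestBuildTransitionTable:
    def test_direct_count_example(self):
        sol_a = _solution("oral", "autumn", {"a_au": "A", "b_au": "A", "c_au": "B"})
        sol_w = _solution("oral", "winter", {"a_wi": "A", "b_wi": "B", "c_wi": "B"})
        meta = _metadata_for([
            ("a_au", "a", "oral", "autumn"), ("b_au", "b", "oral", "autumn"),
            ("c_au", "c", "oral", "autumn"), ("a_wi", "a", "oral", "winter"),
            ("b_wi", "b", "oral", "winter"), ("c_wi", "c", "oral", "winter")])
        tt = cs.build_transition_table(sol_a, sol_w, meta)
        np.testing.assert_array_equal(tt.matrix.to_numpy(), [[1, 1], [0, 1]])
        assert tt.n_subjects == 3
        assert tt.attrition["paired"] == 3

    def test_disjoint_subjects_give_empty_table_full_attrition(self):
        sol_a = _solution("oral", "autumn", {"a_au": "A"})
        sol_w = _solution("oral", "winter", {"b_wi": "A"})
        meta = _metadata_for([("a_au", "a", "oral", "autumn"),
                              ("b_wi", "b", "oral", "winter")])
        tt = cs.build_transition_table(sol_a, sol_w, meta)
        assert tt.n_subjects == 0
        assert tt.attrition == {"only_first_season": 1,
                                "only_second_season": 1, "paired": 0}

    def test_non_adjacent_seasons_rejected(self):
        sol_a = _solution("oral", "autumn", {"a_au": "A"})
        sol_s = _solution("oral", "spring", {"a_sp": "A"})
        meta = _metadata_for([("a_au", "a", "oral", "autumn"),
                              ("a_sp", "a", "oral", "spring")])
        with pytest.raises(DataError, match="adjacent"):
            cs.build_transition_table(sol_a, sol_s, meta)

    def test_empirical_matrix_recovers_planted_markov_rows(self):
        spec = cs.planted_transition_spec(seed=0, n_subjects=800)
        _, _, meta, truth = cs.simulate_cohort(spec)
        arch = truth.archetype_of()
        sols = {}
        for season in ("autumn", "winter"):
            ids = sorted(meta.stratum("nasopharyngeal", season))
            sols[season] = _solution("nasopharyngeal", season,
                                     arch.loc[ids].to_dict())
        tt = cs.build_transition_table(sols["autumn"], sols["winter"], meta)
        names = spec.archetype_names("nasopharyngeal")
        planted = np.asarray(spec.transition_matrices["nasopharyngeal"][0])
        emp = tt.matrix.loc[names, names].to_numpy().astype(float)
        emp_rows = emp / emp.sum(axis=1, keepdims=True)
        row_n = emp.sum(axis=1)
        se = np.sqrt(planted * (1 - planted) / row_n[:, None])
        assert np.all(np.abs(emp_rows - planted) < 4 * se + 0.01)


class TestTestTransitions:
    def test_margins_conserved(self):
        sol_a = _solution("oral", "autumn",
                          {f"s{i}_a": c for i, c in enumerate("AABBB")})
        sol_w = _solution("oral", "winter",
                          {f"s{i}_w": c for i, c in enumerate("ABABB")})
        meta = _metadata_for(
            [(f"s{i}_a", f"p{i}", "oral", "autumn") for i in range(5)]
            + [(f"s{i}_w", f"p{i}", "oral", "winter") for i in range(5)])
        tt = cs.build_transition_table(sol_a, sol_w, meta)
        res = cs.test_transitions(tt)
        for fc in tt.matrix.index:
            row_total = int(tt.matrix.loc[fc].sum())
            assert res[res["from_cluster"] == fc]["count"].sum() == row_total
        # every 2x2 is margin-consistent with the table total
        for _, r in res.iterrows():
            assert r["n11"] + r["n12"] + r["n21"] + r["n22"] == tt.n_subjects

    def test_bh_family_matches_classical_step_up(self):
        spec = cs.planted_transition_spec(seed=4)
        _, _, meta, truth = cs.simulate_cohort(spec)
        arch = truth.archetype_of()
        sols = {s: _solution("nasopharyngeal", s,
                             arch.loc[sorted(meta.stratum("nasopharyngeal", s))].to_dict())
                for s in ("autumn", "winter")}
        res = cs.test_transitions(
            cs.build_transition_table(sols["autumn"], sols["winter"], meta))
        ok = res[~res["untestable"]]
        p = ok["fisher_p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        below = [i for i, idx in enumerate(order, 1) if p[idx] <= 0.05 * i / m]
        k = max(below) if below else 0
        classical = np.zeros(m, bool)
        classical[order[:k]] = True
        np.testing.assert_array_equal(ok["significant"].to_numpy(), classical)

    def test_planted_enriched_transition_detected(self):
        spec = cs.planted_transition_spec(seed=1)
        _, _, meta, truth = cs.simulate_cohort(spec)
        arch = truth.archetype_of()
        sols = {s: _solution("nasopharyngeal", s,
                             arch.loc[sorted(meta.stratum("nasopharyngeal", s))].to_dict())
                for s in ("autumn", "winter")}
        res = cs.test_transitions(
            cs.build_transition_table(sols["autumn"], sols["winter"], meta))
        row = res[(res["from_cluster"] == "Streptococcus")
                  & (res["to_cluster"] == "Moraxella")].iloc[0]
        assert row["significant"] and row["odds_ratio"] > 1


class TestTransitionNetwork:
    def test_direct_construction(self):
        matrix = pd.DataFrame([[1, 1], [0, 1]], index=["A", "B"],
                              columns=["A", "B"])
        tt = cs.TransitionTable("oral", ("autumn", "winter"), matrix,
                                ["a", "b", "c"])
        g = cs.build_transition_network(tt)
        assert sorted(g.nodes) == ["A", "B"]
        assert g.number_of_edges() == 3
        assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))

    def test_empty_table_empty_graph(self):
        matrix = pd.DataFrame(np.zeros((0, 0), dtype=int))
        tt = cs.TransitionTable("oral", ("autumn", "winter"), matrix, [])
        g = cs.build_transition_network(tt)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_significance_flag_passthrough(self):
        matrix = pd.DataFrame([[4, 0], [0, 4]], index=["A", "B"],
                              columns=["A", "B"])
        tt = cs.TransitionTable("oral", ("autumn", "winter"), matrix,
                                [f"p{i}" for i in range(8)])
        res = cs.test_transitions(tt)
        g = cs.build_transition_network(tt, res)
        flagged = {(u, v): d["significant"] for u, v, d in g.edges(data=True)}
        expect = {(r["from_cluster"], r["to_cluster"]): bool(r["significant"])
                  for _, r in res.iterrows() if r["count"] > 0}
        assert flagged == expect

    def test_gexf_and_graphml_exports_parse(self, tmp_path):
        matrix = pd.DataFrame([[2, 1], [1, 2]], index=["A", "B"],
                              columns=["A", "B"])
        tt = cs.TransitionTable("oral", ("autumn", "winter"), matrix,
                                [f"p{i}" for i in range(6)])
        g = cs.build_transition_network(tt)
        cs.transitions.write_network(g, gexf_path=tmp_path / "net.gexf",
                                     graphml_path=tmp_path / "net.graphml")
        back = nx.read_gexf(tmp_path / "net.gexf")
        assert sorted(back.nodes) == ["A", "B"]
        back2 = nx.read_graphml(tmp_path / "net.graphml")
        assert back2.number_of_edges() == g.number_of_edges()


class TestTaxonAssociations:
    def test_proportional_genera_positive_edge(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(4), size=30)
        # g1 and g2 move together: split one component in fixed ratio
        frame = np.column_stack([0.6 * base[:, 0], 0.4 * base[:, 0],
                                 base[:, 1], base[:, 2], base[:, 3]])
        rel = rel_from_array(frame)
        rel.fractions.columns = ["g1", "g2", "g3", "g4", "g5"]
        edges, g, hub = cs.taxon_association_network(rel)
        row = edges[(edges["genus_a"] == "g1") & (edges["genus_b"] == "g2")].iloc[0]
        assert row["rho"] == pytest.approx(1.0, abs=1e-9)
        assert row["sign"] == "positive" and row["kept"]

    def test_two_part_composition_forced_negative(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.1, 0.9, size=20)
        rel = rel_from_array(np.column_stack([a, 1 - a]))
        rel.fractions.columns = ["g1", "g2"]
        edges, _, _ = cs.taxon_association_network(rel)
        row = edges.iloc[0]
        # CLR of a 2-part composition is antisymmetric: rho = -1 exactly
        assert row["rho"] == pytest.approx(-1.0, abs=1e-9)
        assert row["sign"] == "negative"

    def test_independent_genera_keep_few_edges(self):
        kept = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rel = rel_from_array(rng.dirichlet(np.ones(10) * 5, size=60))
            edges, _, _ = cs.taxon_association_network(rel)
            kept.append(edges["kept"].mean())
        assert np.mean(kept) < 0.1

    def test_refuses_unstable_small_sample(self):
        rng = np.random.default_rng(2)
        rel = rel_from_array(rng.dirichlet(np.ones(3), size=5))
        with pytest.raises(DataError, match="unstable"):
            cs.taxon_association_network(rel)

    def test_hub_is_maximum_degree_genus(self):
        rng = np.random.default_rng(3)
        base = rng.dirichlet(np.ones(3), size=40)
        # g1 proportional to both g2 and g3 -> degree-2 hub
        frame = np.column_stack([
            0.5 * base[:, 0], 0.3 * base[:, 0], 0.2 * base[:, 0],
            base[:, 1], base[:, 2]])
        rel = rel_from_array(frame)
        rel.fractions.columns = ["g1", "g2", "g3", "g4", "g5"]
        edges, g, hub = cs.taxon_association_network(rel)
        assert hub in {"g1", "g2", "g3"}
        assert g.degree(hub) == max(dict(g.degree).values())


def test_clr_transform_centers_rows():
    rng = np.random.default_rng(4)
    rel = rel_from_array(rng.dirichlet(np.ones(5), size=8))
    clr = cs.clr_transform(rel)
    np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)
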