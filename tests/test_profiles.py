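"""Profiles, clustering, ontology closure, enrichment, and the set sampler."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ovitome.profiles import (
    ClusterSet,
    MGSAParams,
    TermEnrichment,
    build_profiles,
    hierarchical_cluster,
    hypergeom_enrichment,
    mgsa,
    mgsa_exact,
    propagate_annotations,
    report_clusters,
)

LAYOUT = {
    "standard": {7: "s7", 11: "s11", 14: "s14", 21: "s21"},
    "delayed": {7: "d7", 11: "d11", 14: "d14", 21: "d21"},
}


def expr_frame(rows: dict):
    return pd.DataFrame(rows, index=["s7", "s11", "s14", "s21",
                                     "d7", "d11", "d14", "d21"]).T


class TestBuildProfiles:
    def test_hand_computed_zscores(self):
        m = expr_frame({"g": [1, 2, 3, 4, 10, 10, 10, 10]})
        ps = build_profiles(m, ["g"], LAYOUT)
        v = ps.values.loc["g"].to_numpy()
        expected = np.array([-1.161895, -0.387298, 0.387298, 1.161895])
        assert np.allclose(v[:4], expected, atol=1e-5)
        assert np.allclose(v[4:], 0.0)  # constant block -> zeros
        assert ps.degenerate_blocks == {"g": ["delayed"]}

    def test_vector_length_is_eight(self):
        m = expr_frame({"g": [1, 5, 2, 7, 3, 3, 9, 1]})
        ps = build_profiles(m, ["g"], LAYOUT)
        assert ps.values.shape == (1, 8)

    def test_blocks_standardized_independently(self):
        rng = np.random.default_rng(0)
        m = expr_frame({f"g{i}": rng.gamma(2, 5, 8) for i in range(20)})
        ps = build_profiles(m, list(m.index), LAYOUT)
        for half in (ps.values.iloc[:, :4], ps.values.iloc[:, 4:]):
            assert np.allclose(half.mean(axis=1), 0.0, atol=1e-9)
            assert np.allclose(half.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_missing_lane_rejected(self):
        m = expr_frame({"g": [1, 2, 3, 4, 5, 6, 7, 8]}).drop(columns=["d21"])
        with pytest.raises(ValueError):
            build_profiles(m, ["g"], LAYOUT)


class TestHierarchicalCluster:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.05, size=(15, 8))
        b = rng.normal(3, 0.05, size=(15, 8))
        profiles = pd.DataFrame(np.vstack([a, b]),
                                index=[f"g{i}" for i in range(30)])
        cs = hierarchical_cluster(profiles, k=2)
        labels_a = {cs.assignments[f"g{i}"] for i in range(15)}
        labels_b = {cs.assignments[f"g{i}"] for i in range(15, 30)}
        assert len(labels_a) == 1 and len(labels_b) == 1
        assert labels_a != labels_b

    def test_k_equals_n_gives_singletons(self):
        profiles = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 8)),
                                index=list("abcdef"))
        cs = hierarchical_cluster(profiles, k=6)
        assert len(set(cs.assignments.values())) == 6

    def test_k_out_of_range_rejected(self):
        profiles = pd.DataFrame(np.zeros((3, 8)))
        with pytest.raises(ValueError):
            hierarchical_cluster(profiles, k=4)

    def test_matches_brute_force_average_linkage(self):
        """Partition at k equals a naive O(n^3) agglomeration."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 8))
        profiles = pd.DataFrame(X, index=[f"g{i}" for i in range(20)])

        def naive_partition(k):
            clusters = [[i] for i in range(len(X))]
            d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
            while len(clusters) > k:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                        if best is None or dist < best[0]:
                            best = (dist, i, j)
                _, i, j = best
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
            return {frozenset(c) for c in clusters}

        for k in (2, 4, 7):
            cs = hierarchical_cluster(profiles, k=k)
            groups: dict[int, set] = {}
            for gi, label in enumerate(cs.assignments[f"g{i}"] for i in range(20)):
                groups.setdefault(label, set()).add(gi)
            assert {frozenset(g) for g in groups.values()} == naive_partition(k)


def test_obo_subset_roundtrip(tmp_path):
    """An id/name/is_a OBO subset loads into a child -> parent digraph."""
    from ovitome.profiles import load_ontology

    obo = (
        "format-version: 1.2\n"
        "ontology: test\n\n"
        "[Term]\nid: GO:0000001\nname: child\nis_a: GO:0000002 ! parent\n\n"
        "[Term]\nid: GO:0000002\nname: parent\nis_a: GO:0000003 ! root\n\n"
        "[Term]\nid: GO:0000003\nname: root\n"
    )
    path = tmp_path / "mini.obo"
    path.write_text(obo)
    dag = load_ontology(path)
    closed = propagate_annotations(dag, {"g": {"GO:0000001"}})
    assert closed["g"] == {"GO:0000001", "GO:0000002", "GO:0000003"}


class TestPropagateAnnotations:
    def chain(self):
        dag = nx.DiGraph()
        dag.add_edges_from([("child", "parent"), ("parent", "root")])
        return dag

    def test_chain_closure(self):
        closed = propagate_annotations(self.chain(), {"g": {"child"}})
        assert closed["g"] == {"child", "parent", "root"}

    def test_root_annotation_unchanged(self):
        closed = propagate_annotations(self.chain(), {"g": {"root"}})
        assert closed["g"] == {"root"}

    def test_idempotent(self):
        dag = self.chain()
        once = propagate_annotations(dag, {"g": {"child"}})
        twice = propagate_annotations(dag, once)
        assert once == twice

    def test_cycle_rejected(self):
        dag = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            propagate_annotations(dag, {"g": {"a"}})


class TestHypergeomEnrichment:
    def test_whole_population_term_not_enriched(self):
        population = {f"g{i}" for i in range(20)}
        ann = {g: {"T"} for g in population}
        res = hypergeom_enrichment(set(list(population)[:5]), population, ann)
        assert res[0].p_hypergeom == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        population = {f"g{i}" for i in range(100)}
        term_genes = {f"g{i}" for i in range(5)}
        ann = {g: ({"T"} if g in term_genes else set()) for g in population}
        res = hypergeom_enrichment(term_genes, population, ann)
        assert res[0].p_hypergeom == pytest.approx(1 / comb(100, 5), rel=1e-9)

    def test_study_equals_population_all_one(self):
        population = {f"g{i}" for i in range(10)}
        ann = {g: {"A"} if int(g[1:]) < 4 else {"B"} for g in population}
        res = hypergeom_enrichment(population, population, ann)
        assert all(r.p_hypergeom == pytest.approx(1.0) for r in res)

    def test_matches_direct_enumeration_small_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            N = int(rng.integers(5, 30))
            population = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term_genes = set(rng.choice(sorted(population), K, replace=False))
            study = set(rng.choice(sorted(population), n, replace=False))
            ann = {g: ({"T"} if g in term_genes else set()) for g in population}
            res = hypergeom_enrichment(study, population, ann)
            k = len(study & term_genes)
            want = sum(
                comb(K, i) * comb(N - K, n - i)
                for i in range(k, min(K, n) + 1)
            ) / comb(N, n)
            assert res[0].p_hypergeom == pytest.approx(want, rel=1e-9)

    def test_study_outside_population_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"x"}, {"y"}, {})


class TestMGSA:
    def make_world(self, rng, n_genes=60, n_terms=8, term_size=10):
        genes = [f"g{i}" for i in range(n_genes)]
        ann = {g: set() for g in genes}
        for t in range(n_terms):
            for g in rng.choice(genes, term_size, replace=False):
                ann[g].add(f"T{t}")
        return genes, ann

    def test_sampler_matches_exact_enumeration(self):
        rng = np.random.default_rng(21)
        genes, ann = self.make_world(rng)
        active_genes = {g for g in genes if "T3" in ann[g]}
        flags = {g: (g in active_genes) != (rng.random() < 0.05) for g in genes}
        params = MGSAParams(iterations=100_000, seed=3)
        exact = mgsa_exact(flags, ann, params)
        sampled = mgsa(flags, ann, params)
        for t in exact:
            assert abs(exact[t] - sampled[t]) < 0.03

    def test_empty_study_marginals_near_prior(self):
        rng = np.random.default_rng(22)
        genes, ann = self.make_world(rng, n_terms=6)
        flags = {g: False for g in genes}
        params = MGSAParams(iterations=60_000, seed=4)
        exact = mgsa_exact(flags, ann, params)
        sampled = mgsa(flags, ann, params)
        prior = 1.0 / 6
        for t in exact:
            assert exact[t] <= prior  # all-off data argues against activation
            assert abs(exact[t] - sampled[t]) < 0.03

    def test_identical_terms_get_equal_marginals(self):
        genes = [f"g{i}" for i in range(40)]
        members = set(genes[:10])
        ann = {g: ({"Ta", "Tb"} if g in members else set()) for g in genes}
        flags = {g: g in members for g in genes}
        out = mgsa(flags, ann, MGSAParams(iterations=100_000, seed=5))
        assert abs(out["Ta"] - out["Tb"]) < 0.05

    def test_no_terms_rejected(self):
        with pytest.raises(ValueError):
            mgsa({"g": True}, {"g": set()}, MGSAParams())

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            MGSAParams(alpha=0.0)


class TestReportClusters:
    def make_enrichment(self, term, study, marginal):
        return TermEnrichment(term, study, study + 5, mgsa_marginal=marginal)

    def test_top_three_by_annotated_count(self):
        cs = ClusterSet(assignments={"g": 1}, k=1, linkage=np.empty((0, 4)))
        terms = [self.make_enrichment(f"T{i}", count, 0.6)
                 for i, count in enumerate([3, 9, 5, 7, 4])]
        report = report_clusters(cs, {1: terms})
        assert [t.term_id for t in report[1]] == ["T1", "T3", "T2"]

    def test_below_marginal_cut_excluded(self):
        cs = ClusterSet(assignments={"g": 1}, k=1, linkage=np.empty((0, 4)))
        terms = [self.make_enrichment("T0", 5, 0.4)]
        assert report_clusters(cs, {1: terms})[1] == []

    def test_single_qualifying_term(self):
        cs = ClusterSet(assignments={"g": 1}, k=1, linkage=np.empty((0, 4)))
        terms = [self.make_enrichment("T0", 5, 0.9)]
        assert len(report_clusters(cs, {1: terms})[1]) == 1
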