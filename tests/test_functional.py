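import networkx as nx
import numpy as np
import pytest

from methconsist.functional import (
    AnnotationDAG,
    cross_dataset_edges,
    enrich,
    gene_similarity,
    geneset_similarity,
    make_toy_annotation,
    make_toy_network,
    null_similarity,
    term_similarity,
    topology,
)
from methconsist.consistency import overlap_significance

from _oracles import betweenness_oracle, clustering_oracle


@pytest.fixture
def chain_dag():
    """root <- A <- B with is-a weight 0.8."""
    dag = AnnotationDAG(
        parents={"A": [("root", 0.8)], "B": [("A", 0.8)]},
        gene2terms={"gA": {"A"}, "gB": {"B"}},
        roots={"root"},
    )
    dag.validate()
    return dag


@pytest.fixture
def fork_dag():
    """Two depth-1 siblings sharing only the root."""
    dag = AnnotationDAG(
        parents={"A": [("root", 0.8)], "B": [("root", 0.8)]},
        gene2terms={"gA": {"A"}, "gB": {"B"}},
        roots={"root"},
    )
    dag.validate()
    return dag


class TestTermSimilarity:
    def test_identity(self, chain_dag):
        assert term_similarity("A", "A", chain_dag) == 1.0

    def test_chain_hand_computation(self, chain_dag):
        # S_B = {B:1, A:.8, root:.64}; S_A = {A:1, root:.8}
        # shared {A, root}: (.8+1 + .64+.8) / (2.44 + 1.8) = 3.24/4.24
        got = term_similarity("A", "B", chain_dag)
        assert got == pytest.approx(3.24 / 4.24, abs=1e-9)

    def test_siblings_share_only_root(self, fork_dag):
        got = term_similarity("A", "B", fork_dag)
        assert got == pytest.approx(1.6 / 3.6, abs=1e-9)

    def test_symmetric_and_strict_identity(self):
        dag = make_toy_annotation([f"g{i}" for i in range(10)], seed=4)
        terms = sorted(dag.parents)[:8]
        for a in terms:
            for b in terms:
                sab = term_similarity(a, b, dag)
                assert sab == pytest.approx(term_similarity(b, a, dag), abs=1e-12)
                if a != b:
                    assert sab < 1.0  # weights < 1 forbid perfect similarity

    def test_unknown_term_rejected(self, chain_dag):
        with pytest.raises(KeyError):
            chain_dag.s_values("nope")

    def test_multi_parent_takes_best_path(self):
        # B has two routes to root; S(root) must be the max product
        dag = AnnotationDAG(
            parents={
                "A": [("root", 0.8)],
                "C": [("root", 0.6)],
                "B": [("A", 0.8), ("C", 0.6)],
            },
            gene2terms={},
            roots={"root"},
        )
        dag.validate()
        s = dag.s_values("B")
        assert s["root"] == pytest.approx(0.64)  # via A, not via C (0.36)


class TestGenesetSimilarity:
    def test_identical_sets(self):
        dag = make_toy_annotation([f"g{i}" for i in range(12)], seed=2)
        s = {"g0", "g3", "g5"}
        assert geneset_similarity(s, s, dag) == pytest.approx(1.0)

    def test_singletons_with_identical_terms(self, chain_dag):
        dag = AnnotationDAG(
            parents=dict(chain_dag.parents),
            gene2terms={"x": {"A", "B"}, "y": {"A", "B"}},
            roots={"root"},
        )
        assert geneset_similarity({"x"}, {"y"}, dag) == pytest.approx(1.0)

    def test_unannotated_set_is_nan(self, chain_dag):
        assert np.isnan(geneset_similarity({"zz"}, {"gA"}, chain_dag))

    def test_same_branch_beats_cross_branch(self):
        genes = [f"g{i}" for i in range(20)]
        branch = {g: (0 if i < 10 else 1) for i, g in enumerate(genes)}
        dag = make_toy_annotation(genes, branch_of=branch, seed=6)
        within = geneset_similarity(set(genes[:5]), set(genes[5:10]), dag)
        across = geneset_similarity(set(genes[:5]), set(genes[10:15]), dag)
        assert within > across


class TestNullSimilarity:
    def test_zero_draws_empty(self, chain_dag):
        out = null_similarity(chain_dag, {"gA", "gB"}, n_draws=0)
        assert out.samples.size == 0 and np.isnan(out.mean)

    def test_seeded_reproducibility(self):
        dag = make_toy_annotation([f"g{i}" for i in range(15)], seed=1)
        uni = set(dag.gene2terms)
        a = null_similarity(dag, uni, n_draws=25, seed=9)
        b = null_similarity(dag, uni, n_draws=25, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.quantiles == b.quantiles


class TestEnrich:
    def test_complete_overlap_enumeration(self):
        universe = {f"g{i}" for i in range(20)}
        ann = {g: {"term1"} if int(g[1:]) < 5 else {"other"} for g in universe}
        out = enrich({f"g{i}" for i in range(5)}, ann, universe).set_index("term")
        assert out.loc["term1", "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        ann = {g: {"term1"} if int(g[1:]) < 5 else {"other"} for g in universe}
        out = enrich({"g10", "g11"}, ann, universe).set_index("term")
        assert out.loc["term1", "p_value"] == pytest.approx(1.0)

    def test_ancestor_propagation(self, chain_dag):
        universe = {"gA", "gB"}
        out = enrich({"gB"}, chain_dag, universe).set_index("term")
        # gB is annotated only to leaf B, yet counts toward A and root
        assert out.loc["A", "K"] == 2   # gA directly, gB via propagation
        assert out.loc["root", "K"] == 2
        assert out.loc["B", "K"] == 1

    def test_agrees_with_overlap_significance(self):
        rng = np.random.default_rng(8)
        universe = {f"g{i}" for i in range(30)}
        members = set(rng.choice(sorted(universe), size=12, replace=False))
        ann = {g: ({"T"} if g in members else {"other"}) for g in universe}
        query = set(rng.choice(sorted(universe), size=10, replace=False))
        out = enrich(query, ann, universe).set_index("term")
        assert out.loc["T", "p_value"] == pytest.approx(
            overlap_significance(members, query, universe), rel=1e-12
        )

    def test_empty_universe_rejected(self, chain_dag):
        with pytest.raises(ValueError):
            enrich({"gA"}, chain_dag, set())


class TestTopology:
    def test_path_betweenness(self):
        g = nx.path_graph(["a", "b", "c"])
        out = topology(g)
        assert out.loc["b", "betweenness"] == 1.0
        assert out.loc["a", "betweenness"] == 0.0

    def test_triangle(self):
        g = nx.complete_graph(3)
        out = topology(g)
        assert (out["betweenness"] == 0).all()
        assert (out["transitivity"] == 1.0).all()

    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, 4 leaves
        out = topology(g)
        assert out.loc[0, "betweenness"] == 6.0  # C(4,2) pairs
        assert out.loc[0, "transitivity"] == 0.0

    def test_absent_genes_zeroed(self):
        g = nx.path_graph(["a", "b", "c"])
        out = topology(g, {"a", "zz"})
        assert (out.loc["zz"] == 0).all()

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                    seed=int(rng.integers(1 << 30)))
            adj = {v: set(g.neighbors(v)) for v in g.nodes}
            out = topology(g)
            bc = betweenness_oracle(adj)
            cc = clustering_oracle(adj)
            for v in g.nodes:
                assert out.loc[v, "betweenness"] == pytest.approx(bc[v], abs=1e-9)
                assert out.loc[v, "transitivity"] == pytest.approx(cc[v], abs=1e-9)


class TestCrossDatasetEdges:
    def test_disjoint_unconnected_sets(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        out = cross_dataset_edges(g, {"x": {"a", "b"}, "y": {"e"}})
        assert out.loc["x", "y"] == 0 and out.loc["y", "x"] == 0

    def test_identical_sets_rule(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        sets = {"x": {"a", "b", "c"}, "y": {"a", "b", "c"}}
        out = cross_dataset_edges(g, sets)
        # shared genes are exclusive to no dataset: off-diagonal 0
        assert out.loc["x", "y"] == 0
        assert out.loc["x", "x"] == 2  # both edges internal

    def test_matches_brute_force_classification(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(12)]
        g = make_toy_network(genes, n_communities=2, p_within=0.5,
                             p_between=0.3, seed=3)
        sets = {
            "a": set(rng.choice(genes, 5, replace=False)),
            "b": set(rng.choice(genes, 5, replace=False)),
            "c": set(rng.choice(genes, 4, replace=False)),
        }
        out = cross_dataset_edges(g, sets)
        member = {x: [d for d, s in sets.items() if x in s] for x in genes}
        for i in sets:
            for j in sets:
                want = 0
                for u, v in g.edges:
                    if i == j:
                        want += u in sets[i] and v in sets[i]
                    else:
                        want += (
                            (member[u] == [i] and member[v] == [j])
                            or (member[u] == [j] and member[v] == [i])
                        )
                assert out.loc[i, j] == want
        assert (out.to_numpy() == out.to_numpy().T).all()


class TestToyGenerators:
    def test_annotation_validates_and_covers_genes(self):
        genes = [f"g{i}" for i in range(25)]
        dag = make_toy_annotation(genes, seed=5)
        dag.validate()
        assert set(dag.gene2terms) == set(genes)
        assert all(dag.gene2terms[g] for g in genes)

    def test_network_simple_graph(self):
        g = make_toy_network([f"g{i}" for i in range(30)], seed=5)
        assert not any(u == v for u, v in g.edges)
        assert g.number_of_nodes() == 30
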