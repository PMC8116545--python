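"""Functional consistency: enrichment, semantic similarity, network topology.

Three ways of asking whether gene sets called from different assays "mean
the same thing" biologically:

* over-representation — hypergeometric upper-tail test of a gene set against
  each annotation term, with ancestor propagation on the term DAG (a gene
  annotated to a term is implicitly annotated to all its ancestors) and
  Benjamini–Hochberg adjustment across terms;
* semantic similarity — Wang's graph-based term similarity (max-product of
  edge weights up the is-a DAG), combined into gene-gene and set-set scores
  by best-match averaging (BMA);
* interaction-network topology — degree, betweenness (Brandes) and the local
  clustering coefficient ("transitivity") of genes in an undirected
  interaction network, plus cross-dataset edge counts.

A toy annotation DAG and a community-structured toy network generator ship
with the module so the layer is fully testable without database downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "AnnotationDAG",
    "enrich",
    "term_similarity",
    "gene_similarity",
    "geneset_similarity",
    "null_similarity",
    "topology",
    "cross_dataset_edges",
    "make_toy_annotation",
    "make_toy_network",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationDAG:
    """A GO-like term DAG with gene annotations.

    ``parents`` maps each term to its (parent, weight) edges pointing
    rootward; weights lie in (0, 1) (the conventional Wang weights are 0.8
    for is-a and 0.6 for part-of edges).  ``gene2terms`` maps gene ids to
    their directly annotated terms.
    """

    parents: dict[str, list[tuple[str, float]]]
    gene2terms: dict[str, set[str]]
    roots: set[str]
    _s_cache: dict[str, dict[str, float]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _anc_cache: dict[str, frozenset] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def terms(self) -> set[str]:
        out = set(self.parents)
        for edges in self.parents.values():
            out.update(p for p, _ in edges)
        out.update(self.roots)
        return out

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, edges in self.parents.items():
            for parent, w in edges:
                if not (0.0 < w < 1.0):
                    raise ValueError(f"edge weight {w} outside (0, 1)")
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term graph contains a cycle")
        reach_root = set(self.roots)
        for r in self.roots:
            reach_root |= nx.ancestors(g, r)  # nodes with a rootward path
        for gene, terms in self.gene2terms.items():
            for t in terms:
                if t not in g:
                    raise ValueError(f"gene {gene} annotated to unknown term {t}")
                if t not in reach_root:
                    raise ValueError(f"term {t} cannot reach a root")

    def s_values(self, term: str) -> dict[str, float]:
        """Wang S-values: best max-product edge-weight path from ``term`` to
        each of its ancestors (including itself, S = 1)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        cached = self._s_cache.get(term)
        if cached is not None:
            return cached
        S = {term: 1.0}
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, w in self.parents.get(t, []):
                s = S[t] * w
                if s > S.get(parent, 0.0):
                    S[parent] = s
                    stack.append(parent)
        self._s_cache[term] = S
        return S

    def ancestors(self, term: str) -> frozenset:
        """The term itself plus everything reachable rootward."""
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(self.s_values(term))
            self._anc_cache[term] = cached
        return cached


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def enrich(
    gene_set: set,
    annotation: AnnotationDAG | dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set against each term.

    With an :class:`AnnotationDAG`, gene annotations are propagated to
    ancestor terms before counting; a flat gene->terms mapping (e.g. a
    pathway table) is used as-is.  Terms annotating no universe gene are
    skipped.  Returns a DataFrame sorted by p with columns term, k, K, n, N,
    p_value, q_value.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = frozenset(gene_set) & universe
    if isinstance(annotation, AnnotationDAG):
        gene2terms = {
            g: frozenset().union(*(annotation.ancestors(t) for t in ts))
            if ts else frozenset()
            for g, ts in annotation.gene2terms.items()
        }
    else:
        gene2terms = {g: frozenset(ts) for g, ts in annotation.items()}

    term_genes: dict[str, set] = {}
    for g in universe:
        for t in gene2terms.get(g, ()):
            term_genes.setdefault(t, set()).add(g)

    N, n = len(universe), len(gene_set)
    rows = []
    for t, members in sorted(term_genes.items()):
        K = len(members)
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": t, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term"], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Wang semantic similarity
# ---------------------------------------------------------------------------


def term_similarity(t1: str, t2: str, dag: AnnotationDAG) -> float:
    """Wang similarity of two terms in [0, 1].

    sim = sum over shared ancestors a of (S1(a) + S2(a)), divided by
    (sum of all S1) + (sum of all S2), where S are the max-product S-values
    and each term counts itself with S = 1.
    """
    s1 = dag.s_values(t1)
    s2 = dag.s_values(t2)
    shared = set(s1) & set(s2)
    num = sum(s1[a] + s2[a] for a in shared)
    den = sum(s1.values()) + sum(s2.values())
    return num / den if den else 0.0


def _bma(matrix: np.ndarray) -> float:
    """Best-match average of a pairwise similarity matrix."""
    if matrix.size == 0:
        return float("nan")
    return float((matrix.max(axis=1).mean() + matrix.max(axis=0).mean()) / 2.0)


def gene_similarity(g1: str, g2: str, dag: AnnotationDAG) -> float:
    """BMA over the two genes' annotated term sets."""
    t1 = sorted(dag.gene2terms.get(g1, ()))
    t2 = sorted(dag.gene2terms.get(g2, ()))
    if not t1 or not t2:
        return float("nan")
    m = np.array([[term_similarity(a, b, dag) for b in t2] for a in t1])
    return _bma(m)


def geneset_similarity(set_a: set, set_b: set, annotation: AnnotationDAG) -> float:
    """BMA set-set similarity over the gene-gene Wang similarity matrix.

    Unannotated genes are dropped (logged); NaN when either set is entirely
    unannotated.
    """
    a = sorted(g for g in set_a if annotation.gene2terms.get(g))
    b = sorted(g for g in set_b if annotation.gene2terms.get(g))
    dropped = (len(set_a) - len(a)) + (len(set_b) - len(b))
    if dropped:
        logger.info("geneset_similarity: dropped %d unannotated genes", dropped)
    if not a or not b:
        return float("nan")
    m = np.array([[gene_similarity(x, y, annotation) for y in b] for x in a])
    return _bma(m)


@dataclass
class NullSimilaritySummary:
    """Empirical null distribution of similarity between random draws."""

    samples: np.ndarray
    quantiles: dict[str, float]
    mean: float
    n_draws: int


def null_similarity(
    annotation: AnnotationDAG,
    universe: set,
    set_sizes: tuple[int, int] = (1, 1),
    n_draws: int = 1000,
    seed: int = 0,
) -> NullSimilaritySummary:
    """Similarity of randomly drawn gene pairs/sets from the universe.

    ``set_sizes = (1, 1)`` draws random gene pairs (the density-of-random-
    pairs null); larger sizes draw two independent random sets (each without
    internal replacement, overlap between the two allowed, as for two
    independently called gene lists) and score them with
    :func:`geneset_similarity`.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(g for g in universe if annotation.gene2terms.get(g)))
    a_size, b_size = set_sizes
    if n_draws > 0 and len(genes) < max(a_size, b_size):
        raise ValueError("universe too small for the requested set sizes")
    vals = []
    for _ in range(n_draws):
        if a_size == 1 and b_size == 1:
            pick = rng.choice(genes, size=2, replace=False)
            vals.append(gene_similarity(pick[0], pick[1], annotation))
        else:
            a = rng.choice(genes, size=a_size, replace=False)
            b = rng.choice(genes, size=b_size, replace=False)
            vals.append(geneset_similarity(set(a), set(b), annotation))
    samples = np.asarray(vals, dtype=float)
    if len(samples):
        qs = {f"q{int(q * 100):02d}": float(np.quantile(samples, q))
              for q in (0.05, 0.25, 0.5, 0.75, 0.95)}
        mean = float(samples.mean())
    else:
        qs, mean = {}, float("nan")
    return NullSimilaritySummary(samples=samples, quantiles=qs, mean=mean,
                                 n_draws=n_draws)


# ---------------------------------------------------------------------------
# network topology
# ---------------------------------------------------------------------------


def topology(network: nx.Graph, gene_set: set | None = None) -> pd.DataFrame:
    """Degree, betweenness and local clustering for genes of interest.

    Betweenness is exact Brandes accumulation over all shortest paths on the
    full network, unnormalized (each unordered pair contributes once);
    transitivity is the local clustering coefficient, 0 for degree < 2.
    Genes absent from the network get all-zero rows (logged).
    """
    if any(u == v for u, v in network.edges):
        raise ValueError("network must not contain self-loops")
    genes = sorted(gene_set) if gene_set is not None else sorted(network.nodes)
    bc = nx.betweenness_centrality(network, normalized=False)
    cc = nx.clustering(network)
    missing = [g for g in genes if g not in network]
    if missing:
        logger.info("topology: %d genes absent from the network", len(missing))
    rows = []
    for g in genes:
        if g in network:
            rows.append({"gene_id": g, "degree": network.degree[g],
                         "betweenness": float(bc[g]), "transitivity": float(cc[g])})
        else:
            rows.append({"gene_id": g, "degree": 0, "betweenness": 0.0,
                         "transitivity": 0.0})
    return pd.DataFrame(rows).set_index("gene_id")


def cross_dataset_edges(
    network: nx.Graph, dmg_sets: dict[str, set]
) -> pd.DataFrame:
    """Symmetric matrix of interaction edges linking dataset DMG sets.

    Off-diagonal (i, j): edges whose endpoints are *exclusive* members of
    dataset i's and dataset j's DMG sets respectively (genes belonging to
    more than one set contribute to no off-diagonal cell).  Diagonal (i, i):
    edges with both endpoints in dataset i's set, regardless of exclusivity.
    """
    names = list(dmg_sets)
    membership: dict[str, list[str]] = {}
    for d, s in dmg_sets.items():
        for g in s:
            membership.setdefault(g, []).append(d)
    exclusive = {g: ds[0] for g, ds in membership.items() if len(ds) == 1}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for u, v in network.edges:
        for d in names:
            if u in dmg_sets[d] and v in dmg_sets[d]:
                mat.loc[d, d] += 1
        du, dv = exclusive.get(u), exclusive.get(v)
        if du is not None and dv is not None and du != dv:
            mat.loc[du, dv] += 1
            mat.loc[dv, du] += 1
    return mat


# ---------------------------------------------------------------------------
# toy annotation and network generators
# ---------------------------------------------------------------------------


def make_toy_annotation(
    genes: list[str],
    n_branches: int = 4,
    depth: int = 3,
    children_per_term: int = 2,
    weight: float = 0.8,
    terms_per_gene: int = 3,
    branch_of: dict[str, int] | None = None,
    seed: int = 0,
) -> AnnotationDAG:
    """A branchy GO-like DAG with genes annotated within one branch each.

    The DAG is a root with ``n_branches`` complete ``children_per_term``-ary
    subtrees of the given depth; every is-a edge carries ``weight``.  Each
    gene is assigned a branch (``branch_of`` overrides the random
    assignment) and annotated to ``terms_per_gene`` random terms of that
    branch, so genes in the same branch are semantically coherent.
    """
    rng = np.random.default_rng(seed)
    root = "T:root"
    parents: dict[str, list[tuple[str, float]]] = {}
    branch_terms: list[list[str]] = []
    for b in range(n_branches):
        top = f"T:{b}"
        parents[top] = [(root, weight)]
        terms = [top]
        frontier = [top]
        for lvl in range(1, depth):
            nxt = []
            for t in frontier:
                for c in range(children_per_term):
                    child = f"{t}.{c}"
                    parents[child] = [(t, weight)]
                    nxt.append(child)
            terms.extend(nxt)
            frontier = nxt
        branch_terms.append(terms)

    gene2terms: dict[str, set[str]] = {}
    for g in genes:
        b = branch_of.get(g) if branch_of and g in branch_of else int(rng.integers(n_branches))
        pool = branch_terms[b]
        k = min(terms_per_gene, len(pool))
        gene2terms[g] = set(rng.choice(pool, size=k, replace=False))
    dag = AnnotationDAG(parents=parents, gene2terms=gene2terms, roots={root})
    dag.validate()
    return dag


def make_toy_network(
    genes: list[str],
    community_of: dict[str, int] | None = None,
    n_communities: int = 4,
    p_within: float = 0.3,
    p_between: float = 0.02,
    seed: int = 0,
) -> nx.Graph:
    """A planted-partition interaction network: dense within communities.

    Emulates the clustering of functionally related genes in interaction
    databases; no self-loops or duplicate edges.
    """
    rng = np.random.default_rng(seed)
    comm = {
        g: (community_of.get(g) if community_of and g in community_of
            else int(rng.integers(n_communities)))
        for g in genes
    }
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, u in enumerate(genes):
        for v in genes[i + 1:]:
            p = p_within if comm[u] == comm[v] else p_between
            if rng.random() < p:
                g.add_edge(u, v)
    return g
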