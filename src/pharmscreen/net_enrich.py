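"""Network connectivity and annotation-term enrichment for gene lists.

Two generic statistics applied to biomarker gene lists:

* a **connectivity test** — are the genes in a set more connected to one
  another in a protein–protein interaction network than random same-size
  node sets?  The null is built by uniform permutation of node sets and the
  p-value uses the add-one estimator (1 + #{null >= observed})/(1 + n_perm),
  so it is never exactly zero.
* **term enrichment** — hypergeometric upper-tail test of the overlap
  between the gene set and each annotation term (GMT gene sets), with
  Benjamini–Hochberg FDR adjustment across all tested terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SCORE_CUTOFF = 0.4


@dataclass
class ConnectivityResult:
    set_size: int
    observed_edges: int
    expected_edges: float
    p_value: float
    n_perm: int


@dataclass
class EnrichmentResult:
    term: str
    overlap: int      # k
    set_size: int     # n
    term_size: int    # K
    universe_size: int  # N
    p: float
    fdr: float


def network_from_edges(edges: pd.DataFrame,
                       score_cutoff: float = DEFAULT_SCORE_CUTOFF) -> nx.Graph:
    """Build an undirected simple graph from a two/three-column edge table.

    Columns: gene_a, gene_b[, score].  Edges with score below the cutoff
    are dropped at load time; self-loops and duplicate (unordered) edges
    are discarded.
    """
    g = nx.Graph()
    has_score = edges.shape[1] >= 3
    for row in edges.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            continue
        if has_score and float(row[2]) < score_cutoff:
            continue
        g.add_edge(a, b)
    return g


def connectivity_test(gene_set, network: nx.Graph, n_perm: int = 10000,
                      seed: int = 0) -> ConnectivityResult:
    """Observed vs expected within-set edge count with a permutation null.

    Genes absent from the network are dropped with a warning.  The null
    draws ``n_perm`` uniform node sets of the same size; the expectation is
    their mean edge count and the p-value is the add-one upper tail.
    """
    nodes = list(network.nodes)
    members = sorted(set(gene_set) & set(nodes))
    dropped = set(gene_set) - set(members)
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) not in network dropped",
                      stacklevel=2)
    k = len(members)
    if k < 2:
        raise ValueError("need >=2 genes present in the network")

    observed = network.subgraph(members).number_of_edges()

    index = {n: i for i, n in enumerate(nodes)}
    edge_idx = np.array([(index[a], index[b]) for a, b in network.edges],
                        dtype=np.intp).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    mask = np.zeros(len(nodes), dtype=bool)
    for i in range(n_perm):
        pick = rng.choice(len(nodes), size=k, replace=False)
        mask[pick] = True
        if edge_idx.size:
            null[i] = np.count_nonzero(mask[edge_idx[:, 0]]
                                       & mask[edge_idx[:, 1]])
        else:
            null[i] = 0
        mask[pick] = False

    p = (1.0 + int(np.count_nonzero(null >= observed))) / (1.0 + n_perm)
    return ConnectivityResult(set_size=k, observed_edges=int(observed),
                              expected_edges=float(null.mean()),
                              p_value=p, n_perm=n_perm)


def term_enrichment(gene_set, annotations: dict[str, list[str]],
                    universe) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a gene set against annotation terms.

    For each term with gene list restricted to the universe, tests
    P(X >= k) where X ~ Hypergeom(N=len(universe), K=|term|, n=|set|),
    then applies Benjamini–Hochberg across all tested terms.  Results are
    sorted by (fdr, p, term).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    gset = set(gene_set)
    if not gset <= universe:
        raise ValueError("gene set must be contained in the universe")
    N, n = len(universe), len(gset)

    terms, ps, meta = [], [], []
    for term, genes in annotations.items():
        tgenes = set(genes) & universe
        K = len(tgenes)
        if K == 0:
            continue
        k = len(tgenes & gset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        terms.append(term)
        ps.append(min(p, 1.0))
        meta.append((k, K))
    if not terms:
        return []
    fdrs = stats.false_discovery_control(ps, method="bh")
    results = [EnrichmentResult(term=t, overlap=m[0], set_size=n,
                                term_size=m[1], universe_size=N,
                                p=p, fdr=float(f))
               for t, p, f, m in zip(terms, ps, fdrs, meta)]
    results.sort(key=lambda r: (r.fdr, r.p, r.term))
    return results
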