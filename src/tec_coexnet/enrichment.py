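"""GO over-representation and semantic-similarity term reduction.

Module genes are tested for term over-representation with the one-sided
hypergeometric test against the analysed gene universe, restricted to
terms annotating between 15 and 500 background genes (inclusive) after
propagating annotations to ancestors along is_a and part_of edges.
Significant terms are condensed by a term semantic-similarity analysis:
pairwise Wang similarity, a seeded 2-D embedding of ``1 - similarity``
(UMAP by default, classical metric scaling as the deterministic,
order-equivariant alternative), DBSCAN density clustering, and selection
of the member with the largest ``-log10(p_adj)`` as each cluster's
representative.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

EDGE_TYPES = ("is_a", "part_of")
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def _parents(dag: nx.MultiDiGraph, term: str):
    """Typed child->parent edges leaving ``term`` (is_a / part_of only)."""
    for _, parent, key in dag.out_edges(term, keys=True):
        if key in EDGE_TYPES:
            yield parent, key


def ancestors(dag: nx.MultiDiGraph, term: str) -> set[str]:
    """All terms reachable from ``term`` along is_a/part_of edges (excl. itself)."""
    seen: set[str] = set()
    queue = deque([term])
    while queue:
        t = queue.popleft()
        for parent, _ in _parents(dag, t):
            if parent not in seen:
                seen.add(parent)
                queue.append(parent)
    return seen


def propagate_annotations(dag: nx.MultiDiGraph, ann: dict[str, set[str]]) -> dict[str, set[str]]:
    """Close gene->term annotations over ancestors (true-path rule)."""
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag:
                raise KeyError(f"annotated term {t} not in ontology")
            if t not in cache:
                cache[t] = {t} | ancestors(dag, t)
            closed |= cache[t]
        out[gene] = closed
    return out


def enrich(
    module_genes: set[str],
    background: set[str],
    ann: dict[str, set[str]],
    dag: nx.MultiDiGraph | None = None,
    min_size: int = 15,
    max_size: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of terms in a gene module.

    Term sizes are counted on the background after (optional) ancestor
    propagation; only terms annotating between ``min_size`` and
    ``max_size`` background genes (inclusive) are tested.  p-values are
    BH-adjusted over the tested terms.
    """
    from .diffexpr import adjust_pvalues

    if not module_genes:
        raise ValueError("empty module gene set")
    if not module_genes <= background:
        raise ValueError("module genes must be a subset of the background")
    if dag is not None:
        ann = propagate_annotations(dag, {g: t for g, t in ann.items() if g in background})
    term_genes: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        if gene not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    N, n = len(background), len(module_genes)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        K = len(genes)
        if K < min_size or K > max_size:
            continue
        k = len(genes & module_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(result):
        result["p_adj"] = adjust_pvalues(result["p"], "bh")
        result["neg_log10_p_adj"] = -np.log10(np.maximum(result["p_adj"], 1e-300))
        result["significant"] = result["p_adj"] < alpha
        result = result.set_index("term")
    return result


# ---------------------------------------------------------------------------
# Wang semantic similarity


def _svalues(dag: nx.MultiDiGraph, term: str, weights: dict[str, float]) -> dict[str, float]:
    """Semantic S-values of a term's ancestor graph.

    ``SV(term) = 1``; for an ancestor t, SV(t) is the maximum over its
    children c inside the ancestor graph of ``w(c->t) * SV(c)`` —
    contributions decay along each edge walked away from the query term.
    """
    nodes = {term} | ancestors(dag, term)
    sv = {term: 1.0}
    # process children before parents: topological order of the sub-DAG
    sub = nx.DiGraph()
    sub.add_nodes_from(nodes)
    for t in nodes:
        for parent, key in _parents(dag, t):
            if parent in nodes:
                # keep the strongest edge type between a pair
                w = weights[key]
                if sub.has_edge(t, parent):
                    w = max(w, sub[t][parent]["w"])
                sub.add_edge(t, parent, w=w)
    for t in nx.topological_sort(sub):
        if t == term:
            continue
        best = 0.0
        for child in sub.predecessors(t):
            best = max(best, sub[child][t]["w"] * sv[child])
        sv[t] = best
    return sv


def wang_similarity(
    dag: nx.MultiDiGraph, t1: str, t2: str, w_isa: float = 0.8, w_partof: float = 0.6
) -> float:
    """Graph-based Wang similarity of two terms in (0, 1]."""
    ns1 = dag.nodes[t1].get("namespace")
    ns2 = dag.nodes[t2].get("namespace")
    if ns1 is not None and ns2 is not None and ns1 != ns2:
        raise ValueError(f"terms {t1} and {t2} are in disjoint namespaces")
    weights = {"is_a": w_isa, "part_of": w_partof}
    sv1 = _svalues(dag, t1, weights)
    sv2 = _svalues(dag, t2, weights)
    common = sv1.keys() & sv2.keys()
    if not common:
        return 0.0
    num = sum(sv1[t] + sv2[t] for t in common)
    return float(num / (sum(sv1.values()) + sum(sv2.values())))


def similarity_matrix(dag: nx.MultiDiGraph, terms: list[str]) -> pd.DataFrame:
    weights = WANG_WEIGHTS
    svs = {t: _svalues(dag, t, weights) for t in terms}
    totals = {t: sum(svs[t].values()) for t in terms}
    n = len(terms)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = svs[terms[i]], svs[terms[j]]
            common = a.keys() & b.keys()
            num = sum(a[t] + b[t] for t in common)
            S[i, j] = S[j, i] = num / (totals[terms[i]] + totals[terms[j]])
    return pd.DataFrame(S, index=terms, columns=terms)


# ---------------------------------------------------------------------------
# term reduction (GOTSSA)


def _embed(D: np.ndarray, method: str, seed: int) -> np.ndarray:
    if method == "umap":
        import umap

        n = D.shape[0]
        # random init: the spectral initialisation is not reproducible across
        # calls under numba threading even with a fixed random_state
        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed",
            random_state=seed,
            n_neighbors=max(2, min(15, n - 1)),
            min_dist=0.1,
            init="random",
        )
        return np.asarray(reducer.fit_transform(D), dtype=float)
    if method == "mds":
        # classical metric scaling of the squared distances
        n = D.shape[0]
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][:2]
        coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
        return coords
    raise ValueError(f"unknown embedding {method!r}")


def reduce_terms(
    results: pd.DataFrame,
    dag: nx.MultiDiGraph,
    epsilon: float = 0.6,
    min_neighbors: int = 5,
    seed: int = 0,
    embedding: str = "umap",
) -> pd.DataFrame:
    """Cluster significant terms by semantic similarity; pick representatives.

    Returns a table indexed by term with embedding coordinates, cluster id
    (-1 = noise), and the representative flag.  With fewer than
    ``min_neighbors`` significant terms every term is noise and its own
    representative.
    """
    from sklearn.cluster import DBSCAN

    sig = results[results["significant"]] if "significant" in results.columns else results
    terms = list(sig.index)
    if len(terms) == 0:
        return pd.DataFrame(columns=["x", "y", "cluster", "representative"])
    if len(terms) < min_neighbors:
        return pd.DataFrame(
            {
                "x": np.zeros(len(terms)),
                "y": np.zeros(len(terms)),
                "cluster": -1,
                "representative": True,
            },
            index=pd.Index(terms, name="term"),
        )
    S = similarity_matrix(dag, terms)
    D = 1.0 - S.to_numpy()
    np.fill_diagonal(D, 0.0)
    coords = _embed(D, embedding, seed)
    labels = DBSCAN(eps=epsilon, min_samples=min_neighbors).fit_predict(coords)
    out = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "cluster": labels, "representative": False},
        index=pd.Index(terms, name="term"),
    )
    score = sig["neg_log10_p_adj"]
    for lab in np.unique(labels):
        members = out.index[out["cluster"] == lab]
        if lab == -1:
            out.loc[members, "representative"] = True
            continue
        best = sorted(members, key=lambda t: (-score[t], t))[0]
        out.loc[best, "representative"] = True
    return out
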