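"""Signed weighted co-expression network and iterative module detection.

The network is built from the biweight midcorrelation (a robust,
median/MAD-based correlation), soft-thresholded into a signed adjacency
``a_ij = ((1 + c_ij) / 2) ** beta`` and smoothed into the topological
overlap measure (TOM).  Modules are branches of an average-linkage
dendrogram of ``1 - TOM``, cut at a height quantile, dissolved when
smaller than the minimum size, and optionally grown by a PAM-like stage
that adopts unassigned genes whose module membership (kME, correlation
with the module eigengene) clears a threshold.  The iterative variant
alternates network construction, detection and pruning of low-kME genes
until the assignment stabilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .simulate import UNASSIGNED

#: deepsplit -> merge-height quantile of the dendrogram cut
DEEPSPLIT_QUANTILE = {0: 0.999, 1: 0.995, 2: 0.99, 3: 0.98, 4: 0.95}


@dataclass
class NetworkConfig:
    beta: int = 12
    correlation: str = "bicor"  # or "pearson"
    network_type: str = "signed"
    min_module_size: int = 30
    deepsplit: int = 2
    pam_stage: bool = True
    mm_prune_threshold: float = 0.8
    max_iterations: int = 10
    cut_height_quantile: float | None = None  # None -> derived from deepsplit
    max_genes: int = 20000

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0 < self.mm_prune_threshold < 1) and self.mm_prune_threshold != 0:
            raise ValueError("mm_prune_threshold must lie in [0, 1)")
        if self.deepsplit not in DEEPSPLIT_QUANTILE:
            raise ValueError("deepsplit must be an integer in 0..4")
        if self.network_type != "signed":
            raise ValueError("only signed networks are supported")
        if self.correlation not in ("bicor", "pearson"):
            raise ValueError("correlation must be 'bicor' or 'pearson'")

    @property
    def height_quantile(self) -> float:
        if self.cut_height_quantile is not None:
            return self.cut_height_quantile
        return DEEPSPLIT_QUANTILE[self.deepsplit]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModuleAssignment:
    module_of_gene: pd.Series  # gene -> module label or UNASSIGNED
    iteration_history: list[pd.Series] = field(default_factory=list)
    converged: bool = True

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.module_of_gene[self.module_of_gene != UNASSIGNED]
        return assigned.value_counts().sort_index()

    def genes_of(self, module: str) -> pd.Index:
        return self.module_of_gene.index[self.module_of_gene == module]


# ---------------------------------------------------------------------------
# correlation


def _bicor_prepare(M: np.ndarray) -> np.ndarray:
    """Per-row robust standardisation used by the biweight midcorrelation.

    Rows are median-centred and weighted with ``w = (1 - u^2)^2`` for
    ``|u| < 1`` where ``u = (x - median) / (9 * MAD)``; rows with zero MAD
    fall back to the Pearson standardisation (mean-centred).  Each row is
    scaled to unit Euclidean norm so that correlations are dot products.
    """
    med = np.median(M, axis=1, keepdims=True)
    mad = np.median(np.abs(M - med), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (M - med) / (9.0 * mad)
    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1)
    out = (M - med) * w
    if fallback.any():
        out[fallback] = M[fallback] - M[fallback].mean(axis=1, keepdims=True)
    norms = np.sqrt((out**2).sum(axis=1, keepdims=True))
    zero = (norms == 0).ravel()
    if zero.any():
        warnings.warn("constant row(s) in bicor; correlations set to 0", RuntimeWarning)
        norms[zero] = 1.0
    return out / norms


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (tuning constant 9 x MAD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    P = _bicor_prepare(np.vstack([x, y]))
    return float(np.clip(P[0] @ P[1], -1.0, 1.0))


def correlation_matrix(X: pd.DataFrame, method: str = "bicor") -> pd.DataFrame:
    """Gene-gene correlation of a genes x samples matrix."""
    M = X.to_numpy(dtype=float)
    if method == "bicor":
        P = _bicor_prepare(M)
    elif method == "pearson":
        P = M - M.mean(axis=1, keepdims=True)
        norms = np.sqrt((P**2).sum(axis=1, keepdims=True))
        norms[norms == 0] = 1.0
        P = P / norms
    else:
        raise ValueError(f"unknown correlation {method!r}")
    C = np.clip(P @ P.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=X.index, columns=X.index)


# ---------------------------------------------------------------------------
# adjacency and topological overlap


def signed_adjacency(C: pd.DataFrame, beta: int = 12) -> pd.DataFrame:
    """Soft-thresholded signed adjacency ``((1 + c) / 2) ** beta`` with unit diagonal."""
    A = np.power((1.0 + C.to_numpy(dtype=float)) / 2.0, beta)
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=C.index, columns=C.columns)


def tom_similarity(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour-smoothed adjacency, unit diagonal.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    the sum over u distinct from i and j and ``k`` the connectivity.
    """
    A0 = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A0) / (kmin + 1.0 - A0)
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=A.index, columns=A.columns)


# ---------------------------------------------------------------------------
# module detection


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Deterministic module names M1, M2, ... by decreasing size (ties: first gene id)."""
    assigned = labels[labels != UNASSIGNED]
    if assigned.empty:
        return labels
    order = (
        assigned.groupby(assigned)
        .agg(size="size", first=lambda s: s.index.min())
        .sort_values(["size", "first"], ascending=[False, True])
    )
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order.index)}
    return labels.map(lambda lab: mapping.get(lab, UNASSIGNED))


def module_eigengenes(X: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    Each module's gene-standardised submatrix is decomposed by SVD; the
    leading right singular vector across samples is scaled to unit sample
    variance and flipped so that its mean correlation with the module genes
    is non-negative.
    """
    eigs = {}
    for m in assignment.module_sizes.index:
        genes = assignment.genes_of(m)
        if len(genes) < 3:
            raise ValueError(f"module {m} has fewer than 3 genes")
        sub = X.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (sub - mu) / sd
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        e = Vt[0]
        e = e / e.std(ddof=1)
        corr = (Z @ e) / ((Z**2).sum(axis=1) ** 0.5 * (e @ e) ** 0.5)
        if corr.mean() < 0:
            e = -e
        eigs[m] = e
    return pd.DataFrame(eigs, index=X.columns).T


def module_membership(
    X: pd.DataFrame, eigengenes: pd.DataFrame, method: str = "bicor"
) -> pd.DataFrame:
    """kME: correlation of every gene with every module eigengene."""
    combined = pd.concat([X, eigengenes])
    C = correlation_matrix(combined, method=method)
    return C.iloc[: len(X), len(X) :].copy()


def _quantile_cut(D: np.ndarray, quantile: float) -> np.ndarray:
    """Average-linkage clustering of a dissimilarity matrix, cut at the
    given quantile of the merge heights; returns integer labels."""
    Z = average(squareform(D, checks=False))
    cut = np.quantile(Z[:, 2], quantile)
    return fcluster(Z, t=cut, criterion="distance")


def _median_own_kme(X: pd.DataFrame, genes, method: str) -> float:
    sub = X.loc[genes]
    assignment = ModuleAssignment(pd.Series("m", index=sub.index))
    eig = module_eigengenes(sub, assignment)
    kme = module_membership(sub, eig, method=method)
    return float(kme["m"].median())


def detect_modules(
    tom: pd.DataFrame,
    config: NetworkConfig,
    X: pd.DataFrame | None = None,
    max_depth: int = 6,
) -> ModuleAssignment:
    """Single-pass module detection on a TOM matrix.

    Average-linkage clustering of ``1 - TOM``, cut at the configured
    quantile of the merge heights; clusters below ``min_module_size``
    dissolve to unassigned.  When the expression matrix is supplied, any
    cluster whose median module membership falls below
    ``mm_prune_threshold`` is re-split recursively on its own subtree with
    a progressively lower cut quantile — heterogeneous branches (several
    modules or noise lumped together at the global cut) separate, while
    pure-noise branches dissolve; coherent modules are never re-split.
    With ``pam_stage`` on, unassigned genes are finally adopted by the
    module whose eigengene they correlate with best, provided kME reaches
    ``mm_prune_threshold``.
    """
    genes = tom.index
    if len(genes) < 2 * config.min_module_size:
        raise ValueError("need at least 2 * min_module_size genes")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    Dframe = pd.DataFrame(D, index=genes, columns=genes)

    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    next_id = [0]
    q0 = config.height_quantile

    def accept(sub: pd.Index) -> None:
        next_id[0] += 1
        labels.loc[sub] = str(next_id[0])

    def split(members: pd.Index, depth: int) -> None:
        # halve the retained top-merge mass per level: 0.99, 0.98, 0.96, ...
        quantile = max(1.0 - (1.0 - q0) * 2**depth, 0.5)
        raw = _quantile_cut(Dframe.loc[members, members].to_numpy(), quantile)
        clusters = pd.Series(raw, index=members)
        sizes = clusters.value_counts()
        valid = [c for c in sizes.index if sizes[c] >= config.min_module_size]
        for c in valid:
            sub = clusters.index[clusters == c]
            coherent = (
                X is None
                or config.mm_prune_threshold == 0
                or _median_own_kme(X, sub, config.correlation) >= config.mm_prune_threshold
            )
            if coherent or depth >= max_depth:
                accept(sub)
            else:
                split(sub, depth + 1)

    split(genes, 0)
    labels = _relabel_by_size(labels)
    assignment = ModuleAssignment(module_of_gene=labels)
    if config.pam_stage and X is not None and len(assignment.module_sizes) > 0:
        eig = module_eigengenes(X, assignment)
        pool = labels.index[labels == UNASSIGNED]
        if len(pool) > 0:
            kme = module_membership(X.loc[pool], eig, method=config.correlation)
            best = kme.idxmax(axis=1)
            best_val = kme.max(axis=1)
            adopt = best_val >= config.mm_prune_threshold
            labels.loc[pool[adopt]] = best[adopt]
            assignment = ModuleAssignment(module_of_gene=_relabel_by_size(labels))
    return assignment


def iterative_wgcna(
    X: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[ModuleAssignment, pd.DataFrame, pd.DataFrame]:
    """Iterative, membership-pruned network construction.

    Loop: build the signed network on the currently assigned genes, detect
    modules, compute each gene's kME against its own module eigengene, and
    move genes with kME below ``mm_prune_threshold`` back to the unassigned
    pool — until the assignment repeats or ``max_iterations`` is reached.
    Finally, pooled genes are re-adopted by any module whose eigengene they
    match at or above the threshold (best module first).  Returns the
    assignment (with per-iteration history), the eigengene matrix and the
    kME matrix of all genes against the final eigengenes.
    """
    if config is None:
        config = NetworkConfig()
    if len(X) > config.max_genes:
        raise ValueError(f"{len(X)} genes exceeds the configured cap {config.max_genes}")
    current = pd.Index(X.index)
    history: list[pd.Series] = []
    prev_labels: pd.Series | None = None
    labels = pd.Series(UNASSIGNED, index=X.index)
    eig = pd.DataFrame(index=pd.Index([]), columns=X.columns)
    converged = False

    for _ in range(config.max_iterations):
        sub = X.loc[current]
        C = correlation_matrix(sub, method=config.correlation)
        A = signed_adjacency(C, beta=config.beta)
        T = tom_similarity(A)
        assignment = detect_modules(T, config, X=sub)
        labels = pd.Series(UNASSIGNED, index=X.index)
        labels.loc[current] = assignment.module_of_gene
        if len(assignment.module_sizes) == 0:
            history.append(labels.copy())
            break
        eig = module_eigengenes(sub, assignment)
        assigned_genes = labels.index[labels != UNASSIGNED]
        kme_all = module_membership(X.loc[assigned_genes], eig, method=config.correlation)
        own = pd.Series(
            [kme_all.at[g, labels[g]] for g in assigned_genes], index=assigned_genes
        )
        prune = own.index[own < config.mm_prune_threshold]
        labels.loc[prune] = UNASSIGNED
        # drop modules that fell below the minimum size after pruning
        sizes = labels[labels != UNASSIGNED].value_counts()
        dead = sizes.index[sizes < config.min_module_size]
        labels[labels.isin(dead)] = UNASSIGNED
        history.append(labels.copy())
        if prev_labels is not None and labels.equals(prev_labels):
            converged = True
            break
        prev_labels = labels.copy()
        current = labels.index[labels != UNASSIGNED]
        if len(current) < 2 * config.min_module_size:
            break

    labels = _relabel_by_size(labels)
    assignment = ModuleAssignment(module_of_gene=labels, iteration_history=history, converged=converged)
    if len(assignment.module_sizes) == 0:
        eig = pd.DataFrame(index=pd.Index([]), columns=X.columns)
        kme = pd.DataFrame(index=X.index, columns=pd.Index([]))
        return assignment, eig, kme
    # eigengenes of the converged cores, then re-adoption of pooled genes
    eig = module_eigengenes(X, assignment)
    kme = module_membership(X, eig, method=config.correlation)
    pool = labels.index[labels == UNASSIGNED]
    if len(pool) > 0:
        best = kme.loc[pool].idxmax(axis=1)
        best_val = kme.loc[pool].max(axis=1)
        adopt = best_val >= config.mm_prune_threshold
        labels.loc[pool[adopt]] = best[adopt]
    assignment = ModuleAssignment(
        module_of_gene=labels, iteration_history=history, converged=converged
    )
    return assignment, eig, kme
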