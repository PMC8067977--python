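"""Single-sample gene-set variation scoring.

Per gene, expression is normalised across samples by a Gaussian-kernel
cumulative density estimate (bandwidth = SD/4); per sample, genes are
ranked by decreasing kernel-CDF score and a Kolmogorov-Smirnov-like
weighted random walk over the ranking turns each gene set into one score
per sample in [-1, 1].  Positive scores indicate coordinated
over-expression of the set in that sample.  The score matrix is then
analysed for differential pathway activity with the same moderated linear
model used for genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .diffexpr import DesignSpec, ModeratedFit, fit_group_means, moderate_and_test

log = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def gene_level_statistics(X: pd.DataFrame, bandwidth_factor: float = 4.0) -> pd.DataFrame:
    """Signed centred rank statistics from per-gene kernel CDF scores.

    For gene i and sample j the kernel CDF score is
    ``mean_k Phi((x_ij - x_ik) / h_i)`` with ``h_i = SD_i / bandwidth_factor``.
    Within each sample, genes are ranked by increasing score (average ranks
    for ties) and centred: the returned statistic is ``r_ij - (p + 1) / 2``.
    Its magnitude is the random-walk weight and its sign orders the walk
    (most positive = most highly expressed, walked first).  A constant gene
    gets a flat CDF score of 0.5 with a warning.
    """
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    V = X.to_numpy(dtype=float)
    p, n = V.shape
    sds = V.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): uniform statistic", RuntimeWarning)
    h = np.where(constant, 1.0, sds / bandwidth_factor)
    diff = (V[:, :, None] - V[:, None, :]) / h[:, None, None]
    z = norm.cdf(diff).mean(axis=2)  # genes x samples
    z[constant] = 0.5
    ranks = rankdata(z, axis=0)  # per-sample ranks across genes, ties averaged
    centred = ranks - (p + 1) / 2.0
    return pd.DataFrame(centred, index=X.index, columns=X.columns)


def _walk_score(order_weights: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Score one sample: max positive plus min negative deviation of the walk."""
    w = np.abs(order_weights) ** tau
    w_in = np.where(in_set, w, 0.0)
    denom_in = w_in.sum()
    n_out = int((~in_set).sum())
    if n_out == 0 or denom_in == 0:
        return 0.0
    steps = np.where(in_set, w_in / denom_in, -1.0 / n_out)
    walk = np.cumsum(steps)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def score_sets(
    stats: pd.DataFrame,
    collection: dict[str, list[str]],
    tau: float = 1.0,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """GSVA-style score per gene set and sample from the rank statistics.

    Each sample's genes are walked in order of decreasing statistic;
    inside-set steps add the rank weight ``|r|^tau`` (normalised), outside
    steps subtract a uniform decrement.  The score is the sum of the
    largest positive and the most negative deviation of the walk.  Sets
    overlapping the gene universe in fewer than ``min_overlap`` genes are
    dropped and logged; a set covering the whole universe has no
    outside-set contrast and scores 0.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    genes = pd.Index(stats.index)
    S = stats.to_numpy(dtype=float)
    p, n = S.shape
    # stable walk order per sample: decreasing statistic, ties by gene position
    order = np.argsort(-S, axis=0, kind="stable")

    scored: dict[str, np.ndarray] = {}
    for name, members in collection.items():
        member_idx = genes.get_indexer(pd.unique(pd.Index(members)))
        member_idx = member_idx[member_idx >= 0]
        dropped = len(set(members)) - len(member_idx)
        if dropped:
            log.info("set %s: %d gene(s) not in matrix", name, dropped)
        if len(member_idx) < min_overlap:
            log.warning("set %s skipped: overlap %d < %d", name, len(member_idx), min_overlap)
            continue
        mask = np.zeros(p, dtype=bool)
        mask[member_idx] = True
        col_scores = np.empty(n)
        for j in range(n):
            oj = order[:, j]
            col_scores[j] = _walk_score(S[oj, j], mask[oj], tau)
        scored[name] = col_scores
    if not scored:
        raise ValueError("no set overlaps the gene universe sufficiently")
    return pd.DataFrame(scored, index=stats.columns).T


def gsva_scores(
    X: pd.DataFrame, collection: dict[str, list[str]], tau: float = 1.0, min_overlap: int = 2
) -> pd.DataFrame:
    """Convenience: kernel statistics then set scoring on an expression matrix."""
    return score_sets(gene_level_statistics(X), collection, tau=tau, min_overlap=min_overlap)


def differential_pathways(
    scores: pd.DataFrame,
    design: DesignSpec,
    rho: float = 0.0,
    contrasts: list[str] | None = None,
    adjust: str = "bh",
) -> tuple[ModeratedFit, dict[str, pd.DataFrame]]:
    """Moderated linear-model analysis of the set-score matrix.

    Constant score rows are excluded with a warning (their t-statistic is
    undefined).  Returns the fit and one result table per contrast with the
    score difference, moderated t, p and adjusted p; no fold-change cutoff
    is applied to scores (the DE convention is for genes).
    """
    keep = scores.std(axis=1, ddof=1) > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant score row(s) excluded", RuntimeWarning)
    scores = scores.loc[keep]
    fit = fit_group_means(scores, design, rho=rho)
    if contrasts is None:
        contrasts = list(design.contrasts)
    tables = {}
    for name in contrasts:
        tab = moderate_and_test(fit, name, adjust=adjust, lfc_threshold=0.0)
        tab = tab.rename(columns={"log2FC": "score_diff"})
        tab["significant"] = tab["p_adj"] < 0.05
        tables[name] = tab
    return fit, tables
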