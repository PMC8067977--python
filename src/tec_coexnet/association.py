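"""Eigengene-trait association, module selection, connectivity and hub calling.

Each module eigengene y is modelled as

    y_ijk = b0_i + beta1 * origin_j + beta2 * activation_k + e_ijk

with a subject-specific random intercept b0_i to absorb the pairing of
fractions from the same subject.  The model is fitted by REML (profiled
over the variance ratio, with closed-form per-block algebra) and the
fixed-effect t-statistics use Satterthwaite-approximated degrees of
freedom.  Traits are coded 0/1 (non-tumour/tumour, ENG-/ENG+), so a
positive t means up-regulation in tumour or activated cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist, ttest_ind

from .coexnet import ModuleAssignment
from .diffexpr import adjust_pvalues
from .simulate import UNASSIGNED


# ---------------------------------------------------------------------------
# random-intercept REML


class RandomInterceptModel:
    """REML fit of ``y = X beta + Z b + e`` with one random intercept per group."""

    def __init__(self, y, X, groups):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        codes, _ = pd.factorize(np.asarray(groups))
        self.codes = codes
        self.sizes = np.bincount(codes)
        self.n, self.p = self.X.shape
        self.singular = False
        self._fit()

    # -- linear algebra helpers (V = sigma_e^2 I + sigma_b^2 Z Z') ---------

    def _solve_W(self, M: np.ndarray, gamma: float) -> np.ndarray:
        """(I + gamma Z Z')^{-1} M via the per-block Sherman-Morrison form."""
        out = M.copy()
        for b, m in enumerate(self.sizes):
            idx = self.codes == b
            shrink = gamma / (1.0 + gamma * m)
            out[idx] -= shrink * M[idx].sum(axis=0, keepdims=True)
        return out

    def _reml_profile(self, gamma: float) -> tuple[float, np.ndarray, float]:
        """Profiled REML criterion; returns (-2 log-lik, beta, sigma_e^2)."""
        WX = self._solve_W(self.X, gamma)
        Wy = self._solve_W(self.y[:, None], gamma).ravel()
        G = self.X.T @ WX
        beta = np.linalg.solve(G, self.X.T @ Wy)
        r = self.y - self.X @ beta
        q = float(r @ self._solve_W(r[:, None], gamma).ravel())
        df = self.n - self.p
        sigma_e2 = max(q / df, 1e-300)
        logdetW = float(np.log1p(gamma * self.sizes).sum())
        sign, logdetG = np.linalg.slogdet(G)
        crit = df * math.log(sigma_e2) + logdetW + logdetG
        return crit, beta, sigma_e2

    def _fit(self) -> None:
        res = minimize_scalar(
            lambda u: self._reml_profile(math.exp(u))[0],
            bounds=(-14.0, 10.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = math.exp(res.x)
        crit0, _, _ = self._reml_profile(0.0)
        if crit0 <= res.fun:  # boundary: no subject variance
            gamma = 0.0
        _, beta, sigma_e2 = self._reml_profile(gamma)
        self.gamma = gamma
        self.beta = beta
        self.sigma_e2 = sigma_e2
        self.sigma_b2 = gamma * sigma_e2
        if self.sigma_b2 < 1e-10 * (self.sigma_e2 + self.sigma_b2):
            self.singular = True

    # -- Satterthwaite machinery -------------------------------------------

    def _var_contrast(self, c: np.ndarray, sigma_b2: float, sigma_e2: float) -> float:
        gamma = sigma_b2 / sigma_e2
        WX = self._solve_W(self.X, gamma)
        G = self.X.T @ WX / sigma_e2
        return float(c @ np.linalg.solve(G, c))

    def _reml_loglik(self, sigma_b2: float, sigma_e2: float) -> float:
        """Unprofiled REML log-likelihood (up to a constant)."""
        if sigma_e2 <= 0 or np.any(sigma_e2 + self.sizes * sigma_b2 <= 0):
            return -np.inf
        gamma = sigma_b2 / sigma_e2
        WX = self._solve_W(self.X, gamma)
        Wy = self._solve_W(self.y[:, None], gamma).ravel()
        G = self.X.T @ WX
        beta = np.linalg.solve(G, self.X.T @ Wy)
        r = self.y - self.X @ beta
        q = float(r @ self._solve_W(r[:, None], gamma).ravel()) / sigma_e2
        logdetV = (self.n - len(self.sizes)) * math.log(sigma_e2) + float(
            np.log(sigma_e2 + self.sizes * sigma_b2).sum()
        )
        _, logdetG = np.linalg.slogdet(G / sigma_e2)
        return -0.5 * (logdetV + logdetG + q)

    def test_contrast(self, c: np.ndarray) -> tuple[float, float, float, float]:
        """Satterthwaite t-test of ``c' beta``; returns (estimate, t, df, p)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        theta = np.array([max(self.sigma_b2, 1e-10 * self.sigma_e2), self.sigma_e2])
        var_c = self._var_contrast(c, theta[0], theta[1])
        se = math.sqrt(var_c)
        t = est / se if se > 0 else 0.0

        # gradient of var_c and Hessian of the REML log-likelihood in theta
        h = np.maximum(1e-4 * theta, 1e-10 * theta[1])
        g = np.empty(2)
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            g[j] = (self._var_contrast(c, *tp) - self._var_contrast(c, *tm)) / (2 * h[j])
        H = np.empty((2, 2))
        for j in range(2):
            for k in range(j, 2):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[j] += h[j]; tpp[k] += h[k]
                tpm[j] += h[j]; tpm[k] -= h[k]
                tmp[j] -= h[j]; tmp[k] += h[k]
                tmm[j] -= h[j]; tmm[k] -= h[k]
                H[j, k] = H[k, j] = (
                    self._reml_loglik(*tpp)
                    - self._reml_loglik(*tpm)
                    - self._reml_loglik(*tmp)
                    + self._reml_loglik(*tmm)
                ) / (4 * h[j] * h[k])
        try:
            cov_theta = np.linalg.pinv(-H)
        except np.linalg.LinAlgError:
            cov_theta = np.zeros((2, 2))
        denom = float(g @ cov_theta @ g)
        df = 2 * var_c**2 / denom if denom > 0 else float(self.n - self.p)
        df = float(np.clip(df, 1.0, 1e8))
        p = float(2 * t_dist.sf(abs(t), df))
        return est, t, df, p


@dataclass
class MixedModelResult:
    table: pd.DataFrame  # per module: beta/t/df/p/p_adj per trait + variances


def fit_eigengene_model(
    E: pd.DataFrame, annotation: pd.DataFrame, adjust: str = "bh"
) -> MixedModelResult:
    """Per-module mixed-effects association with origin and activation.

    ``E`` is modules x samples; ``annotation`` supplies subject, origin and
    activation per sample.  p-values are BH-adjusted across modules,
    separately per trait.
    """
    ann = annotation.set_index("sample_id").loc[E.columns]
    subjects = ann["subject_id"]
    if subjects.value_counts().ge(2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 samples")
    origin01 = (ann["origin"] == "tumour").to_numpy(float)
    act01 = (ann["activation"] == "ENG+").to_numpy(float)
    for vec, name in ((origin01, "origin"), (act01, "activation")):
        if len(np.unique(vec)) < 2:
            raise ValueError(f"both {name} levels must be present")
    X = np.column_stack([np.ones(len(ann)), origin01, act01])

    rows = []
    for m in E.index:
        model = RandomInterceptModel(E.loc[m].to_numpy(), X, subjects.to_numpy())
        if model.singular:
            warnings.warn(f"module {m}: singular fit (subject variance at boundary)", RuntimeWarning)
        b1, t1, df1, p1 = model.test_contrast([0.0, 1.0, 0.0])
        b2, t2, df2, p2 = model.test_contrast([0.0, 0.0, 1.0])
        rows.append(
            {
                "module": m,
                "beta1": b1, "t1": t1, "df1": df1, "p1": p1,
                "beta2": b2, "t2": t2, "df2": df2, "p2": p2,
                "subject_var": model.sigma_b2,
                "residual_var": model.sigma_e2,
                "singular": model.singular,
            }
        )
    table = pd.DataFrame(rows).set_index("module")
    table["p1_adj"] = adjust_pvalues(table["p1"], adjust)
    table["p2_adj"] = adjust_pvalues(table["p2"], adjust)
    return MixedModelResult(table=table)


# ---------------------------------------------------------------------------
# module selection, connectivity, hubs


def select_modules(kme: pd.DataFrame, assignment: ModuleAssignment, threshold: float = 0.8) -> pd.DataFrame:
    """Median |kME| per module; strict ``> threshold`` selection."""
    rows = []
    for m in assignment.module_sizes.index:
        genes = assignment.genes_of(m)
        med = float(kme.loc[genes, m].abs().median())
        rows.append({"module": m, "median_abs_kme": med, "selected": med > threshold})
    return pd.DataFrame(rows).set_index("module")


def intramodular_connectivity(
    A: pd.DataFrame, assignment: ModuleAssignment, hub_fraction: float = 0.1
) -> pd.DataFrame:
    """kWithin, its module-max-normalised version, and the hub flag.

    kWithin_i sums a gene's adjacencies to the other genes of its own
    module; per module, the ``ceil(hub_fraction * size)`` genes with the
    highest normalised connectivity are hubs (ties broken by gene id).
    """
    rows = []
    for m in assignment.module_sizes.index:
        genes = assignment.genes_of(m)
        if len(genes) < 2:
            raise ValueError(f"module {m} is a singleton")
        sub = A.loc[genes, genes].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, 0.0)
        kwithin = pd.Series(sub.sum(axis=1), index=genes)
        kmax = kwithin.max()
        knorm = kwithin / kmax if kmax > 0 else kwithin * 0.0
        n_hubs = math.ceil(hub_fraction * len(genes))
        # deterministic: by decreasing connectivity, ties by gene id
        order = sorted(genes, key=lambda g: (-knorm[g], g))
        hubs = set(order[:n_hubs])
        for g in genes:
            rows.append(
                {
                    "gene_id": g,
                    "module": m,
                    "kWithin": float(kwithin[g]),
                    "kWithin_norm": float(knorm[g]),
                    "is_hub": g in hubs,
                }
            )
    return pd.DataFrame(rows).set_index("gene_id")


def compare_eigengene_groups(E: pd.DataFrame, annotation: pd.DataFrame, adjust: str = "bh") -> pd.DataFrame:
    """Pairwise Student t-tests between the four groups, BH within module."""
    from .simulate import group_label

    ann = annotation.set_index("sample_id").loc[E.columns]
    groups = pd.Series(
        [group_label(o, a) for o, a in zip(ann["origin"], ann["activation"])], index=E.columns
    )
    levels = sorted(groups.unique())
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    rows = []
    for m in E.index:
        y = E.loc[m]
        pvals = []
        for a, b in pairs:
            ya, yb = y[groups == a], y[groups == b]
            if len(ya) < 2 or len(yb) < 2:
                raise ValueError(f"group {a if len(ya) < 2 else b} has fewer than 2 samples")
            stat = ttest_ind(ya, yb, equal_var=True)
            diff = float(ya.mean() - yb.mean())
            pvals.append(stat.pvalue if np.isfinite(stat.pvalue) else 1.0)
            rows.append(
                {"module": m, "group1": a, "group2": b, "mean_diff": diff,
                 "t": float(stat.statistic) if np.isfinite(stat.statistic) else 0.0,
                 "p": pvals[-1]}
            )
        adj = adjust_pvalues(pvals, adjust)
        for off, val in enumerate(adj):
            rows[-len(pairs) + off]["p_adj"] = float(val)
    return pd.DataFrame(rows)


def annotate_druggability(hubs: pd.DataFrame, drug_table: pd.DataFrame) -> pd.DataFrame:
    """Left-join hub genes onto a local gene->drug table (case-insensitive).

    ``drug_table`` needs columns gene_id, drug, evidence.  Output has one
    row per hub-gene/drug pair (or one row with empty drug for undrugged
    hubs) and a ``druggable`` flag.
    """
    required = {"gene_id", "drug", "evidence"}
    if not required.issubset(drug_table.columns):
        raise ValueError(f"drug table must have columns {sorted(required)}")
    hub_genes = hubs.index[hubs["is_hub"]] if "is_hub" in hubs.columns else hubs.index
    left = pd.DataFrame({"gene_id": hub_genes, "_key": [g.upper() for g in hub_genes]})
    right = drug_table.assign(_key=drug_table["gene_id"].str.upper()).drop(columns="gene_id")
    merged = left.merge(right, on="_key", how="left").drop(columns="_key")
    merged["druggable"] = merged["drug"].notna()
    return merged
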