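"""Moderated differential expression for the paired 2x2 design.

The model is ``expression ~ 0 + group`` with the four groups formed by
concatenating origin and activation (NECneg, NECpos, TECneg, TECpos).
Pairing of fractions from the same subject is absorbed by a single
consensus within-subject correlation: each gene is fitted by generalised
least squares under within-block equicorrelation, residual variances are
shrunk towards a common prior fitted by moment matching on the
log-variances, and contrasts are tested with moderated t-statistics on the
augmented degrees of freedom.  Multiple testing is controlled by
Benjamini-Hochberg (Hochberg's step-up is available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist, trim_mean
from statsmodels.stats.multitest import multipletests

GROUP_ORDER = ("NECneg", "NECpos", "TECneg", "TECpos")


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Step-up multiple-testing adjustment ('bh' or 'hochberg')."""
    codes = {"bh": "fdr_bh", "hochberg": "simes-hochberg"}
    if method not in codes:
        raise ValueError(f"unknown adjustment {method!r}")
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method=codes[method])[1]
    return out


@dataclass
class DesignSpec:
    """Group factor, subject blocking, and named contrasts for a cohort."""

    group: pd.Series  # per-sample group label
    block: pd.Series  # per-sample subject id
    contrasts: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group.index.equals(self.block.index):
            raise ValueError("group and block must be indexed by the same samples")
        for name, c in self.contrasts.items():
            if abs(float(np.sum(c))) > 1e-12:
                raise ValueError(f"contrast {name!r} weights do not sum to 0")

    @property
    def levels(self) -> list[str]:
        present = pd.unique(self.group)
        ordered = [g for g in GROUP_ORDER if g in set(present)]
        extra = sorted(set(present) - set(ordered))
        return ordered + extra

    def design_matrix(self) -> pd.DataFrame:
        """Cell-means coding: one indicator column per group level."""
        levels = self.levels
        M = pd.DataFrame(0.0, index=self.group.index, columns=levels)
        for lvl in levels:
            M.loc[self.group == lvl, lvl] = 1.0
        return M

    def contrast_vector(self, name: str) -> np.ndarray:
        c = self.contrasts[name]
        return np.array([float(c.get(lvl, 0.0)) for lvl in self.levels])

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame, contrasts: dict | None = None) -> "DesignSpec":
        from .simulate import group_label

        idx = pd.Index(annotation["sample_id"])
        group = pd.Series(
            [group_label(o, a) for o, a in zip(annotation["origin"], annotation["activation"])],
            index=idx,
            name="group",
        )
        block = pd.Series(annotation["subject_id"].to_numpy(), index=idx, name="block")
        if contrasts is None:
            contrasts = default_contrasts()
        contrasts = {k: pd.Series(v) for k, v in contrasts.items()}
        return cls(group=group, block=block, contrasts=contrasts)


def default_contrasts() -> dict[str, pd.Series]:
    """Pairwise level differences of common interest."""
    return {
        "TECneg_vs_NECneg": pd.Series({"TECneg": 1.0, "NECneg": -1.0}),
        "TECpos_vs_NECpos": pd.Series({"TECpos": 1.0, "NECpos": -1.0}),
        "NECpos_vs_NECneg": pd.Series({"NECpos": 1.0, "NECneg": -1.0}),
        "TECpos_vs_TECneg": pd.Series({"TECpos": 1.0, "TECneg": -1.0}),
    }


@dataclass
class ModeratedFit:
    """Per-gene GLS fit plus empirical-Bayes moderation state."""

    coefficients: pd.DataFrame  # genes x levels
    sigma2: pd.Series  # residual variance per gene
    df_resid: float
    cov_coef: pd.DataFrame  # unscaled (X' V^-1 X)^-1
    rho: float
    design: DesignSpec
    d0: float | None = None
    s0_2: float | None = None
    tests: dict[str, pd.DataFrame] = field(default_factory=dict)

    def posterior_variance(self) -> pd.Series:
        if self.d0 is None:
            raise RuntimeError("call moderate_and_test first")
        if np.isinf(self.d0):
            return pd.Series(self.s0_2, index=self.sigma2.index)
        return (self.d0 * self.s0_2 + self.df_resid * self.sigma2) / (self.d0 + self.df_resid)


def _block_sizes(block: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(block)
    sizes = np.bincount(codes)
    return codes, sizes


def estimate_consensus_correlation(
    X: pd.DataFrame, design: DesignSpec, trim: float = 0.1, grid_size: int = 241
) -> float:
    """Consensus within-subject correlation of the cohort.

    Per gene, the intraclass correlation of a random-intercept model is
    estimated on the residuals from the group-means fit by profiled REML
    over a grid (parabolically refined); the consensus is the 10% trimmed
    mean on the Fisher-z scale, clamped to (-0.99, 0.99).
    """
    codes, sizes = _block_sizes(design.block)
    if (sizes >= 2).sum() < 2:
        warnings.warn("fewer than 2 blocks with >=2 samples; consensus set to 0", RuntimeWarning)
        return 0.0
    M = design.design_matrix().to_numpy()
    Y = X.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(M, Y.T, rcond=None)
    R = Y - (M @ beta).T  # genes x samples residuals

    n = R.shape[1]
    q = sizes.size
    B = np.zeros((n, q))
    B[np.arange(n), codes] = 1.0
    S2 = (R @ B) ** 2  # squared block sums, genes x blocks
    SS = (R**2).sum(axis=1)

    rhos = np.linspace(-0.2, 0.99, grid_size)
    gammas = rhos / (1 - rhos)
    # c_b(rho) = gamma / (1 + gamma * n_b); quadratic form q_g = SS - sum_b c_b S_gb^2
    C = gammas[:, None] / (1 + gammas[:, None] * sizes[None, :])  # grid x blocks
    logdet = np.log1p(gammas[:, None] * sizes[None, :]).sum(axis=1)  # grid
    Q = SS[:, None] - S2 @ C.T  # genes x grid
    Q = np.maximum(Q, 1e-300)
    ll = -0.5 * (n * np.log(Q / n) + logdet[None, :])  # genes x grid

    best = np.argmax(ll, axis=1)
    rho_hat = rhos[best].copy()
    # parabolic refinement on interior maxima
    interior = (best > 0) & (best < grid_size - 1)
    i = best[interior]
    y0, y1, y2 = (
        ll[interior, i - 1],
        ll[interior, i],
        ll[interior, i + 1],
    )
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
    step = rhos[1] - rhos[0]
    rho_hat[interior] = rhos[i] + np.clip(shift, -1, 1) * step

    z = np.arctanh(np.clip(rho_hat, -0.98, 0.989))
    consensus = float(np.tanh(trim_mean(z, proportiontocut=trim)))
    return float(np.clip(consensus, -0.99, 0.99))


def _whitening_matrix(block: pd.Series, rho: float) -> np.ndarray:
    """Block-diagonal V^{-1/2} for within-block equicorrelation rho."""
    codes, sizes = _block_sizes(block)
    n = len(codes)
    W = np.zeros((n, n))
    for b, m in enumerate(sizes):
        idx = np.flatnonzero(codes == b)
        if 1 + (m - 1) * rho <= 0 or 1 - rho <= 0:
            raise ValueError(f"rho={rho} makes a block covariance non-positive-definite")
        a = 1.0 / np.sqrt(1 - rho)
        c = 1.0 / np.sqrt(1 + (m - 1) * rho)
        Jm = np.full((m, m), 1.0 / m)
        W[np.ix_(idx, idx)] = a * (np.eye(m) - Jm) + c * Jm
    return W


def fit_group_means(X: pd.DataFrame, design: DesignSpec, rho: float = 0.0) -> ModeratedFit:
    """Per-gene GLS fit of the cell-means model under equicorrelation ``rho``."""
    M = design.design_matrix()
    W = _whitening_matrix(design.block, rho)
    Xt = W @ M.to_numpy()
    if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = X[M.index].to_numpy(dtype=float)
    Yt = Y @ W.T
    XtX = Xt.T @ Xt
    XtXi = np.linalg.inv(XtX)
    coef = Yt @ Xt @ XtXi.T  # genes x levels
    resid = Yt - coef @ Xt.T
    n, p = Xt.shape
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    return ModeratedFit(
        coefficients=pd.DataFrame(coef, index=X.index, columns=M.columns),
        sigma2=pd.Series(sigma2, index=X.index, name="sigma2"),
        df_resid=float(df),
        cov_coef=pd.DataFrame(XtXi, index=M.columns, columns=M.columns),
        rho=float(rho),
        design=design,
    )


def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the inverse-chi-square variance prior.

    Returns ``(d0, s0_2)``: prior degrees of freedom (may be ``inf``) and
    prior variance, from the mean and excess variance of the log sample
    variances with digamma/trigamma corrections.
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2)
    if evar > 0:
        y = _trigamma_inverse(evar)
        d0 = 2 * y
        s0_2 = np.exp(emean + digamma(y) - np.log(y))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def moderate_and_test(
    fit: ModeratedFit,
    contrast: str,
    d0_override: float | None = None,
    adjust: str = "bh",
    lfc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t-test of a named contrast; appends the table to ``fit.tests``.

    The DE flag is |log2FC| > ``lfc_threshold`` and adjusted p < ``alpha``.
    """
    n_genes = len(fit.sigma2)
    if fit.d0 is None:
        if d0_override is not None:
            fit.d0 = float(d0_override)
            fit.s0_2 = float(np.maximum(fit.sigma2.mean(), 1e-12))
        elif n_genes < 10:
            warnings.warn("too few genes for stable prior estimation; using d0=0", RuntimeWarning)
            fit.d0, fit.s0_2 = 0.0, float(np.maximum(fit.sigma2.mean(), 1e-12))
        else:
            fit.d0, fit.s0_2 = squeeze_variances(fit.sigma2.to_numpy(), fit.df_resid)
    c = fit.design.contrast_vector(contrast)
    lfc = fit.coefficients.to_numpy() @ c
    se_unscaled = float(np.sqrt(c @ fit.cov_coef.to_numpy() @ c))
    s2_post = fit.posterior_variance().to_numpy()
    se = se_unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    df_total = fit.df_resid + fit.d0
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2 * norm.sf(np.abs(t))
    else:
        p = 2 * t_dist.sf(np.abs(t), df_total)
    p_adj = adjust_pvalues(p, adjust)
    table = pd.DataFrame(
        {
            "log2FC": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "de_flag": (np.abs(lfc) > lfc_threshold) & (p_adj < alpha),
        },
        index=fit.coefficients.index,
    )
    fit.tests[contrast] = table
    return table
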