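"""Probe summarisation, two-Gaussian expression filtering, sample-network outliers.

Low-expression filtering assumes the pooled log2 intensity distribution is a
mixture of two Gaussians — a background component and an expressed
component.  The filter threshold is the smallest point between the component
means where the posterior probability of the expressed component reaches
0.5; genes whose maximum over samples stays below it are dropped.  Outlier
arrays are flagged by their z-normalised inter-sample connectivity zK (sum
of correlations to all other samples, z-scored across samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, iqr
from sklearn.mixture import GaussianMixture


@dataclass
class TwoGaussianFit:
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    weight_low: float
    threshold: float
    converged: bool
    n_iterations: int

    def posterior_high(self, x):
        """Posterior probability that a value belongs to the expressed component."""
        x = np.asarray(x, dtype=float)
        lo = (1 - self.weight_low) * norm.pdf(x, self.mu_high, self.sigma_high)
        hi = self.weight_low * norm.pdf(x, self.mu_low, self.sigma_low)
        return lo / (lo + hi)


@dataclass
class OutlierReport:
    zk: pd.Series
    excluded_samples: list[str]
    zk_threshold: float = 1.96
    one_sided: bool = True


def summarize_probes(probes: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with maximal interquartile range across samples
    is kept; ties are broken by lexicographic probe id.  Probes without a
    mapping are dropped.
    """
    probe_to_gene = probe_to_gene.dropna()
    mapped = probes.index.intersection(probe_to_gene.index)
    if len(mapped) == 0:
        raise ValueError("no probe maps to a gene")
    sub = probes.loc[mapped]
    spread = pd.Series(iqr(sub.to_numpy(), axis=1), index=sub.index)
    table = pd.DataFrame(
        {"gene": probe_to_gene.loc[mapped].to_numpy(), "iqr": spread, "probe": sub.index}
    )
    # highest IQR first, then lexicographic probe id for ties
    table = table.sort_values(["gene", "iqr", "probe"], ascending=[True, False, True], kind="stable")
    best = table.drop_duplicates("gene", keep="first")
    out = sub.loc[best["probe"]]
    out.index = pd.Index(best["gene"].to_numpy(), name="gene_id")
    return out.sort_index()


def fit_two_gaussian(values, seed: int = 0, max_iter: int = 500, tol: float = 1e-8) -> TwoGaussianFit:
    """EM fit of a 2-component Gaussian mixture to pooled log2 intensities.

    The filter threshold is the smallest point between the component means
    where the posterior probability of the high (expressed) component
    reaches 0.5, located by a grid scan refined with a root finder.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 values to fit the mixture")
    if np.ptp(x) == 0:
        raise ValueError("values have zero spread; mixture fit is degenerate")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="diag",
        init_params="kmeans",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
        n_init=1,
        reg_covar=1e-10,
    ).fit(x[:, None])
    if not gm.converged_:
        warnings.warn("mixture EM did not converge; returning best fit", RuntimeWarning)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = int(np.argmin(means)), int(np.argmax(means))
    fit = TwoGaussianFit(
        mu_low=float(means[lo]),
        mu_high=float(means[hi]),
        sigma_low=float(sds[lo]),
        sigma_high=float(sds[hi]),
        weight_low=float(weights[lo]),
        threshold=np.nan,
        converged=bool(gm.converged_),
        n_iterations=int(gm.n_iter_),
    )
    fit.threshold = _posterior_threshold(fit)
    return fit


def _posterior_threshold(fit: TwoGaussianFit, n_grid: int = 2001) -> float:
    """Smallest point in (mu_low, mu_high) with posterior(high) >= 0.5."""

    def f(x):
        return (1 - fit.weight_low) * norm.pdf(x, fit.mu_high, fit.sigma_high) - fit.weight_low * norm.pdf(
            x, fit.mu_low, fit.sigma_low
        )

    grid = np.linspace(fit.mu_low, fit.mu_high, n_grid)
    sign = f(grid) >= 0
    cross = np.flatnonzero(sign[1:] != sign[:-1])
    if cross.size == 0:
        # posterior never crosses 0.5 strictly inside: fall back to midpoint
        return float(0.5 * (fit.mu_low + fit.mu_high))
    i = int(cross[0])
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-12))


def filter_low_expression(X: pd.DataFrame, fit: TwoGaussianFit | float) -> pd.DataFrame:
    """Drop genes whose maximum over samples falls below the mixture threshold."""
    threshold = fit.threshold if isinstance(fit, TwoGaussianFit) else float(fit)
    keep = X.max(axis=1) >= threshold
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    return X.loc[keep]


def sample_connectivity(X: pd.DataFrame, method: str = "pearson") -> pd.Series:
    """Inter-sample connectivity k_i = sum of correlations to all other samples."""
    V = X.to_numpy(dtype=float)
    sds = V.std(axis=0)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant sample(s); their correlations are set to 0",
            RuntimeWarning,
        )
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(V, rowvar=False)
    elif method == "spearman":
        from scipy.stats import rankdata

        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(rankdata(V, axis=0), rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 0.0)
    return pd.Series(C.sum(axis=0), index=X.columns, name="k")


def sample_outliers(
    X: pd.DataFrame,
    zk_threshold: float = 1.96,
    one_sided: bool = True,
    method: str = "pearson",
) -> OutlierReport:
    """Flag low-connectivity arrays by z-normalised inter-sample connectivity.

    By default only the low tail (zK < -threshold) is excluded; the
    two-sided |zK| > threshold rule is available with ``one_sided=False``.
    """
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples for outlier detection")
    k = sample_connectivity(X, method=method)
    sd = k.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(k.abs().max())):  # all-equal up to float jitter
        zk = pd.Series(np.zeros(len(k)), index=k.index, name="zk")
        return OutlierReport(zk=zk, excluded_samples=[], zk_threshold=zk_threshold, one_sided=one_sided)
    zk = ((k - k.mean()) / sd).rename("zk")
    if one_sided:
        bad = zk.index[zk < -zk_threshold]
    else:
        bad = zk.index[zk.abs() > zk_threshold]
    return OutlierReport(
        zk=zk, excluded_samples=sorted(bad), zk_threshold=zk_threshold, one_sided=one_sided
    )
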