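"""Synthetic cohorts, expression matrices, gene sets and a toy ontology.

The generator emulates the structure of a paired 2x2 microarray study of
liver endothelial cells: each subject contributes up to four cell fractions
(origin: non-tumour vs tumour, crossed with angiogenic activation: ENG- vs
ENG+), some fractions are missing, the pooled log2 expression distribution
is a two-Gaussian mixture (low "background" component plus an expressed
component), a handful of gene modules share a planted eigengene that carries
origin and/or activation effects on top of a subject-specific random
intercept, and a few samples are replaced by independent noise so that they
show up as low-connectivity outliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"

#: order of the four cell fractions (origin x activation)
FRACTIONS = (
    ("non-tumour", "ENG-"),
    ("non-tumour", "ENG+"),
    ("tumour", "ENG-"),
    ("tumour", "ENG+"),
)

GROUP_LABELS = {
    ("non-tumour", "ENG-"): "NECneg",
    ("non-tumour", "ENG+"): "NECpos",
    ("tumour", "ENG-"): "TECneg",
    ("tumour", "ENG+"): "TECpos",
}


def group_label(origin: str, activation: str) -> str:
    return GROUP_LABELS[(origin, activation)]


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults mirror the emulated study design: 16 subjects, four fractions
    with per-fraction missingness chosen so that the used-array counts are
    (15, 8, 14, 6) — ENG+ fractions were collected for only half of the
    subjects, which is folded into the missing probabilities.  Effects are
    in log2 units on the module eigengene.
    """

    n_subjects: int = 16
    # per-fraction probability of a missing array, order as FRACTIONS
    fraction_missing: tuple[float, ...] | float = (1 / 16, 0.5, 2 / 16, 10 / 16)
    missingness: str = "exact"  # "exact": round(p*n) dropped; "bernoulli": iid
    n_modules: int = 6
    module_sizes: tuple[int, ...] = (40, 60, 80, 100, 120, 100)
    origin_effects: tuple[float, ...] = (2.0, 0.0, -1.5, 1.0, 0.0, 1.0)
    activation_effects: tuple[float, ...] = (0.0, 1.5, 0.5, 0.0, -1.0, 1.0)
    subject_sd: float = 0.5
    noise_sd: float = 0.3
    eigengene_sd: float = 1.0
    loading_range: tuple[float, float] = (0.7, 1.0)
    background_low_mean: float = 4.0
    background_high_mean: float = 8.0
    background_sd: float = 1.0
    background_high_weight: float = 0.5
    n_background_genes: int = 1500
    n_outlier_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if len(self.origin_effects) != self.n_modules or len(self.activation_effects) != self.n_modules:
            raise ValueError("effect vectors must have one entry per module")
        for name in ("subject_sd", "noise_sd", "eigengene_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie within (0, 1]")
        if self.missingness not in ("exact", "bernoulli"):
            raise ValueError("missingness must be 'exact' or 'bernoulli'")

    def streams(self) -> dict[str, np.random.Generator]:
        """Deterministic per-stage random streams derived from the one seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("cohort", "expression", "genesets")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    true_module_of_gene: dict[str, str]
    true_eigengene_matrix: pd.DataFrame  # modules x samples
    planted_effects: dict[str, tuple[float, float]]  # module -> (origin, activation)
    outlier_sample_ids: list[str]

    def to_json(self, path) -> None:
        payload = {
            "true_module_of_gene": self.true_module_of_gene,
            "true_eigengene_matrix": {
                "modules": list(self.true_eigengene_matrix.index),
                "samples": list(self.true_eigengene_matrix.columns),
                "values": self.true_eigengene_matrix.to_numpy().tolist(),
            },
            "planted_effects": {k: list(v) for k, v in self.planted_effects.items()},
            "outlier_sample_ids": self.outlier_sample_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the sample annotation table (sample_id, subject_id, origin, activation).

    Each subject contributes up to four fractions; missingness is applied per
    fraction, either as an exact count of dropped subjects (default, so the
    group sizes reproduce the design pattern) or as independent Bernoulli
    draws.  Raises if any of the four groups would end up empty.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = config.streams()["cohort"]
    p_missing = config.fraction_missing
    if np.isscalar(p_missing):
        p_missing = (float(p_missing),) * 4

    rows = []
    suffix = {"NECneg": "N0", "NECpos": "N1", "TECneg": "T0", "TECpos": "T1"}
    for f_idx, (origin, activation) in enumerate(FRACTIONS):
        p = p_missing[f_idx]
        if config.missingness == "exact":
            n_miss = int(round(p * config.n_subjects))
            missing = set(rng.choice(config.n_subjects, size=n_miss, replace=False))
        else:
            missing = set(np.flatnonzero(rng.random(config.n_subjects) < p))
        for s in range(config.n_subjects):
            if s in missing:
                continue
            subject = f"P{s + 1:02d}"
            g = group_label(origin, activation)
            rows.append(
                {
                    "sample_id": f"{subject}_{suffix[g]}",
                    "subject_id": subject,
                    "origin": origin,
                    "activation": activation,
                }
            )
    annotation = pd.DataFrame(rows)
    counts = annotation.groupby(["origin", "activation"]).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("missingness removed an entire group")
    # stable, design-ordered sample order: by subject then fraction
    annotation = annotation.sort_values("sample_id", kind="stable").reset_index(drop=True)
    return annotation


def _module_ids(n: int) -> list[str]:
    return [f"M{i + 1}" for i in range(n)]


def simulate_expression(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the log2 expression matrix (genes x samples) plus ground truth.

    Module eigengene for module m:
        e_m(sample) = beta1_m * origin01 + beta2_m * activation01
                      + subject intercept (sd ``subject_sd``)
                      + eigengene residual (sd ``eigengene_sd``)
    Module gene g: baseline_g (high-component Gaussian) + loading_g * e_m
    + N(0, noise_sd) per entry.  Background genes get a baseline from the
    low-expression Gaussian plus entry noise.  Outlier samples are fully
    replaced by i.i.d. noise, destroying their correlation to every other
    sample.
    """
    required = {"sample_id", "subject_id", "origin", "activation"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    rng = config.streams()["expression"]
    samples = annotation["sample_id"].to_numpy()
    n_samples = len(samples)
    origin01 = (annotation["origin"] == "tumour").to_numpy(float)
    activation01 = (annotation["activation"] == "ENG+").to_numpy(float)
    subjects = annotation["subject_id"].to_numpy()
    subject_levels = pd.unique(subjects)

    modules = _module_ids(config.n_modules)
    n_module_genes = int(np.sum(config.module_sizes)) if config.n_modules else 0
    n_genes = n_module_genes + config.n_background_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    values = np.empty((n_genes, n_samples))
    truth_map: dict[str, str] = {}
    eig = np.zeros((config.n_modules, n_samples))

    subject_intercepts = rng.normal(0.0, config.subject_sd, size=(config.n_modules, len(subject_levels)))
    subj_index = pd.Series(np.arange(len(subject_levels)), index=subject_levels)
    subj_col = subj_index[subjects].to_numpy()

    row = 0
    for m_idx, m in enumerate(modules):
        size = config.module_sizes[m_idx]
        e = (
            config.origin_effects[m_idx] * origin01
            + config.activation_effects[m_idx] * activation01
            + subject_intercepts[m_idx, subj_col]
            + rng.normal(0.0, config.eigengene_sd, size=n_samples)
        )
        eig[m_idx] = e
        baselines = rng.normal(config.background_high_mean, config.background_sd, size=size)
        loadings = rng.uniform(*config.loading_range, size=size)
        noise = rng.normal(0.0, config.noise_sd, size=(size, n_samples))
        values[row : row + size] = baselines[:, None] + loadings[:, None] * e[None, :] + noise
        for g in gene_ids[row : row + size]:
            truth_map[g] = m
        row += size

    if config.n_background_genes:
        # bimodal background: a low (unexpressed) and a high (expressed but
        # uncorrelated) component; the latter are the network's noise genes
        high = rng.random(config.n_background_genes) < config.background_high_weight
        means = np.where(high, config.background_high_mean, config.background_low_mean)
        baselines = rng.normal(means, config.background_sd)
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_background_genes, n_samples))
        values[row:] = baselines[:, None] + noise
        for g in gene_ids[row:]:
            truth_map[g] = UNASSIGNED

    outlier_ids: list[str] = []
    if config.n_outlier_samples:
        if config.n_outlier_samples >= n_samples:
            raise ValueError("cannot replace every sample with noise")
        picks = rng.choice(n_samples, size=config.n_outlier_samples, replace=False)
        for j in picks:
            values[:, j] = rng.normal(config.background_high_mean, config.background_sd, size=n_genes)
            outlier_ids.append(samples[j])

    X = pd.DataFrame(values, index=gene_ids, columns=samples)
    truth = SyntheticTruth(
        true_module_of_gene=truth_map,
        true_eigengene_matrix=pd.DataFrame(eig, index=modules, columns=samples),
        planted_effects={
            m: (config.origin_effects[i], config.activation_effects[i]) for i, m in enumerate(modules)
        },
        outlier_sample_ids=sorted(outlier_ids),
    )
    return X, truth


def simulate_genesets_and_ontology(
    config: SimulationConfig,
    truth: SyntheticTruth,
    n_decoy_sets: int = 5,
    decoy_size: int = 50,
):
    """One gene set per planted module plus random decoy sets, and a toy GO-like DAG.

    Returns ``(genesets, dag, annotations)`` where ``genesets`` maps set name
    to a gene list, ``dag`` is a networkx MultiDiGraph with child->parent
    edges keyed ``is_a``/``part_of`` (the in-memory form an OBO reader
    produces), and ``annotations`` maps gene -> set of directly annotated
    term ids.  Per planted module one leaf term is annotated with exactly the
    module's genes; remaining leaves get random genes, so that enrichment of
    a module is concentrated in its matching leaf and its ancestors.
    """
    import networkx as nx

    rng = config.streams()["genesets"]
    genes = sorted(truth.true_module_of_gene)
    module_genes: dict[str, list[str]] = {}
    for g, m in truth.true_module_of_gene.items():
        if m != UNASSIGNED:
            module_genes.setdefault(m, []).append(g)
    for m in module_genes:
        module_genes[m].sort()

    genesets: dict[str, list[str]] = {f"SET_{m}": gs for m, gs in sorted(module_genes.items())}
    for d in range(n_decoy_sets):
        size = min(decoy_size, len(genes))
        picks = rng.choice(len(genes), size=size, replace=False)
        genesets[f"DECOY_{d + 1}"] = sorted(genes[i] for i in picks)

    # toy ontology: one root, ~10 internal terms, ~30 leaves
    dag = nx.MultiDiGraph()
    root = "TOY:0000001"
    dag.add_node(root, name="biological_process", namespace="biological_process")
    n_internal, n_leaves = 10, 30
    internal = [f"TOY:{i + 2:07d}" for i in range(n_internal)]
    leaves = [f"TOY:{i + 2 + n_internal:07d}" for i in range(n_leaves)]
    for i, t in enumerate(internal):
        dag.add_node(t, name=f"internal process {i + 1}", namespace="biological_process")
        dag.add_edge(t, root, key="is_a")
    for i, t in enumerate(leaves):
        dag.add_node(t, name=f"leaf process {i + 1}", namespace="biological_process")
        parent = internal[i % n_internal]
        dag.add_edge(t, parent, key="is_a")
        if i % 5 == 0:  # sprinkle part_of edges to a second parent
            other = internal[(i // 5) % n_internal]
            if other != parent:
                dag.add_edge(t, other, key="part_of")

    annotations: dict[str, set[str]] = {}
    module_names = sorted(module_genes)
    for i, m in enumerate(module_names):
        leaf = leaves[i]
        for g in module_genes[m]:
            annotations.setdefault(g, set()).add(leaf)
    for leaf in leaves[len(module_names) :]:
        size = min(25, len(genes))
        for idx in rng.choice(len(genes), size=size, replace=False):
            annotations.setdefault(genes[idx], set()).add(leaf)
    return genesets, dag, annotations
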