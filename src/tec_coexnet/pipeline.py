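"""End-to-end orchestration of the co-expression workflow.

Stages: simulate (optional) -> preprocess -> dge -> gsva -> network ->
associate -> enrich.  Every intermediate is persisted as TSV/JSON in the
output directory, counts are logged after every filter, and a manifest
records the package version, the full configuration and the SHA256 of all
external inputs, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import (
    compare_eigengene_groups,
    fit_eigengene_model,
    intramodular_connectivity,
    select_modules,
)
from .coexnet import NetworkConfig, correlation_matrix, iterative_wgcna, signed_adjacency
from .diffexpr import DesignSpec, estimate_consensus_correlation, fit_group_means, moderate_and_test
from .enrichment import enrich, reduce_terms
from .gsva import differential_pathways, gsva_scores
from .preprocess import filter_low_expression, fit_two_gaussian, sample_outliers
from .simulate import SimulationConfig, simulate_cohort, simulate_expression, simulate_genesets_and_ontology

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_preprocess: bool = True
    run_dge: bool = True
    run_gsva: bool = True
    run_network: bool = True
    run_associate: bool = True
    run_enrich: bool = True
    # inputs when simulation is off
    expression_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    obo_path: str | None = None
    gene_terms_path: str | None = None
    # stage parameter blocks
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {"zk_threshold": 1.96, "one_sided": True})
    dge: dict = field(default_factory=lambda: {"lfc_threshold": 2.0, "alpha": 0.05})
    network: dict = field(default_factory=dict)
    associate: dict = field(default_factory=lambda: {"hub_fraction": 0.1, "mm_threshold": 0.8})
    enrich: dict = field(
        default_factory=lambda: {
            "min_size": 15, "max_size": 500, "epsilon": 0.6,
            "min_neighbors": 5, "embedding": "umap",
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recorded = config.to_dict()
    recorded["out_dir"] = ""  # a run location, not part of the scientific config
    manifest: dict = {"version": __version__, "config": recorded, "stages": {}, "inputs": {}}

    # ---------------- simulate / load ----------------
    if config.run_simulate:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulate})
        annotation = simulate_cohort(sim_cfg)
        X, truth = simulate_expression(sim_cfg, annotation)
        genesets, dag, gene_terms = simulate_genesets_and_ontology(sim_cfg, truth)
        io.write_annotation(annotation, out / "annotation.tsv")
        io.write_expression(X, out / "expression.tsv")
        truth.to_json(out / "truth.json")
        io.write_gmt(genesets, out / "genesets.gmt")
        io.write_obo(dag, out / "ontology.obo")
        io.write_gene_terms(gene_terms, out / "gene_terms.tsv")
        manifest["stages"]["simulate"] = {"n_genes": int(len(X)), "n_samples": int(X.shape[1])}
        log.info("simulate: %d genes x %d samples", len(X), X.shape[1])
    else:
        if not config.expression_path or not config.annotation_path:
            raise ValueError("expression_path and annotation_path are required when simulate is off")
        X = io.read_expression(config.expression_path)
        annotation = io.read_annotation(config.annotation_path)
        genesets = io.read_gmt(config.gmt_path) if config.gmt_path else None
        dag = io.read_obo(config.obo_path) if config.obo_path else None
        gene_terms = io.read_gene_terms(config.gene_terms_path) if config.gene_terms_path else None
        for key in ("expression_path", "annotation_path", "gmt_path", "obo_path", "gene_terms_path"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = io.sha256(path)

    # ---------------- preprocess ----------------
    if config.run_preprocess:
        # outlier arrays first: their profiles are pure noise and would mask
        # the low-expression component of every gene they touch
        report = sample_outliers(
            X,
            zk_threshold=config.preprocess.get("zk_threshold", 1.96),
            one_sided=config.preprocess.get("one_sided", True),
        )
        Xc = X.drop(columns=report.excluded_samples)
        fit = fit_two_gaussian(Xc.to_numpy().ravel(), seed=config.seed)
        Xf = filter_low_expression(Xc, fit)
        annotation = annotation[~annotation["sample_id"].isin(report.excluded_samples)].reset_index(drop=True)
        io.write_json(
            {
                "mixture": {
                    "mu_low": fit.mu_low, "mu_high": fit.mu_high,
                    "sigma_low": fit.sigma_low, "sigma_high": fit.sigma_high,
                    "weight_low": fit.weight_low, "threshold": fit.threshold,
                    "converged": fit.converged, "n_iterations": fit.n_iterations,
                },
                "zk": report.zk.round(10).to_dict(),
                "excluded_samples": report.excluded_samples,
            },
            out / "preprocess_report.json",
        )
        io.write_expression(Xf, out / "expression_filtered.tsv")
        io.write_annotation(annotation, out / "annotation_filtered.tsv")
        manifest["stages"]["preprocess"] = {
            "threshold": fit.threshold,
            "n_genes_retained": int(len(Xf)),
            "n_samples_retained": int(Xf.shape[1]),
            "excluded_samples": report.excluded_samples,
        }
        log.info(
            "preprocess: threshold %.3f, %d genes and %d samples retained",
            fit.threshold, len(Xf), Xf.shape[1],
        )
        X = Xf

    design = DesignSpec.from_annotation(annotation)

    # ---------------- differential expression ----------------
    if config.run_dge:
        rho = estimate_consensus_correlation(X, design)
        fit = fit_group_means(X, design, rho=rho)
        n_de = {}
        for name in design.contrasts:
            table = moderate_and_test(
                fit,
                name,
                lfc_threshold=config.dge.get("lfc_threshold", 2.0),
                alpha=config.dge.get("alpha", 0.05),
            )
            table.rename_axis("gene_id").to_csv(out / f"dge_{name}.tsv", sep="\t")
            n_de[name] = int(table["de_flag"].sum())
        manifest["stages"]["dge"] = {"consensus_correlation": rho, "n_de": n_de}
        log.info("dge: consensus correlation %.3f, DE counts %s", rho, n_de)

    # ---------------- gene-set scoring ----------------
    if config.run_gsva and genesets:
        scores = gsva_scores(X, genesets)
        io.write_expression(scores.rename_axis("set"), out / "gsva_scores.tsv")
        score_rho = estimate_consensus_correlation(scores, design)
        _, tables = differential_pathways(scores, design, rho=score_rho)
        n_sig = {}
        for name, table in tables.items():
            table.rename_axis("set").to_csv(out / f"gsva_{name}.tsv", sep="\t")
            n_sig[name] = int(table["significant"].sum())
        manifest["stages"]["gsva"] = {
            "n_sets": int(len(scores)),
            "consensus_correlation": score_rho,
            "n_significant": n_sig,
        }
        log.info("gsva: %d sets scored, significant %s", len(scores), n_sig)

    # ---------------- network ----------------
    assignment = eigengenes = kme = None
    if config.run_network:
        net_cfg = NetworkConfig(**config.network)
        assignment, eigengenes, kme = iterative_wgcna(X, net_cfg)
        modules_table = pd.DataFrame({"module": assignment.module_of_gene})
        own_kme = [
            kme.at[g, m] if m in kme.columns else np.nan
            for g, m in assignment.module_of_gene.items()
        ]
        modules_table["kME"] = own_kme
        modules_table.rename_axis("gene_id").to_csv(out / "modules.tsv", sep="\t")
        eigengenes.rename_axis("module").to_csv(out / "eigengenes.tsv", sep="\t")
        with open(out / "network_config.yaml", "w") as fh:
            yaml.safe_dump(net_cfg.to_dict(), fh)
        sizes = assignment.module_sizes
        manifest["stages"]["network"] = {
            "n_modules": int(len(sizes)),
            "module_sizes": {str(k): int(v) for k, v in sizes.items()},
            "n_iterations": len(assignment.iteration_history),
            "converged": bool(assignment.converged),
        }
        log.info("network: %d modules, sizes %s", len(sizes), sizes.to_dict())

    # ---------------- association ----------------
    if config.run_associate:
        if assignment is None or eigengenes is None or len(eigengenes) == 0:
            raise RuntimeError("association requires the network stage (no modules available)")
        result = fit_eigengene_model(eigengenes, annotation)
        result.table.to_csv(out / "module_trait.tsv", sep="\t")
        selection = select_modules(kme, assignment, threshold=config.associate.get("mm_threshold", 0.8))
        selection.to_csv(out / "module_selection.tsv", sep="\t")
        pairwise = compare_eigengene_groups(eigengenes, annotation)
        pairwise.to_csv(out / "eigengene_pairwise.tsv", sep="\t", index=False)
        assigned = assignment.module_of_gene.index[assignment.module_of_gene != "unassigned"]
        A = signed_adjacency(
            correlation_matrix(X.loc[assigned], method=NetworkConfig(**config.network).correlation),
            beta=NetworkConfig(**config.network).beta,
        )
        hubs = intramodular_connectivity(A, assignment, hub_fraction=config.associate.get("hub_fraction", 0.1))
        drug_path = config.associate.get("drug_table")
        if drug_path:
            from .association import annotate_druggability

            drugs = pd.read_csv(drug_path, sep="\t", dtype=str)
            annotate_druggability(hubs, drugs).to_csv(out / "hub_drugs.tsv", sep="\t", index=False)
            manifest["inputs"]["drug_table"] = io.sha256(drug_path)
        hubs.to_csv(out / "hubs.tsv", sep="\t")
        manifest["stages"]["associate"] = {
            "n_selected_modules": int(selection["selected"].sum()),
            "n_hub_genes": int(hubs["is_hub"].sum()),
        }
        log.info(
            "associate: %d modules selected, %d hub genes",
            int(selection["selected"].sum()), int(hubs["is_hub"].sum()),
        )

    # ---------------- enrichment ----------------
    if config.run_enrich:
        if assignment is None:
            raise RuntimeError("enrichment requires the network stage (no modules available)")
        if dag is None or gene_terms is None:
            raise RuntimeError("enrichment requires an ontology and gene annotations")
        background = set(X.index)
        sizes = assignment.module_sizes
        n_sig = {}
        for m in sizes.index:
            genes = set(assignment.genes_of(m))
            result = enrich(
                genes, background, gene_terms, dag=dag,
                min_size=config.enrich.get("min_size", 15),
                max_size=config.enrich.get("max_size", 500),
            )
            result.to_csv(out / f"enrichment_{m}.tsv", sep="\t")
            n_sig[m] = int(result["significant"].sum()) if len(result) else 0
            if n_sig[m]:
                clusters = reduce_terms(
                    result, dag,
                    epsilon=config.enrich.get("epsilon", 0.6),
                    min_neighbors=config.enrich.get("min_neighbors", 5),
                    seed=config.seed,
                    embedding=config.enrich.get("embedding", "umap"),
                )
                clusters.to_csv(out / f"term_clusters_{m}.tsv", sep="\t")
        manifest["stages"]["enrich"] = {"n_significant_terms": {str(k): v for k, v in n_sig.items()}}
        log.info("enrich: significant terms per module %s", n_sig)

    io.write_json(manifest, out / "manifest.json")
    return manifest
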