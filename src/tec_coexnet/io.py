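"""Plain-text readers and writers for every pipeline artifact.

All tabular artifacts are TSV (expression: genes x samples with the gene id
in the first column), gene sets are GMT, the ontology is a minimal OBO
subset (id/name/namespace/is_a/relationship: part_of) read back with
obonet, and run metadata is JSON.
"""

from __future__ import annotations

import hashlib
import json

import networkx as nx
import pandas as pd

from .gsva import read_gmt, write_gmt  # noqa: F401  (re-exported)


def read_expression(path) -> pd.DataFrame:
    X = pd.read_csv(path, sep="\t", index_col=0)
    X.index.name = "gene_id"
    return X


def write_expression(X: pd.DataFrame, path) -> None:
    X.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "origin", "activation"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation is missing columns {sorted(missing)}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"}.issubset(table.columns):
        raise ValueError("probe map needs columns probe_id, gene_id")
    return table.set_index("probe_id")["gene_id"]


def read_gene_terms(path) -> dict[str, set[str]]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(table.columns):
        raise ValueError("annotation map needs columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for gene, term in zip(table["gene_id"], table["term_id"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_gene_terms(ann: dict[str, set[str]], path) -> None:
    rows = [(g, t) for g in sorted(ann) for t in sorted(ann[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def write_obo(dag: nx.MultiDiGraph, path) -> None:
    """Serialise a toy ontology graph as a minimal OBO file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for term in sorted(dag.nodes):
            data = dag.nodes[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {data.get('name', term)}\n")
            if "namespace" in data:
                fh.write(f"namespace: {data['namespace']}\n")
            for _, parent, key in sorted(dag.out_edges(term, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent} ! {dag.nodes[parent].get('name', parent)}\n")
                elif key == "part_of":
                    fh.write(f"relationship: part_of {parent} ! {dag.nodes[parent].get('name', parent)}\n")


def read_obo(path) -> nx.MultiDiGraph:
    import obonet

    return obonet.read_obo(path)


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
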