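"""Plain-text readers and writers for every pipeline artifact.

All tabular artifacts are tab-separated text; networks additionally export
to GraphML and SIF for Cytoscape-style viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexpr import SampleDesign

__all__ = [
    "read_matrix", "write_matrix",
    "read_design", "write_design",
    "read_annotation", "write_annotation", "read_gaf",
    "read_truth", "write_truth",
    "read_deg_table", "write_deg_table",
    "write_enrichment_table",
    "write_edge_list", "write_node_table",
    "write_graphml", "read_graphml", "write_sif",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample log2 expression matrix (TSV, first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f")


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column (sample, condition) TSV into a SampleDesign."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"design file {path} needs two columns (sample, condition)")
    return SampleDesign(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(design.items(), columns=["sample", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column (gene, category) TSV; one pair per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs two columns (gene, category)")
    return df.iloc[:, :2].set_axis(["gene", "category"], axis=1)


def write_annotation(category_map: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        (gene, cat)
        for gene in sorted(category_map)
        for cat in sorted(category_map[gene])
    ]
    pd.DataFrame(rows, columns=["gene", "category"]).to_csv(path, sep="\t", index=False)


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Minimal GAF 2.x reader: keeps only the object symbol (col 2, 0-based 1)
    and the GO id (col 5, 0-based 4)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5:
                rows.append((fields[1], fields[4]))
    return pd.DataFrame(rows, columns=["gene", "category"])


def read_truth(path: str | Path):
    from .simulate import TruthTable

    with open(path) as fh:
        return TruthTable.from_json_dict(json.load(fh))


def write_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "selected" in df:
        df["selected"] = df["selected"].astype(bool)
    return df


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = [
        (u, v, f"{d['weight']:.6f}", d["sign"])
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene1", "gene2", "r", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(net: nx.Graph, core_index: dict[str, int], path: str | Path) -> None:
    deg = dict(net.degree())
    n = net.number_of_nodes()
    rows = [
        (g, deg[g], (deg[g] / (n - 1)) if n > 1 else 0.0, core_index.get(g, 0))
        for g in sorted(net.nodes)
    ]
    pd.DataFrame(
        rows, columns=["gene", "degree", "degree_normalized", "core_index"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(net: nx.Graph, core_index: dict[str, int], path: str | Path) -> None:
    g = net.copy()
    for node in g.nodes:
        g.nodes[node]["core_index"] = int(core_index.get(node, 0))
        g.nodes[node]["degree"] = int(g.degree(node))
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(net: nx.Graph, path: str | Path) -> None:
    """SIF export: relation is 'pos' or 'neg'; isolated nodes on bare lines."""
    with open(path, "w") as fh:
        for u, v, d in sorted(net.edges(data=True)):
            rel = "pos" if d["sign"] == "positive" else "neg"
            fh.write(f"{u}\t{rel}\t{v}\n")
        for node in sorted(net.nodes):
            if net.degree(node) == 0:
                fh.write(f"{node}\n")
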