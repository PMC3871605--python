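"""Signed Pearson co-expression networks and differential hub ranking.

One undirected network is built per condition over a chosen gene set
(typically the DEG list): nodes are genes, and an edge joins two genes
whose Pearson correlation across that condition's samples exceeds a strict
magnitude threshold (default |r| > 0.999, an extremely stringent rule that
with 3-4 samples is nevertheless permissive in null data — see the methods
note).  Edges carry the signed r.  Hubs within one network are located by
raw degree ("link numbers") and k-core decomposition; candidate core
regulatory factors across conditions are ranked by the between-network
degree difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import SampleDesign

__all__ = [
    "KCoreAssignment",
    "pearson_matrix",
    "build_network",
    "degree_centrality",
    "kcore_decompose",
    "core_regulators",
    "condition_networks",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.999


def pearson_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between gene rows.

    Requires >= 3 samples (on 2 points every correlation is +/-1, which is
    meaningless).  Genes with zero variance across the samples have no
    defined correlation; they are dropped with a warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError(
            f"pearson_matrix needs >= 3 samples, got {matrix.shape[1]}"
        )
    sd = matrix.to_numpy().std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        logger.warning(
            "dropping %d zero-variance gene(s) before correlation: %s",
            len(dropped), dropped[:10],
        )
        matrix = matrix.loc[keep]
    values = matrix.to_numpy()
    corr = np.corrcoef(values) if len(values) > 1 else np.ones((len(values),) * 2)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def build_network(
    corr: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    condition: str = "",
) -> nx.Graph:
    """Threshold a correlation matrix into a signed co-expression network.

    Edge (i, j) is present iff |r_ij| > threshold (strictly), i != j; each
    edge stores ``weight`` (the signed r) and ``sign`` ('positive' or
    'negative').  All genes stay as nodes even when isolated.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    genes = list(corr.index)
    g = nx.Graph(condition=condition, threshold=threshold)
    g.add_nodes_from(genes)
    r = corr.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    hit = np.abs(r[iu, ju]) > threshold
    for i, j in zip(iu[hit], ju[hit]):
        rij = float(r[i, j])
        g.add_edge(
            genes[i], genes[j],
            weight=rij, sign="positive" if rij > 0 else "negative",
        )
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw degree (edge count) per node."""
    return dict(net.degree())


@dataclass(frozen=True)
class KCoreAssignment:
    """Result of a k-core decomposition.

    ``core_index[g]`` is the largest k such that gene g survives in the
    k-core (the maximal subgraph of minimum internal degree k); ``max_k``
    is the largest realized index and ``max_core_members`` the genes of the
    innermost core — the within-network core-regulator candidates.
    """

    core_index: dict[str, int]
    max_k: int
    max_core_members: frozenset[str]


def kcore_decompose(net: nx.Graph) -> KCoreAssignment:
    """Standard k-core decomposition (iterative minimum-degree removal)."""
    if net.number_of_nodes() == 0:
        return KCoreAssignment({}, 0, frozenset())
    core = nx.core_number(net)
    max_k = max(core.values())
    members = frozenset(g for g, k in core.items() if k == max_k)
    return KCoreAssignment(dict(core), max_k, members)


def core_regulators(net_a: nx.Graph, net_b: nx.Graph) -> pd.DataFrame:
    """Rank genes by the degree difference between the two condition networks.

    Genes missing from one network count as degree 0 there.  The table is
    sorted by |degree_diff| descending, ties broken by degree_B then gene
    id; ``rank`` is 1-based in that order.  degree_diff = degree_B -
    degree_A, so positive values mark genes far better connected under
    condition B.
    """
    deg_a = degree_centrality(net_a)
    deg_b = degree_centrality(net_b)
    genes = sorted(set(deg_a) | set(deg_b))
    table = pd.DataFrame(
        {
            "gene": genes,
            "degree_A": [deg_a.get(g, 0) for g in genes],
            "degree_B": [deg_b.get(g, 0) for g in genes],
        }
    )
    table["degree_diff"] = table["degree_B"] - table["degree_A"]
    table["abs_diff"] = table["degree_diff"].abs()
    table = table.sort_values(
        ["abs_diff", "degree_B", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="abs_diff")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.set_index("gene")


def condition_networks(
    matrix: pd.DataFrame,
    design: SampleDesign,
    genes: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, nx.Graph]:
    """Build one signed co-expression network per condition.

    Correlations are computed within each condition separately, across that
    condition's samples only, over ``genes`` (default: all matrix genes).
    """
    if genes is not None:
        missing = [g for g in genes if g not in matrix.index]
        if missing:
            raise ValueError(f"genes absent from matrix: {missing[:10]}")
        matrix = matrix.loc[genes]
    nets = {}
    for cond in design.conditions:
        sub = matrix[design.samples(cond)]
        corr = pearson_matrix(sub)
        nets[cond] = build_network(corr, threshold=threshold, condition=cond)
    return nets
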