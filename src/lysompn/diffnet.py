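"""Differential co-expression networks.

Per-group Pearson networks are thresholded at r > 0.6 (signed, matching the
printed inequality; an absolute-value mode is available). Differential edges
are those exceeding the threshold in the carrier group but not in the
non-carrier group, confirmed by a protein-interaction template edge with
combined score > 700. Modules come from greedy modularity maximization on
|r|-weighted edges; hub genes are ranked by within-module weighted degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

R_THRESHOLD = 0.6
MIN_TEMPLATE_SCORE = 700


@dataclass
class CorrelationNetwork:
    group: str
    edges: pd.DataFrame  # gene_a < gene_b, r
    threshold: float
    genes: list[str] = field(default_factory=list)  # full universe


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between rows (genes); constant rows dropped."""
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 columns for correlation")
    variances = expr.var(axis=1, ddof=0)
    constant = variances == 0
    if constant.any():
        import warnings

        warnings.warn(f"dropping {int(constant.sum())} constant gene(s)")
        expr = expr.loc[~constant]
    r = np.corrcoef(expr.to_numpy())
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def correlation_network(
    expr: pd.DataFrame,
    threshold: float = R_THRESHOLD,
    *,
    group: str = "",
    absolute: bool = False,
) -> CorrelationNetwork:
    """Thresholded Pearson network over a genes x samples (or genes x cells)
    expression matrix. Edges kept when r > threshold (or |r| > threshold
    with ``absolute``)."""
    r = pearson_matrix(expr)
    mat = r.to_numpy()
    iu = np.triu_indices(len(mat), k=1)
    vals = mat[iu]
    keep = (np.abs(vals) if absolute else vals) > threshold
    genes = r.index.to_numpy()
    a, b = genes[iu[0][keep]], genes[iu[1][keep]]
    swap = a > b
    edges = pd.DataFrame(
        {
            "gene_a": np.where(swap, b, a),
            "gene_b": np.where(swap, a, b),
            "r": vals[keep],
        }
    ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return CorrelationNetwork(
        group=group, edges=edges, threshold=threshold, genes=list(expr.index)
    )


@dataclass
class DifferentialNetwork:
    edges: pd.DataFrame  # gene_a, gene_b, r (carrier), score (template)
    n_edges: int
    n_genes: int


def _edge_keys(edges: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(edges[["gene_a", "gene_b"]])


def differential_edges(
    carrier_net: CorrelationNetwork,
    noncarrier_net: CorrelationNetwork,
    template: pd.DataFrame,
    min_score: int = MIN_TEMPLATE_SCORE,
) -> DifferentialNetwork:
    """Edges above threshold in carriers, at or below it in non-carriers,
    and present in the template with score > ``min_score``."""
    if template.empty:
        raise ValueError("empty template network")
    if set(carrier_net.genes) != set(noncarrier_net.genes):
        raise ValueError("carrier and non-carrier networks differ in gene universe")
    carrier_only = carrier_net.edges[
        ~_edge_keys(carrier_net.edges).isin(_edge_keys(noncarrier_net.edges))
    ]
    strong = template[template["score"] > min_score]
    merged = carrier_only.merge(strong, on=["gene_a", "gene_b"], how="inner")
    n_genes = len(set(merged["gene_a"]) | set(merged["gene_b"]))
    return DifferentialNetwork(
        edges=merged.reset_index(drop=True), n_edges=len(merged), n_genes=n_genes
    )


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, weight=abs(row.r), r=row.r)
    return g


def detect_modules(
    net: DifferentialNetwork | CorrelationNetwork, seed: int = 0
) -> dict[int, list[str]]:
    """Greedy modularity communities on |r|-weighted edges; singletons are
    discarded; module ids ordered by decreasing size then gene symbols."""
    edges = net.edges
    if edges.empty:
        raise ValueError("network has no edges")
    g = to_graph(edges)
    communities = nx.algorithms.community.greedy_modularity_communities(
        g, weight="weight"
    )
    modules = [sorted(c) for c in communities if len(c) > 1]
    modules.sort(key=lambda m: (-len(m), m))
    return {i + 1: m for i, m in enumerate(modules)}


def rank_hubs(
    module: list[str], net: DifferentialNetwork | CorrelationNetwork
) -> pd.DataFrame:
    """Genes of a module ordered by descending within-module weighted degree
    (sum of |r| over incident module edges); ties broken by symbol."""
    module_set = set(module)
    edges = net.edges
    inside = edges[
        edges["gene_a"].isin(module_set) & edges["gene_b"].isin(module_set)
    ]
    degree = dict.fromkeys(module, 0.0)
    for row in inside.itertuples(index=False):
        degree[row.gene_a] += abs(row.r)
        degree[row.gene_b] += abs(row.r)
    unknown = set(module) - set(net.edges["gene_a"]) - set(net.edges["gene_b"])
    if isinstance(net, CorrelationNetwork):
        unknown -= set(net.genes)
        if unknown:
            raise ValueError(f"module genes outside network: {sorted(unknown)}")
    out = pd.DataFrame(
        sorted(degree.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "weighted_degree"],
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def write_edges(edges: pd.DataFrame, path: str) -> None:
    from lysompn.io import write_tsv

    write_tsv(edges, path)


def write_graphml(edges: pd.DataFrame, path: str) -> None:
    nx.write_graphml(to_graph(edges), path)
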