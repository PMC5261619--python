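"""Gene-network construction and broker/bridge centrality prioritization.

Per-sibling gene lists (CNV genes, shared-variant genes, exclusive-variant
genes, brain-expression filtered) induce a subnetwork of a protein
interaction edge list thresholded at a minimum combined confidence
(default 0.4, the database's "medium confidence"). On the biggest
connected component six per-gene measures are computed:

degree         number of incident edges
betweenness    unnormalized shortest-path betweenness over unordered pairs
closeness      (n-1) / sum of shortest-path distances
clustering     local clustering coefficient
brokering      (degree/(n-1)) * (1 - clustering) — high-degree genes whose
               neighbors are mutually unconnected
bridging       betweenness * bridging coefficient, where the bridging
               coefficient of v is (1/deg(v)) / sum_{u in N(v)} 1/deg(u) —
               favors genes sitting between densely connected regions

Genes in the top 5% (95th percentile, inclusive) of brokering are
brokers; of bridging, bridges.

All centralities are computed on the unweighted graph: confidence scores
are used only for thresholding edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import networkx as nx
import numpy as np
import pandas as pd

MIN_CONFIDENCE = 0.4
ROLE_PERCENTILE = 95.0


@dataclass
class SiblingGeneList:
    """Per-sibling gene universe with provenance, brain-filtered."""

    sibling: str
    cnv_genes: set[str] = field(default_factory=set)
    shared_variant_genes: set[str] = field(default_factory=set)
    exclusive_variant_genes: set[str] = field(default_factory=set)
    brain_filter_applied: bool = False

    @property
    def universe(self) -> set[str]:
        return self.cnv_genes | self.shared_variant_genes | self.exclusive_variant_genes

    def provenance(self) -> dict[str, set[str]]:
        """gene -> provenance labels; a gene may carry several."""
        prov: dict[str, set[str]] = {}
        for label, genes in (
            ("cnv", self.cnv_genes),
            ("shared_variant", self.shared_variant_genes),
            ("exclusive_variant", self.exclusive_variant_genes),
        ):
            for g in genes:
                prov.setdefault(g, set()).add(label)
        return prov


def assemble_gene_list(
    sibling: str,
    cnv_genes: set[str],
    shared_variant_genes: set[str],
    exclusive_variant_genes: set[str],
    brain_genes: set[str] | None = None,
) -> SiblingGeneList:
    """Intersect each provenance set with the brain-expressed gene list.

    ``brain_genes=None`` disables the filter. An empty resulting
    universe is an error: there is nothing to analyze.
    """
    if brain_genes is not None and not brain_genes:
        raise ValueError("brain filter enabled with an empty brain gene list")

    def _f(genes: set[str]) -> set[str]:
        return set(genes) if brain_genes is None else set(genes) & brain_genes

    out = SiblingGeneList(
        sibling=sibling,
        cnv_genes=_f(cnv_genes),
        shared_variant_genes=_f(shared_variant_genes),
        exclusive_variant_genes=_f(exclusive_variant_genes),
        brain_filter_applied=brain_genes is not None,
    )
    if not out.universe:
        raise ValueError(f"empty gene universe for sibling {sibling!r}")
    return out


def load_edge_list(path: str) -> pd.DataFrame:
    """Read a 3-column tab-separated interaction edge list.

    Columns: geneA, geneB, combined_score. Scores above 1 are assumed to
    be on the 0-1000 database scale and are divided by 1000.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["geneA", "geneB", "combined_score"],
        dtype={"geneA": str, "geneB": str, "combined_score": float},
        skiprows=_header_rows(path),
    )
    if (df["combined_score"] > 1).any():
        df["combined_score"] = df["combined_score"] / 1000.0
    return df


def _header_rows(path: str) -> int:
    with open(path) as fh:
        first = fh.readline().split("\t")
    try:
        float(first[2])
        return 0
    except (ValueError, IndexError):
        return 1


def build_network(
    edges: pd.DataFrame,
    universe: set[str],
    min_confidence: float = MIN_CONFIDENCE,
) -> nx.Graph:
    """Induced confidence-filtered subgraph on a gene universe.

    Keeps edges with both endpoints in ``universe`` and confidence
    >= ``min_confidence`` (boundary inclusive); isolated universe genes
    are retained as degree-0 nodes. Duplicate edges keep the maximum
    confidence; self-loops are dropped.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(universe)
    conf = edges["combined_score"].to_numpy(dtype=float)
    if (conf > 1).any():
        conf = conf / 1000.0  # 0-1000 database scale
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("edge confidence outside [0, 1] after rescaling")
    for (a, b), c in zip(zip(edges["geneA"], edges["geneB"]), conf):
        if a == b or a not in universe or b not in universe:
            continue
        if c < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], float(c))
        else:
            g.add_edge(a, b, confidence=float(c))
    return g


def _trunc2(x: float) -> float:
    """Truncate to 2 decimals, the convention of the printed network stats
    (32/61 connected prints as 52.45%, not 52.46%)."""
    return math.floor(x * 100 + 1e-9) / 100


def summary_stats(net: nx.Graph) -> dict[str, float]:
    """Node/edge counts, average degree 2E/N, and percent of nodes with
    at least one edge; the two ratios truncated to 2 decimals."""
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return {"n_nodes": 0, "n_edges": 0, "average_degree": 0.0, "percent_connected": 0.0}
    connected = sum(1 for _, d in net.degree() if d >= 1)
    return {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": _trunc2(2 * e / n),
        "percent_connected": _trunc2(100 * connected / n),
    }


def biggest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph of the largest connected component.

    Ties by node count are broken by the lexicographically smallest
    sorted node list, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        return net.copy()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(net)),
        key=lambda nodes: (-len(nodes), nodes),
    )
    return net.subgraph(comps[0]).copy()


def brokering_score(degree: int, clustering: float, n: int) -> float:
    """Brokering centrality: normalized degree times (1 - clustering).

    ``n`` is the number of nodes in the component. A hub whose neighbors
    do not interconnect (clustering 0) maximizes the score; a node
    embedded in a clique (clustering 1) scores 0.
    """
    if n < 2:
        raise ValueError("component must have at least 2 nodes")
    return (degree / (n - 1)) * (1.0 - clustering)


def bridging_coefficient(graph: nx.Graph, node) -> float:
    """(1/deg(v)) / sum over neighbors u of 1/deg(u).

    High when a low-degree node's neighbors are themselves high-degree,
    i.e. the node sits between well-connected regions. 0 for isolated
    nodes (no neighbors)."""
    deg = graph.degree(node)
    if deg == 0:
        return 0.0
    denom = sum(1.0 / graph.degree(u) for u in graph.neighbors(node))
    return (1.0 / deg) / denom


def centralities(component: nx.Graph) -> pd.DataFrame:
    """Per-gene centrality table for one connected component.

    Returns a DataFrame indexed by gene with columns degree,
    betweenness, closeness, clustering, brokering, bridging_coefficient,
    bridging. Betweenness is unnormalized (counts over unordered pairs);
    closeness is (n-1)/sum-of-distances.
    """
    n = component.number_of_nodes()
    if n < 2:
        raise ValueError("need a component with at least 2 nodes")
    if not nx.is_connected(component):
        raise ValueError("input must be a single connected component")

    betw = nx.betweenness_centrality(component, normalized=False)
    close = nx.closeness_centrality(component)
    clust = nx.clustering(component)
    rows = []
    for gene in sorted(component.nodes):
        deg = component.degree(gene)
        bc = bridging_coefficient(component, gene)
        rows.append(
            {
                "gene": gene,
                "degree": deg,
                "betweenness": betw[gene],
                "closeness": close[gene],
                "clustering": clust[gene],
                "brokering": brokering_score(deg, clust[gene], n),
                "bridging_coefficient": bc,
                "bridging": betw[gene] * bc,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def classify_roles(records: pd.DataFrame, percentile: float = ROLE_PERCENTILE) -> pd.DataFrame:
    """Assign broker/bridge/both/none roles at a score percentile.

    A gene is a broker when its brokering score is >= the percentile
    (linear interpolation between order statistics) of all brokering
    scores in the component, and a bridge likewise for bridging scores.
    """
    if records.empty:
        raise ValueError("no centrality records to classify")
    out = records.copy()
    brok_cut = float(np.percentile(out["brokering"], percentile))
    brid_cut = float(np.percentile(out["bridging"], percentile))
    is_broker = out["brokering"] >= brok_cut
    is_bridge = out["bridging"] >= brid_cut
    out["role"] = np.select(
        [is_broker & is_bridge, is_broker, is_bridge],
        ["both", "broker", "bridge"],
        default="none",
    )
    out.attrs["brokering_cutoff"] = brok_cut
    out.attrs["bridging_cutoff"] = brid_cut
    return out


def compare_components(comp_a: set[str], comp_b: set[str]) -> dict[str, set[str]]:
    """Shared and exclusive genes between two components' node sets."""
    a, b = set(comp_a), set(comp_b)
    return {"shared": a & b, "exclusive_a": a - b, "exclusive_b": b - a}


def centrality_report(records: pd.DataFrame, sibling: str = "") -> pd.DataFrame:
    """Rounded, role-annotated table in the printed report layout."""
    rep = records.copy()
    rep["betweenness"] = rep["betweenness"].round(2)
    rep["bridging"] = rep["bridging"].round(3)
    for col in ("closeness", "clustering", "brokering"):
        rep[col] = rep[col].round(3)
    rep.insert(0, "sibling", sibling)
    order = ["sibling", "degree", "betweenness", "bridging", "brokering",
             "closeness", "clustering"]
    extra = [c for c in rep.columns if c not in order]
    return rep[order + extra]
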