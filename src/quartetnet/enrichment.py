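"""Enrichment statistics: edge enrichment and gene-set over-representation.

Two questions back the pipeline's interpretation of a gene list:

1. Do the genes interact more than random genes would? ``edge_enrichment``
   compares the number of interaction-network edges inside the gene set
   against a null — either a closed-form density null (expected edges =
   C(k,2) * background density, upper-tail count model) or a seeded
   permutation null drawing equal-size random gene sets from the
   background (the default; the original web services' nulls are not
   reproducible).

2. Is the gene list over-represented in annotation categories?
   ``over_representation`` runs the one-sided hypergeometric upper-tail
   test per category with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EdgeEnrichmentResult:
    observed_edges: int
    expected_edges: float
    p_value: float
    null_model: str  # "density" | "degree_preserving_permutation"
    n_permutations: int = 0


def _edges_within(adj: np.ndarray, idx: np.ndarray) -> int:
    sub = adj[np.ix_(idx, idx)]
    return int(sub.sum() // 2)


def edge_enrichment(
    gene_set: set[str],
    background: nx.Graph,
    null_model: str = "permutation",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> EdgeEnrichmentResult:
    """Test whether a gene set has more internal edges than expected.

    density null: expected = C(k,2) * E_bg / C(N_bg,2); the p-value is
    the upper tail of a Poisson count with that mean.

    permutation null: draw ``n_permutations`` uniform same-size gene
    sets from the background node set and use the pseudo-count p-value
    (1 + #{permutation count >= observed}) / (1 + n_permutations),
    which can never be exactly zero.
    """
    nodes = list(background.nodes)
    missing = set(gene_set) - set(nodes)
    if missing:
        raise ValueError(f"gene set not contained in background: {sorted(missing)[:5]}")
    k = len(gene_set)
    n_bg = len(nodes)
    if k > n_bg:
        raise ValueError("gene set larger than background")

    index = {g: i for i, g in enumerate(nodes)}
    adj = nx.to_numpy_array(background, nodelist=nodes, dtype=np.uint8)
    obs = _edges_within(adj, np.array([index[g] for g in gene_set], dtype=int))

    density = background.number_of_edges() / comb(n_bg, 2) if n_bg >= 2 else 0.0
    expected = comb(k, 2) * density

    if null_model == "density":
        p = float(stats.poisson.sf(obs - 1, expected)) if expected > 0 else float(obs == 0)
        return EdgeEnrichmentResult(obs, expected, min(p, 1.0), "density")
    if null_model == "permutation":
        if n_permutations < 100:
            raise ValueError("permutation null needs n_permutations >= 100")
        rng = np.random.default_rng(seed)
        ge = 0
        all_idx = np.arange(n_bg)
        for _ in range(n_permutations):
            perm = rng.choice(all_idx, size=k, replace=False)
            if _edges_within(adj, perm) >= obs:
                ge += 1
        p = (1 + ge) / (1 + n_permutations)
        return EdgeEnrichmentResult(obs, expected, p, "permutation", n_permutations)
    raise ValueError(f"unknown null model {null_model!r}")


def over_representation(
    gene_set: set[str],
    categories: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set per category.

    For a universe of N genes, a study set of k and a category of K
    genes (intersected with the universe), the raw p-value is
    P[X >= overlap] for X ~ Hypergeom(N, K, k). Benjamini-Hochberg
    adjustment is applied across the tested categories; rows are sorted
    by adjusted then raw p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = set(gene_set) - universe
    if stray:
        raise ValueError(f"gene set not contained in universe: {sorted(stray)[:5]}")
    n_univ = len(universe)
    study = set(gene_set)
    rows = []
    for cat, genes in categories.items():
        cat_genes = set(genes) & universe
        overlap = len(study & cat_genes)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(cat_genes), len(study)))
        rows.append(
            {
                "category": cat,
                "overlap": overlap,
                "set_size": len(study),
                "category_size": len(cat_genes),
                "universe_size": n_univ,
                "p_raw": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = benjamini_hochberg(df["p_raw"].to_numpy())
        df = df.sort_values(["p_adjusted", "p_raw", "category"]).reset_index(drop=True)
    return df


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def load_categories(path: str) -> dict[str, set[str]]:
    """Read gene-set categories from 2-column TSV (category, gene) or
    GMT (category, description, genes...)."""
    cats: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if str(path).endswith(".gmt"):
                cats.setdefault(parts[0], set()).update(g for g in parts[2:] if g)
            else:
                cats.setdefault(parts[0], set()).add(parts[1])
    return cats
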