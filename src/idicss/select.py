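"""Selection of immune-relevant independent components.

A component is called a key immune component when (a) its top-loading genes
are over-represented in at least one immune gene set (hypergeometric test,
Benjamini-Hochberg across the full component x set family) and (b) those
genes are more densely interconnected in a reference PPI network than
degree-matched random gene sets (permutation test). A crosstalk network
(Jaccard overlap between the components' top-gene sets) is built for
reporting and visual clustering of related components.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ica import ICADecomposition, top_genes
from .io import GeneSetCollection

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_MIN_JACCARD = 0.05
DEFAULT_Q_MAX = 0.05
DEFAULT_P_MAX = 0.05
DEFAULT_N_PERM = 999
DEGREE_BINS = 10


@dataclass
class CrosstalkNetwork:
    """Weighted component-overlap graph; edge weight = top-gene Jaccard index."""

    graph: nx.Graph

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"component_a": a, "component_b": b, "jaccard": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["component_a", "component_b", "jaccard"])


def build_crosstalk_network(
    decomp: ICADecomposition,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_jaccard: float = DEFAULT_MIN_JACCARD,
) -> CrosstalkNetwork:
    sets = {c: set(top_genes(decomp, c, z_threshold)) for c in decomp.components}
    graph = nx.Graph()
    for c, genes in sets.items():
        graph.add_node(c, n_top_genes=len(genes))
    comps = decomp.components
    for i, a in enumerate(comps):
        for b in comps[i + 1 :]:
            union = sets[a] | sets[b]
            if not union:
                continue
            jac = len(sets[a] & sets[b]) / len(union)
            if jac >= min_jaccard and jac > 0:
                graph.add_edge(a, b, weight=jac)
    return CrosstalkNetwork(graph)


def hypergeom_enrichment(
    query: set[str], target: set[str], universe: set[str]
) -> tuple[float, int]:
    """One-sided over-representation p = P[X >= overlap] under the
    hypergeometric law; returns (p, overlap count)."""
    if not universe:
        raise ValueError("empty universe")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    target = set(target) & set(universe)
    overlap = len(set(query) & target)
    # P[X >= k] with M = |universe|, n = |target|, N = |query|
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(target), len(query)))
    return min(p, 1.0), overlap


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def ppi_connectivity_test(
    genes: set[str],
    ppi: nx.Graph,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, int]:
    """Degree-matched permutation test of within-set PPI connectivity.

    Statistic: number of PPI edges with both endpoints in the query set.
    Null sets are drawn by binning all PPI nodes into degree deciles and
    sampling, within each bin, as many genes as the query contributes to it.
    Returns ``(p, observed_edges)`` with p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nodes = list(ppi.nodes())
    present = [g for g in genes if g in ppi]
    if len(present) < 2:
        raise ValueError("fewer than 2 query genes present in the PPI network")

    adj = {n: set(ppi.neighbors(n)) for n in nodes}

    def n_edges(gene_set: set[str]) -> int:
        return sum(len(adj[g] & gene_set) for g in gene_set) // 2

    observed = n_edges(set(present))

    degrees = np.array([ppi.degree(n) for n in nodes])
    quantiles = np.quantile(degrees, np.linspace(0, 1, DEGREE_BINS + 1))
    bin_of = np.clip(np.searchsorted(quantiles, degrees, side="right") - 1, 0, DEGREE_BINS - 1)
    bins: dict[int, list[str]] = {}
    for node, b in zip(nodes, bin_of):
        bins.setdefault(int(b), []).append(node)
    query_bins: dict[int, int] = {}
    node_bin = dict(zip(nodes, bin_of))
    for g in present:
        b = int(node_bin[g])
        query_bins[b] = query_bins.get(b, 0) + 1

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        draw: set[str] = set()
        for b, count in query_bins.items():
            pool = bins[b]
            idx = rng.choice(len(pool), size=min(count, len(pool)), replace=False)
            draw.update(pool[i] for i in idx)
        if n_edges(draw) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(p), int(observed)


def select_key_ics(
    decomp: ICADecomposition,
    immune_sets: GeneSetCollection,
    ppi: nx.Graph,
    *,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    q_max: float = DEFAULT_Q_MAX,
    p_max: float = DEFAULT_P_MAX,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-component immune relevance table.

    Columns: ``best_set`` (most enriched immune set), ``best_p``/``best_q``
    (BH over the joint component x set family), ``ppi_p``, ``n_top_genes``,
    ``selected``. A component is selected iff ``best_q < q_max`` and
    ``ppi_p < p_max``. Sorted by best_q.
    """
    if len(immune_sets) == 0:
        raise ValueError("no immune gene sets provided")
    universe = set(decomp.genes)
    records = []
    for comp in decomp.components:
        query = set(top_genes(decomp, comp, z_threshold))
        for name, target in immune_sets.sets.items():
            if query:
                p, overlap = hypergeom_enrichment(query, set(target), universe)
            else:
                p, overlap = 1.0, 0
            records.append((comp, name, p, overlap, len(query)))
    enr = pd.DataFrame(
        records, columns=["component", "set", "p", "overlap", "n_top_genes"]
    )
    enr["q"] = bh_adjust(enr["p"].to_numpy())

    rng = np.random.default_rng(seed)
    rows = []
    for comp, grp in enr.groupby("component", sort=False):
        best = grp.loc[grp["q"].idxmin()]
        query = set(top_genes(decomp, comp, z_threshold))
        try:
            ppi_p, _ = ppi_connectivity_test(
                query, ppi, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
            )
        except ValueError:
            ppi_p = 1.0
        rows.append(
            {
                "component": comp,
                "best_set": best["set"],
                "best_p": best["p"],
                "best_q": best["q"],
                "overlap": int(best["overlap"]),
                "n_top_genes": int(best["n_top_genes"]),
                "ppi_p": ppi_p,
                "selected": bool(best["q"] < q_max and ppi_p < p_max),
            }
        )
    table = pd.DataFrame(rows).sort_values("best_q", kind="stable").reset_index(drop=True)
    return table
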