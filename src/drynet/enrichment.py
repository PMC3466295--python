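"""Hypergeometric enrichment machinery.

Two uses: classical term (e.g. GO) over-representation of a query gene
set against a reference universe, with false-discovery control valid
under arbitrary dependence (Benjamini-Yekutieli); and the trait-link
test, which asks whether an independently obtained gene list (drought
regulated genes from a field trial) is enriched in genes linked to a
given phenotypic trait in the merged gene-phenotype network.

Both the point probability P(X = k) and the upper tail P(X >= k) are
reported throughout.  The trait-link statistic printed alongside the
report of a field transfer is conventionally the point probability
(the Matlab ``hygepdf`` value); the upper tail is the standard one-sided
enrichment p-value.  Probabilities are evaluated from exact integer
binomial coefficients for universes up to 10^4 genes (accurate to float
rounding) and in log space from log-gamma factorials beyond, where the
exact ratio would be slow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .network import genes_of


def _check_bounds(k: int, N: int, K: int, n: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside support [{max(0, n + K - N)}, {min(K, n)}] "
            f"for N={N}, K={K}, n={n}"
        )


def _log_comb(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_logpmf(k, N: int, K: int, n: int):
    k = np.asarray(k)
    return _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)


#: exact integer arithmetic up to this universe size; log-gamma beyond
_EXACT_LIMIT = 10_000


def _exact_pmf(k: int, N: int, K: int, n: int) -> float:
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the number of marked items, n the draw size.
    """
    _check_bounds(k, N, K, n)
    if N <= _EXACT_LIMIT:
        return _exact_pmf(k, N, K, n)
    return float(np.exp(hypergeom_logpmf(k, N, K, n)))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), summed over the upper support."""
    _check_bounds(k, N, K, n)
    if k <= max(0, n + K - N):
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if N <= _EXACT_LIMIT:
        return float(min(1.0, sum(_exact_pmf(int(j), N, K, n) for j in support)))
    logs = hypergeom_logpmf(support, N, K, n)
    peak = logs.max()
    return float(min(1.0, np.exp(peak) * np.exp(logs - peak).sum()))


@dataclass
class EnrichmentRow:
    """One tested term: counts, point probability, raw and adjusted p."""

    term_id: str
    term_name: str
    query_hits: int
    query_total: int
    ref_hits: int
    ref_total: int
    point_probability: float
    p_raw: float
    p_adjusted: float = np.nan


def term_enrichment(
    query_set,
    reference_universe,
    term_annotations: pd.DataFrame,
    term_names: dict[str, str] | None = None,
    min_reference_count: int = 2,
) -> pd.DataFrame:
    """Term over-representation of ``query_set`` within ``reference_universe``.

    ``term_annotations`` is a two-column frame (gene_id, term_id).  Terms
    with at least one query hit and at least ``min_reference_count``
    annotated universe genes are tested with the upper-tail hypergeometric
    p; adjustment is Benjamini-Yekutieli across all tested terms.
    """
    universe = set(reference_universe)
    query = set(query_set) & universe
    if set(query_set) - universe:
        warnings.warn("query genes outside the universe were dropped", stacklevel=2)
    if not query:
        warnings.warn("empty query set: no enrichment computed", stacklevel=2)
        return _rows_to_frame([])
    ann = term_annotations[term_annotations["gene_id"].isin(universe)]
    N, n = len(universe), len(query)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        term_genes = set(genes)
        K = len(term_genes)
        k = len(term_genes & query)
        if k < 1 or K < min_reference_count:
            continue
        rows.append(
            EnrichmentRow(
                term_id=str(term),
                term_name=(term_names or {}).get(str(term), ""),
                query_hits=k,
                query_total=n,
                ref_hits=K,
                ref_total=N,
                point_probability=hypergeom_pmf(k, N, K, n),
                p_raw=hypergeom_upper_tail(k, N, K, n),
            )
        )
    df = _rows_to_frame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method="fdr_by")[1]
        df = df.sort_values("p_raw").reset_index(drop=True)
    return df


def _rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    cols = [
        "term_id",
        "term_name",
        "query_hits",
        "query_total",
        "ref_hits",
        "ref_total",
        "point_probability",
        "p_raw",
        "p_adjusted",
    ]
    return pd.DataFrame([r.__dict__ for r in rows], columns=cols)


@dataclass
class TraitLinkTest:
    """Enrichment of an independent gene list in trait-linked network genes.

    N: merged-network gene universe; K: genes with >= 1 edge to the trait;
    n: field genes present in the network; k: their overlap with the
    trait-linked genes.
    """

    trait: str
    N: int
    K: int
    n: int
    k: int
    point_probability: float
    p_upper_tail: float


def trait_link_enrichment(field_genes, net: nx.Graph, trait: str) -> TraitLinkTest:
    """Test a field gene list for enrichment in genes linked to ``trait``."""
    network_genes = set(genes_of(net))
    if trait not in net:
        raise ValueError(f"trait {trait!r} not present in the network")
    linked = {g for g in net.neighbors(trait) if g in network_genes}
    in_net = set(field_genes) & network_genes
    N, K, n = len(network_genes), len(linked), len(in_net)
    if n == 0:
        raise ValueError("no field gene maps into the network: test undefined")
    k = len(in_net & linked)
    return TraitLinkTest(
        trait=trait,
        N=N,
        K=K,
        n=n,
        k=k,
        point_probability=hypergeom_pmf(k, N, K, n),
        p_upper_tail=hypergeom_upper_tail(k, N, K, n),
    )


def field_subnetwork(field_genes, net: nx.Graph) -> nx.Graph:
    """Induced bipartite subgraph on field genes, keeping all attributes."""
    keep = set(field_genes) & set(genes_of(net))
    if not keep:
        warnings.warn("field list disjoint from network: empty subnetwork", stacklevel=2)
    phen = {n for n, d in net.nodes(data=True) if d.get("kind") == "phenotype"}
    sub = net.subgraph(keep | phen).copy()
    sub.remove_nodes_from([p for p in phen if sub.degree(p) == 0])
    sub.graph.update(net.graph)
    sub.graph["scenario"] = f"{net.graph.get('scenario', '')}-field"
    return sub


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_term_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    return df
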