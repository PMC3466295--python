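"""Bipartite gene-phenotype relevance networks from a fitted sPLS model.

The pairwise association score between gene i and phenotype j is the
latent-variate relevance-network similarity

    score(i, j) = sum_h  cor(x_i, t_h) * cor(y_j, t_h)

accumulated over the model's X-variates t_h on centered/scaled training
data.  As components accumulate this approximates the gene-phenotype
correlation restricted to the subspace the model captures.  Edges are
kept when |score| strictly exceeds the threshold (0.65 by default);
networks fitted under the two drought scenarios (FDS, FIS) are merged by
edge union, tagging each edge FDS / FIS / both and each gene as
FDS-only / shared / FIS-only.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .spls import SplsModel, _columns_variate_correlations

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.65


def association_scores(model: SplsModel, X, Y) -> pd.DataFrame:
    """Genes x phenotypes signed score matrix from the training data.

    Scores are computed for every gene (selected by the sparsity budget
    or not); the accompanying ``selected`` attribute on the returned
    frame flags genes with a non-zero loading on some component.
    Constant columns score 0 with a warning.
    """
    Xa = np.asarray(X[model.x_names] if isinstance(X, pd.DataFrame) else X, dtype=float)
    Ya = np.asarray(Y[model.y_names] if isinstance(Y, pd.DataFrame) else Y, dtype=float)
    if np.any(Xa.std(axis=0) == 0) or np.any(Ya.std(axis=0) == 0):
        warnings.warn("constant column(s): association score set to 0", stacklevel=2)
    cx = _columns_variate_correlations(Xa, model.x_variates)
    cy = _columns_variate_correlations(Ya, model.x_variates)
    scores = pd.DataFrame(cx @ cy.T, index=model.x_names, columns=model.y_names)
    if np.any(np.abs(scores.to_numpy()) > 1.0):
        logger.warning(
            "%d association score(s) exceed 1 in magnitude",
            int((np.abs(scores.to_numpy()) > 1).sum()),
        )
    scores.attrs["selected"] = pd.Series(
        (model.x_weights != 0).any(axis=1), index=model.x_names
    )
    return scores


def build_network(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    scenario_label: str = "",
) -> nx.Graph:
    """Keep gene-phenotype pairs with |score| strictly above ``threshold``.

    Returns a bipartite graph whose gene nodes have ``kind='gene'`` and
    phenotype nodes ``kind='phenotype'``; isolated genes are dropped.
    """
    net = nx.Graph()
    net.graph["scenario"] = scenario_label
    net.graph["threshold"] = threshold
    net.graph["phenotypes"] = ",".join(scores.columns)
    arr = scores.to_numpy()
    genes_idx, phen_idx = np.nonzero(np.abs(arr) > threshold)
    for gi, pj in zip(genes_idx, phen_idx):
        gene = scores.index[gi]
        phen = scores.columns[pj]
        s = float(arr[gi, pj])
        if not net.has_node(gene):
            net.add_node(gene, kind="gene")
        if not net.has_node(phen):
            net.add_node(phen, kind="phenotype")
        net.add_edge(gene, phen, score=s, sign="+" if s > 0 else "-", scenario=scenario_label)
    return net


def genes_of(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d.get("kind") == "gene"]


def phenotypes_of(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d.get("kind") == "phenotype"]


def merge_networks(fds: nx.Graph, fis: nx.Graph) -> nx.Graph:
    """Union of the two scenario networks with provenance tags.

    An edge present in both scenarios is tagged ``both`` and keeps both
    scores (``score_fds`` / ``score_fis``, ``score`` = their mean); gene
    membership is FDS-only / shared / FIS-only by presence of any edge in
    each source network.
    """
    phen_fds, phen_fis = set(phenotypes_of(fds)), set(phenotypes_of(fis))
    # the full name space (before isolated phenotypes were dropped) is kept
    # in the graph attributes; it must agree between the two scenarios
    ns_fds = fds.graph.get("phenotypes")
    ns_fis = fis.graph.get("phenotypes")
    if ns_fds is not None and ns_fis is not None and set(ns_fds.split(",")) != set(
        ns_fis.split(",")
    ):
        raise ValueError("phenotype name spaces differ between scenario networks")
    merged = nx.Graph()
    merged.graph["scenario"] = "merged"
    merged.graph["phenotypes"] = ns_fds or ns_fis or ""
    fds_genes, fis_genes = set(genes_of(fds)), set(genes_of(fis))
    for gene in fds_genes | fis_genes:
        membership = (
            "shared"
            if gene in fds_genes and gene in fis_genes
            else ("FDS-only" if gene in fds_genes else "FIS-only")
        )
        merged.add_node(gene, kind="gene", membership=membership)
    for phen in phen_fds | phen_fis:
        merged.add_node(phen, kind="phenotype")
    for source, label in ((fds, "FDS"), (fis, "FIS")):
        for u, v, data in source.edges(data=True):
            if merged.has_edge(u, v):
                prev = merged.edges[u, v]
                prev["scenario"] = "both"
                prev[f"score_{label.lower()}"] = data["score"]
                prev["score"] = (prev["score_fds"] + prev["score_fis"]) / 2.0
                prev["sign"] = "+" if prev["score"] > 0 else "-"
            else:
                merged.add_edge(
                    u,
                    v,
                    score=data["score"],
                    sign=data["sign"],
                    scenario=label,
                    **{f"score_{label.lower()}": data["score"]},
                )
    return merged


def membership_counts(net: nx.Graph) -> dict[str, int]:
    counts = {"FDS-only": 0, "shared": 0, "FIS-only": 0}
    for n, d in net.nodes(data=True):
        if d.get("kind") == "gene":
            counts[d.get("membership", "shared")] += 1
    return counts


def annotate_nodes(
    net: nx.Graph, fds_anova: pd.DataFrame, fis_anova: pd.DataFrame
) -> nx.Graph:
    """Attach ANOVA effect flags to gene nodes (idempotent, in place).

    Flags follow the merged-network display convention: treatment effect
    under FDS (moderate stress response), treatment effect under FIS
    (severe stress response), and genotype:treatment effect under FIS.
    Full effect classes are carried as secondary attributes.  A gene with
    a network edge but no significant effect keeps all-False flags.
    """
    from .differential import classify_effects

    cls_fds = classify_effects(fds_anova)
    cls_fis = classify_effects(fis_anova)
    for gene in genes_of(net):
        node = net.nodes[gene]
        if gene not in fds_anova.index or gene not in fis_anova.index:
            warnings.warn(f"gene {gene} absent from an ANOVA table", stacklevel=2)
            node["treatment_fds"] = node["treatment_fis"] = node["gxt_fis"] = None
            continue
        node["treatment_fds"] = bool(fds_anova.loc[gene, "sig_treatment"])
        node["treatment_fis"] = bool(fis_anova.loc[gene, "sig_treatment"])
        node["gxt_fis"] = bool(fis_anova.loc[gene, "sig_gxt"])
        node["class_fds"] = str(cls_fds.loc[gene])
        node["class_fis"] = str(cls_fis.loc[gene])
    return net


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Flat edge list (gene, phenotype, score, sign, scenario)."""
    rows = []
    for u, v, data in net.edges(data=True):
        gene, phen = (u, v) if net.nodes[u].get("kind") == "gene" else (v, u)
        rows.append(
            {
                "gene": gene,
                "phenotype": phen,
                "score": data["score"],
                "sign": data["sign"],
                "scenario": data.get("scenario", ""),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "phenotype", "score", "sign", "scenario"])
    return df.sort_values(["gene", "phenotype"]).reset_index(drop=True)


def export_network(net: nx.Graph, basepath, formats=("sif", "graphml", "tsv")) -> list[str]:
    """Write the network as SIF, GraphML and/or a flat edge TSV."""
    written = []
    for fmt in formats:
        path = f"{basepath}.{fmt}"
        if fmt == "sif":
            with open(path, "w") as fh:
                for _, row in edge_table(net).iterrows():
                    rel = "assoc_pos" if row["sign"] == "+" else "assoc_neg"
                    fh.write(f"{row['gene']}\t{rel}\t{row['phenotype']}\n")
        elif fmt == "graphml":
            clean = net.copy()
            for _, d in clean.nodes(data=True):  # GraphML cannot store None
                for k in [k for k, v in d.items() if v is None]:
                    del d[k]
            nx.write_graphml(clean, path)
        elif fmt == "tsv":
            edge_table(net).to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"unknown network format: {fmt}")
        written.append(path)
    return written
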