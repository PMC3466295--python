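"""End-to-end orchestration: simulate/load -> normalize -> ANOVA -> sPLS ->
network -> merge -> annotate -> field enrichment, with a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrichment, network, normalization, spls
from .simulate import (
    PHENOTYPE_NAMES,
    Dataset,
    SimulationConfig,
    generate_field_dataset,
    generate_term_annotations,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERICAL_ERROR = 4


@dataclass
class PipelineConfig:
    """Inputs and settings of a full run.

    Either ``simulate`` is set (synthetic study with ``sim``'s settings)
    or the four input paths point at on-disk tables.
    """

    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expression_path: str | None = None
    samples_path: str | None = None
    phenotypes_path: str | None = None
    field_genes_path: str | None = None
    annotations_path: str | None = None
    threshold: float = 0.65
    n_components: int = 3
    keep_x: int = 50
    keep_y: int | None = None
    alpha: float = 0.05
    per_scenario_normalization: bool = False
    n_field_genes: int = 156
    field_enrichment_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: Dataset | None
    normalized: pd.DataFrame
    anova: dict[str, differential.AnovaResult]
    classes: dict[str, pd.Series]
    crosstab: pd.DataFrame
    models: dict[str, spls.SplsModel]
    scores: dict[str, pd.DataFrame]
    networks: dict[str, "network.nx.Graph"]
    merged: "network.nx.Graph"
    field_genes: list[str]
    trait_tests: dict[str, enrichment.TraitLinkTest]
    term_results: pd.DataFrame | None
    manifest: dict

    def edge_hash(self) -> str:
        blob = network.edge_table(self.merged).round(9).to_csv(index=False).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Execute every stage in order and optionally write all outputs."""
    t0 = time.time()
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "stages": {},
    }

    if config.simulate:
        sim_config = dataclasses.replace(config.sim, seed=config.seed)
        dataset = simulate_dataset(sim_config)
        expression = dataset.expression
        samples = dataset.samples
        phenotypes = dataset.phenotypes
    else:
        dataset = None
        if not (config.expression_path and config.samples_path and config.phenotypes_path):
            raise FileNotFoundError("expression, samples and phenotypes paths are required")
        expression = normalization.read_expression(config.expression_path)
        samples = normalization.read_sample_sheet(config.samples_path)
        phenotypes = pd.read_csv(config.phenotypes_path, index_col=0)
    manifest["stages"]["input"] = {
        "n_genes": int(expression.shape[0]),
        "n_samples": int(expression.shape[1]),
    }

    normalized = normalization.normalize_expression(
        expression, samples, per_scenario=config.per_scenario_normalization
    )
    manifest["stages"]["normalize"] = {"grand_mean": float(normalized.to_numpy().mean())}

    scenarios = sorted(samples["scenario"].unique())
    anova_results, classes, models, scores, networks = {}, {}, {}, {}, {}
    for scen in scenarios:
        cols = samples.index[samples["scenario"] == scen]
        design = samples.loc[cols, ["block", "genotype", "treatment"]]
        res = differential.fit_anova(normalized[cols], design, alpha=config.alpha)
        anova_results[scen] = res
        classes[scen] = res.classes
        manifest["stages"][f"anova_{scen}"] = {
            e: int(res.table[f"sig_{e}"].sum()) for e in differential.EFFECTS
        }

        X = normalized[cols].T  # samples x genes
        Y = phenotypes.loc[cols, PHENOTYPE_NAMES]
        model = spls.fit_spls(
            X,
            Y,
            n_components=config.n_components,
            keep_x=config.keep_x,
            keep_y=config.keep_y,
        )
        models[scen] = model
        sc = network.association_scores(model, X, Y)
        scores[scen] = sc
        networks[scen] = network.build_network(sc, config.threshold, scen)
        manifest["stages"][f"network_{scen}"] = {
            "genes": len(network.genes_of(networks[scen])),
            "edges": networks[scen].number_of_edges(),
        }

    if len(scenarios) == 2:
        crosstab = differential.cross_tabulate_scenarios(
            classes[scenarios[0]], classes[scenarios[1]]
        )
        merged = network.merge_networks(networks[scenarios[0]], networks[scenarios[1]])
    else:
        crosstab = pd.DataFrame()
        merged = next(iter(networks.values()))
    network.annotate_nodes(
        merged,
        anova_results[scenarios[0]].table,
        anova_results[scenarios[-1]].table,
    )
    manifest["stages"]["merged_network"] = {
        "genes": len(network.genes_of(merged)),
        "edges": merged.number_of_edges(),
        "membership": network.membership_counts(merged),
    }

    if config.field_genes_path:
        field_genes = enrichment.read_gene_list(config.field_genes_path)
    elif dataset is not None:
        field_genes = generate_field_dataset(
            dataset.truth,
            n_field_genes=min(config.n_field_genes, expression.shape[0]),
            enrichment_factor=config.field_enrichment_factor,
            seed=config.seed + 1,
        )
    else:
        field_genes = []

    trait_tests = {}
    net_genes = set(network.genes_of(merged))
    if field_genes and net_genes and set(field_genes) & net_genes:
        for trait in network.phenotypes_of(merged):
            trait_tests[trait] = enrichment.trait_link_enrichment(field_genes, merged, trait)
    manifest["stages"]["field"] = {
        "field_genes": len(field_genes),
        "in_network": len(set(field_genes) & net_genes),
        "traits_tested": sorted(trait_tests),
    }

    term_results = None
    if config.annotations_path:
        ann = enrichment.read_term_annotations(config.annotations_path)
        term_results = enrichment.term_enrichment(net_genes, list(expression.index), ann)
    elif dataset is not None and net_genes:
        ann = generate_term_annotations(dataset.truth, seed=config.seed + 2)
        term_results = enrichment.term_enrichment(net_genes, list(expression.index), ann)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    result = PipelineResult(
        config=config,
        dataset=dataset,
        normalized=normalized,
        anova=anova_results,
        classes=classes,
        crosstab=crosstab,
        models=models,
        scores=scores,
        networks=networks,
        merged=merged,
        field_genes=field_genes,
        trait_tests=trait_tests,
        term_results=term_results,
        manifest=manifest,
    )
    manifest["merged_edge_hash"] = result.edge_hash()
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if result.dataset is not None:
        result.dataset.write(out / "input")
    normalization.write_expression(result.normalized, out / "normalized_expression.tsv")
    for scen, res in result.anova.items():
        table = res.table.copy()
        table["effect_class"] = result.classes[scen]
        table.to_csv(out / f"anova_{scen}.tsv", sep="\t", index_label="gene_id")
    if len(result.crosstab):
        result.crosstab.to_csv(out / "effect_crosstab.csv")
    for scen, model in result.models.items():
        model.save(out / f"spls_{scen}.json")
        result.scores[scen].to_csv(out / f"scores_{scen}.tsv", sep="\t", index_label="gene_id")
        network.export_network(result.networks[scen], out / f"network_{scen}")
    network.export_network(result.merged, out / "network_merged")
    if result.field_genes:
        (out / "field_genes.txt").write_text("\n".join(result.field_genes) + "\n")
    if result.trait_tests:
        pd.DataFrame([t.__dict__ for t in result.trait_tests.values()]).to_csv(
            out / "trait_link_tests.tsv", sep="\t", index=False
        )
    if result.term_results is not None:
        result.term_results.to_csv(out / "term_enrichment.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {
        "drynet": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
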