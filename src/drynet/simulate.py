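"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a two-scenario pot drought experiment: eight
genotypes, two treatments (well-watered control vs water-deprived) and
three blocks per scenario, one plant per cell, 96 plants in total.
Water depletion follows a two-segment transpiration response: daily
transpiration is at its genotype-specific maximum while the fraction of
transpirable soil water (FTSW) is above a threshold (0.4 by default) and
declines linearly with FTSW below it.  Genotype-specific maximum rates
span a range, so vigorous genotypes deplete their pots faster, the
fixed-duration scenario (FDS) harvests everything once half the treated
plants drop below FTSW 0.35, and the fixed-intensity scenario (FIS)
harvests each plant as it crosses FTSW 0.1.

Expression is simulated on the log2-intensity scale as gene-specific
baselines plus additive effect components.  Planted effect classes
populate every category of the genotype/treatment/interaction
cross-table: treatment shifts, balanced genotype contrasts, zero-margin
interaction patterns, and their combinations.  A further set of
trait-linked genes couples to phenotype signal profiles built on three
latent axes: the realized integrated-transpired-water (ITW) axis (stress
intensity) and two orthogonal genotype contrasts, mirroring the
stress-vs-genotype axis structure the analysis is meant to recover.
Phenotypes are signed averages of their gene sets plus noise, with the
osmotic-potential coupling sign opposite to ITW so the expected negative
OP-ITW correlation holds; ITW itself comes from the water simulation.

Everything planted is recorded in a :class:`TruthRecord`, including the
model-implied gene-phenotype correlations, so downstream recovery tests
can score the inferred network against the generative truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .physiology import (
    PotTimeSeries,
    compute_ftsw_series,
    compute_itw,
    schedule_fds_harvest,
    schedule_fis_harvest,
    write_pot_weights,
)

PHENOTYPE_NAMES = ["ITW", "E", "OP", "RWC", "LMA", "CID", "PHe", "CoD", "TLA"]

#: latent-axis loading of each modeled phenotype: (axis, sign).  Axis 0 is
#: the realized ITW (stress) axis; axes 1 and 2 are genotype contrasts.
PHENOTYPE_AXES = {
    "ITW": (0, +1),
    "OP": (0, -1),
    "E": (0, -1),
    "RWC": (1, +1),
    "LMA": (1, -1),
    "TLA": (1, +1),
    "CID": (2, +1),
    "PHe": (2, +1),
    "CoD": (2, +1),
}

ANOVA_CLASSES = ("t_o", "g_o", "g*t_o", "g_t", "g*t_g", "g*t_t", "All")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study design."""

    n_genotypes: int = 8
    n_blocks_per_scenario: int = 3
    n_genes: int = 2000
    frac_treatment_genes: float = 0.04
    frac_genotype_genes: float = 0.08
    frac_gxt_genes: float = 0.02
    frac_combo_genes: float = 0.04  # split evenly over g_t, g*t_g, g*t_t, All
    effect_size_sd_units: float = 4.0
    noise_sd: float = 0.5
    n_phenotypes: int = 9
    genes_per_phenotype: int = 15
    phenotype_noise_sd: float = 0.3
    ftsw_threshold_transpiration: float = 0.4
    initial_weight_g: float = 18000.0
    ttsw_g: float = 4000.0
    depletion_rate_min: float = 0.06  # FTSW units per day at full transpiration
    depletion_rate_max: float = 0.14
    rate_jitter_sd: float = 0.08  # lognormal sd of per-plant rate multiplier
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    max_days: int = 60
    seed: int = 0

    def __post_init__(self):
        fracs = [
            self.frac_treatment_genes,
            self.frac_genotype_genes,
            self.frac_gxt_genes,
            self.frac_combo_genes,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("effect-gene fractions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError("effect-gene fractions must sum to at most 1")
        if self.ttsw_g <= 0:
            raise ValueError("TTSW must be positive")
        if self.n_genes < self.n_phenotypes * self.genes_per_phenotype:
            raise ValueError("n_genes must cover n_phenotypes * genes_per_phenotype")
        if not 0.0 < self.ftsw_threshold_transpiration <= 1.0:
            raise ValueError("ftsw_threshold_transpiration must lie in (0, 1]")
        if self.noise_sd <= 0 or self.effect_size_sd_units < 0:
            raise ValueError("noise_sd must be positive, effect size non-negative")
        if self.n_phenotypes != len(PHENOTYPE_NAMES):
            raise ValueError(f"n_phenotypes is fixed at {len(PHENOTYPE_NAMES)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthRecord:
    """Everything planted by the generator, serializable alongside the data."""

    effect_class: dict[str, str]  # gene -> effect-class label ('none' for noise)
    effect_signs: dict[str, int]
    genotype_contrast: dict[str, list[int]]  # gene -> +-1 contrast over genotypes
    gxt_contrast: dict[str, list[int]]
    trait_couplings: list[dict]  # {gene, phenotype, sign}
    genotype_rates: dict[str, float]
    plant_rates: dict[str, float] = dc_field(default_factory=dict)
    harvest_day: dict[str, int] = dc_field(default_factory=dict)
    implied_edges: dict[str, list[dict]] = dc_field(default_factory=dict)

    @property
    def trait_linked_genes(self) -> set[str]:
        return {c["gene"] for c in self.trait_couplings}

    def network_genes(self, scenario: str = "merged") -> set[str]:
        return {e["gene"] for e in self.implied_edges.get(scenario, [])}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh)

    @classmethod
    def load(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Dataset:
    """One simulated study: data tables plus the generative truth."""

    config: SimulationConfig
    expression: pd.DataFrame  # genes x samples, log2 scale
    samples: pd.DataFrame  # sample sheet incl. harvest day and ITW
    phenotypes: pd.DataFrame  # plants x phenotype columns
    pot_series: list[PotTimeSeries]
    truth: TruthRecord

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "samples": outdir / "samples.csv",
            "pot_weights": outdir / "pot_weights.csv",
            "phenotypes": outdir / "phenotypes.csv",
            "truth": outdir / "truth.json",
        }
        self.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
        self.samples.to_csv(paths["samples"], index=False)
        write_pot_weights(self.pot_series, paths["pot_weights"])
        self.phenotypes.to_csv(paths["phenotypes"], index_label="plant_id")
        self.truth.save(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Water depletion


def simulate_water_depletion(
    config: SimulationConfig,
    seed: int | None = None,
    rates: dict[str, float] | None = None,
) -> tuple[list[PotTimeSeries], dict[str, float], dict[str, float]]:
    """Simulate daily pot weights for every plant of both scenarios.

    Daily relative transpiration follows the two-segment response
    min(1, FTSW / threshold); treated pots lose that water, control pots
    have it restored after weighing (weights non-increasing only for
    treated plants).  Genotype rates are evenly spread over the
    configured range unless ``rates`` overrides them.  Returns the pot
    series plus genotype- and plant-level rates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genotypes = [f"G{i+1:02d}" for i in range(config.n_genotypes)]
    if rates is None:
        spread = (
            np.linspace(config.depletion_rate_min, config.depletion_rate_max, config.n_genotypes)
            if config.n_genotypes > 1
            else np.array([config.depletion_rate_min])
        )
        # vigour order is not tied to genotype label order
        rates = dict(zip(genotypes, rng.permutation(spread)))
    theta = config.ftsw_threshold_transpiration
    final_weight = config.initial_weight_g - config.ttsw_g

    series: list[PotTimeSeries] = []
    plant_rates: dict[str, float] = {}
    for scenario, blocks in (("FDS", range(1, config.n_blocks_per_scenario + 1)),
                             ("FIS", range(1, config.n_blocks_per_scenario + 1))):
        for block in blocks:
            for g in genotypes:
                jitter = float(np.exp(rng.normal(0.0, config.rate_jitter_sd)))
                rate = rates[g] * jitter
                for treated in (True, False):
                    pid = f"{scenario}_B{block}_{g}_{'T' if treated else 'C'}"
                    plant_rates[pid] = rate if treated else rates[g]
                    ftsw = 1.0
                    weights, added = [], []
                    for _ in range(config.max_days + 1):
                        weights.append(final_weight + ftsw * config.ttsw_g if treated
                                       else config.initial_weight_g)
                        td = rate * min(1.0, ftsw / theta) * config.ttsw_g
                        if treated:
                            ftsw = max(0.0, ftsw - td / config.ttsw_g)
                            added.append(0.0)
                        else:
                            added.append(td)
                    s = PotTimeSeries(
                        plant_id=pid,
                        is_control=not treated,
                        day=np.arange(config.max_days + 1),
                        weight=np.array(weights),
                        water_added=np.array(added),
                        initial_weight=config.initial_weight_g,
                        final_weight=final_weight,
                    ).with_ftsw()
                    series.append(s)
    return series, rates, plant_rates


def _assign_harvests(series: list[PotTimeSeries]) -> dict[str, int]:
    """Apply the FDS and FIS harvest rules and pair controls with their plants."""
    harvest: dict[str, int] = {}
    fds_treated = [s for s in series if s.plant_id.startswith("FDS") and not s.is_control]
    fds_day = schedule_fds_harvest(fds_treated)
    for s in series:
        if s.plant_id.startswith("FDS"):
            harvest[s.plant_id] = fds_day
    for s in series:
        if s.plant_id.startswith("FIS") and not s.is_control:
            day = schedule_fis_harvest(s)
            harvest[s.plant_id] = day
            harvest[s.plant_id[:-1] + "C"] = day  # paired control, same day
    return harvest


# ---------------------------------------------------------------------------
# Truth planting


def plant_truth(config: SimulationConfig, rng: np.random.Generator) -> tuple[TruthRecord, dict]:
    """Draw the planted structure: effect classes, contrasts, trait gene sets."""
    genes = [f"HuCL{i+1:05d}C001" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)

    n_t = round(config.frac_treatment_genes * config.n_genes)
    n_g = round(config.frac_genotype_genes * config.n_genes)
    n_gt = round(config.frac_gxt_genes * config.n_genes)
    n_combo = round(config.frac_combo_genes * config.n_genes)
    combo_counts = [n_combo // 4 + (1 if i < n_combo % 4 else 0) for i in range(4)]
    counts = dict(zip(ANOVA_CLASSES, [n_t, n_g, n_gt] + combo_counts))

    effect_class = {g: "none" for g in genes}
    pos = 0
    for label, cnt in counts.items():
        for idx in order[pos : pos + cnt]:
            effect_class[genes[idx]] = label
        pos += cnt

    n_trait = config.n_phenotypes * config.genes_per_phenotype
    trait_slice = order[pos : pos + n_trait]
    pos += n_trait

    contrasts = _genotype_contrasts(config.n_genotypes)
    effect_signs, genotype_contrast, gxt_contrast = {}, {}, {}
    for g in genes:
        cls = effect_class[g]
        if cls == "none":
            continue
        effect_signs[g] = int(rng.choice([-1, 1]))
        if cls in ("g_o", "g_t", "g*t_g", "All"):
            genotype_contrast[g] = contrasts[rng.integers(len(contrasts))].tolist()
        if cls in ("g*t_o", "g*t_g", "g*t_t", "All"):
            gxt_contrast[g] = contrasts[rng.integers(len(contrasts))].tolist()

    trait_couplings = []
    for j, phen in enumerate(PHENOTYPE_NAMES):
        for idx in trait_slice[j * config.genes_per_phenotype : (j + 1) * config.genes_per_phenotype]:
            trait_couplings.append(
                {"gene": genes[idx], "phenotype": phen, "sign": int(rng.choice([-1, 1]))}
            )

    truth = TruthRecord(
        effect_class=effect_class,
        effect_signs=effect_signs,
        genotype_contrast=genotype_contrast,
        gxt_contrast=gxt_contrast,
        trait_couplings=trait_couplings,
        genotype_rates={},
    )
    aux = {"genes": genes, "contrasts": contrasts}
    return truth, aux


def _genotype_contrasts(n_genotypes: int) -> np.ndarray:
    """Balanced +-1 contrasts over genotypes (orthogonal when n is a power of 2)."""
    if n_genotypes >= 2 and n_genotypes & (n_genotypes - 1) == 0:
        from scipy.linalg import hadamard

        return hadamard(n_genotypes)[1:]  # drop the all-ones row
    if n_genotypes < 2:
        return np.zeros((1, n_genotypes))
    warnings.warn("non-power-of-2 genotype count: contrasts balanced but not orthogonal")
    base = np.array([1, -1] * (n_genotypes // 2) + [0] * (n_genotypes % 2))
    return np.stack([np.roll(base, k) for k in range(max(1, n_genotypes - 1))])


# ---------------------------------------------------------------------------
# Expression and phenotypes


def _sample_sheet(config: SimulationConfig, harvest: dict[str, int]) -> pd.DataFrame:
    rows = []
    for pid, day in harvest.items():
        scenario, block, geno, trt = pid.split("_")
        rows.append(
            {
                "sample": pid,
                "genotype": geno,
                "treatment": "stressed" if trt == "T" else "control",
                "block": int(block[1:]),
                "scenario": scenario,
                "harvest_day": day,
            }
        )
    df = pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)
    return df.set_index("sample", drop=False)


def _signal_profiles(
    config: SimulationConfig,
    truth: TruthRecord,
    aux: dict,
    samples: pd.DataFrame,
    itw: pd.Series,
) -> pd.DataFrame:
    """Per-gene noiseless signal over all samples (genes with any planting)."""
    genotypes = sorted(samples["genotype"].unique())
    g_index = {g: i for i, g in enumerate(genotypes)}
    x_t = np.where(samples["treatment"] == "stressed", 0.5, -0.5)
    gcodes = samples["genotype"].map(g_index).to_numpy()
    amp = config.effect_size_sd_units * config.noise_sd

    axes = _phenotype_axes(config, aux, samples, itw)

    signals = {}
    for gene, cls in truth.effect_class.items():
        if cls == "none":
            continue
        e = truth.effect_signs[gene]
        sig = np.zeros(len(samples))
        if cls in ("t_o", "g_t", "g*t_t", "All"):
            sig = sig + e * amp * x_t
        if cls in ("g_o", "g_t", "g*t_g", "All"):
            c = np.asarray(truth.genotype_contrast[gene])[gcodes]
            sig = sig + e * (amp / 2.0) * c
        if cls in ("g*t_o", "g*t_g", "g*t_t", "All"):
            c = np.asarray(truth.gxt_contrast[gene])[gcodes]
            sig = sig + e * amp * x_t * c
        signals[gene] = sig
    for coupling in truth.trait_couplings:
        profile = axes[coupling["phenotype"]]
        sig = signals.get(coupling["gene"], np.zeros(len(samples)))
        signals[coupling["gene"]] = sig + coupling["sign"] * amp * profile
    return pd.DataFrame(signals, index=samples.index).T  # genes x samples


def _phenotype_axes(
    config: SimulationConfig, aux: dict, samples: pd.DataFrame, itw: pd.Series
) -> dict[str, np.ndarray]:
    """Standardized noiseless profile of each phenotype, per scenario."""
    genotypes = sorted(samples["genotype"].unique())
    g_index = {g: i for i, g in enumerate(genotypes)}
    gcodes = samples["genotype"].map(g_index).to_numpy()
    contrasts = aux["contrasts"]
    axis_profiles = {}
    scen = samples["scenario"].to_numpy()
    f1 = np.zeros(len(samples))
    for s in np.unique(scen):
        mask = scen == s
        vals = itw.loc[samples.index[mask]].to_numpy(dtype=float)
        sd = vals.std()
        f1[mask] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    axis_profiles[0] = f1
    for axis in (1, 2):
        row = contrasts[(axis - 1) % len(contrasts)]
        axis_profiles[axis] = row[gcodes].astype(float)
    return {
        phen: float(sign) * axis_profiles[axis]
        for phen, (axis, sign) in PHENOTYPE_AXES.items()
    }


def simulate_expression(
    config: SimulationConfig,
    truth: TruthRecord,
    samples: pd.DataFrame,
    itw: pd.Series,
    aux: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Genes x samples log2 expression: baseline + planted signal + noise."""
    genes = aux["genes"]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    noise = rng.normal(0.0, config.noise_sd, size=(len(genes), len(samples)))
    expr = pd.DataFrame(
        baseline[:, None] + noise, index=pd.Index(genes, name="gene_id"), columns=samples.index
    )
    signals = _signal_profiles(config, truth, aux, samples, itw)
    expr.loc[signals.index] += signals.to_numpy()
    return expr


def simulate_phenotypes(
    config: SimulationConfig,
    truth: TruthRecord,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    itw: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-plant phenotype table.

    Each modeled phenotype is the signed mean of its planted gene set's
    expression plus Gaussian noise; ITW comes from the water simulation
    and stomatal conductance (gs) is an uncoupled pass-through
    measurement.  A phenotype with an empty gene set is pure noise.
    """
    table = pd.DataFrame(index=samples.index)
    couplings = pd.DataFrame(truth.trait_couplings) if truth.trait_couplings else None
    for phen in PHENOTYPE_NAMES:
        if phen == "ITW":
            table[phen] = itw.loc[samples.index]
            continue
        noise = rng.normal(0.0, config.phenotype_noise_sd, size=len(samples))
        if couplings is None or phen not in set(couplings["phenotype"]):
            table[phen] = noise
            continue
        sub = couplings[couplings["phenotype"] == phen]
        combo = np.zeros(len(samples))
        for _, row in sub.iterrows():
            combo += row["sign"] * expression.loc[row["gene"]].to_numpy()
        table[phen] = combo / len(sub) + noise
    table["gs"] = rng.normal(0.4, 0.05, size=len(samples))
    table.index.name = "plant_id"
    return table[PHENOTYPE_NAMES[:1] + ["E", "gs"] + PHENOTYPE_NAMES[2:]]


def implied_network_edges(
    config: SimulationConfig,
    truth: TruthRecord,
    aux: dict,
    samples: pd.DataFrame,
    itw: pd.Series,
    threshold: float = 0.65,
) -> dict[str, list[dict]]:
    """Model-implied gene-phenotype correlations above the network threshold.

    The implied correlation attenuates the noiseless signal-profile
    correlation by each side's noise share:

        cor = cov(sig_g, sig_ph) / sqrt((var sig_g + s2) (var sig_ph + s2_ph))

    evaluated per scenario on the realized profiles, with s2 the
    expression noise variance and s2_ph the phenotype noise variance plus
    the averaged-gene noise passed through the phenotype's gene mean.
    """
    signals = _signal_profiles(config, truth, aux, samples, itw)
    axes = _phenotype_axes(config, aux, samples, itw)
    amp = config.effect_size_sd_units * config.noise_sd
    k = max(config.genes_per_phenotype, 1)
    out: dict[str, list[dict]] = {}
    merged: dict[tuple, dict] = {}
    for scen in sorted(samples["scenario"].unique()):
        cols = samples.index[samples["scenario"] == scen]
        edges = []
        sig = signals[cols].to_numpy()
        sig_c = sig - sig.mean(axis=1, keepdims=True)
        gene_var = (sig_c**2).mean(axis=1) + config.noise_sd**2
        for phen in PHENOTYPE_NAMES:
            if phen == "ITW":
                ph_sig = itw.loc[cols].to_numpy(dtype=float)
                ph_noise_var = 0.0
            else:
                ph_sig = amp * axes[phen][samples.index.get_indexer(cols)]
                ph_noise_var = config.phenotype_noise_sd**2 + config.noise_sd**2 / k
            ph_c = ph_sig - ph_sig.mean()
            ph_var = (ph_c**2).mean() + ph_noise_var
            if ph_var <= 0:
                continue
            cov = (sig_c * ph_c).mean(axis=1)
            cors = cov / np.sqrt(gene_var * ph_var)
            for gi in np.nonzero(np.abs(cors) > threshold)[0]:
                gene = signals.index[gi]
                edge = {
                    "gene": gene,
                    "phenotype": phen,
                    "sign": int(np.sign(cors[gi])),
                    "implied_cor": float(cors[gi]),
                    "scenario": scen,
                }
                edges.append(edge)
                merged.setdefault((gene, phen), edge)
        out[scen] = edges
    out["merged"] = list(merged.values())
    return out


def generate_field_dataset(
    truth: TruthRecord,
    n_field_genes: int,
    enrichment_factor: float,
    seed: int,
    gene_universe: list[str] | None = None,
) -> list[str]:
    """Independent gene list enriched for network-linked genes.

    Sampling is without replacement with weight ``enrichment_factor`` on
    genes carrying at least one implied network edge and weight 1 on the
    rest, so a factor of 1 reduces to uniform sampling (hypergeometric
    overlap) and a large factor saturates the list with linked genes.
    """
    if gene_universe is None:
        gene_universe = sorted(truth.effect_class)
    if n_field_genes > len(gene_universe):
        raise ValueError("requested more field genes than exist")
    if n_field_genes == 0:
        return []
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    linked = truth.network_genes("merged")
    rng = np.random.default_rng(seed)
    weights = np.array([enrichment_factor if g in linked else 1.0 for g in gene_universe])
    # weighted sampling without replacement via exponential sort keys
    keys = rng.exponential(1.0, size=len(weights)) / weights
    chosen = np.argsort(keys)[:n_field_genes]
    return sorted(gene_universe[i] for i in chosen)


def generate_term_annotations(
    truth: TruthRecord, seed: int, n_terms: int = 25, mean_term_size: int = 40
) -> pd.DataFrame:
    """Synthetic gene->term annotations with a few effect-enriched terms.

    The first terms preferentially annotate planted effect-class genes so
    enrichment tests have signal to find; the rest are uniform draws.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth.effect_class)
    by_class: dict[str, list[str]] = {}
    for g, cls in truth.effect_class.items():
        by_class.setdefault(cls, []).append(g)
    rows = []
    enriched_classes = [c for c in ("t_o", "g_o", "g*t_o") if by_class.get(c)]
    for ti in range(n_terms):
        term = f"TERM:{ti+1:04d}"
        size = max(3, int(rng.poisson(mean_term_size)))
        if ti < len(enriched_classes):
            pool = sorted(by_class[enriched_classes[ti]])
            n_sig = min(len(pool), max(1, size // 2))
            members = list(rng.choice(pool, size=n_sig, replace=False))
            members += list(rng.choice(genes, size=size - n_sig, replace=False))
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        rows += [{"gene_id": g, "term_id": term} for g in sorted(set(members))]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Top-level


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> Dataset:
    """Run the full generator: water, harvests, expression, phenotypes, truth."""
    config = config or SimulationConfig()
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    seeds = ss.spawn(4)
    rng_expr = np.random.default_rng(seeds[1])
    rng_phen = np.random.default_rng(seeds[2])

    truth, aux = plant_truth(config, np.random.default_rng(seeds[0]))
    series, geno_rates, plant_rates = simulate_water_depletion(config, seed=seeds[3])
    truth.genotype_rates = {k: float(v) for k, v in geno_rates.items()}
    truth.plant_rates = {k: float(v) for k, v in plant_rates.items()}
    harvest = _assign_harvests(series)
    truth.harvest_day = {k: int(v) for k, v in harvest.items()}

    samples = _sample_sheet(config, harvest)
    itw = pd.Series(
        {
            s.plant_id: compute_itw(np.asarray(s.ftsw)[: max(harvest[s.plant_id], 1)])
            for s in series
        },
        name="ITW",
    )
    samples["ITW"] = itw.loc[samples.index]

    expression = simulate_expression(config, truth, samples, itw, aux, rng_expr)
    phenotypes = simulate_phenotypes(config, truth, expression, samples, itw, rng_phen)
    truth.implied_edges = implied_network_edges(config, truth, aux, samples, itw)
    return Dataset(
        config=config,
        expression=expression,
        samples=samples,
        phenotypes=phenotypes,
        pot_series=series,
        truth=truth,
    )
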