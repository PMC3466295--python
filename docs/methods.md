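# Methods

This note documents the models behind `drynet`, the choices made where the
underlying procedures admit more than one reasonable reading, and what the
synthetic benchmark does and does not demonstrate.

## Water balance and harvest scheduling

Pot water status is expressed as the fraction of transpirable soil water,
FTSW = clamp((W_day − W_final)/TTSW, 0, 1), with TTSW the initial-minus-final
weight of a drained-and-dried-down calibration pot. Control plants have their
transpired water restored daily, so their FTSW is fixed at 1. Negative raw
FTSW (a pot drier than the calibration endpoint) is clamped to 0 with a
logged warning rather than rejected: it reflects calibration noise, not a
data error.

Integrated transpired water is discretised as a daily rectangle sum,
ITW = Σ (1 − FTSW) from the day irrigation stops through the day before
harvest. The daily sum matches the daily weighing cadence; no sub-daily
interpolation is attempted.

The fixed-duration rule reads "50% of treated plants below FTSW 0.35"
inclusively (exactly half counts) and resolves ties to the earlier day; the
fixed-intensity rule takes each plant's first day strictly below FTSW 0.1 and
harvests its paired control the same day. RWC = (Fw − Dw)/(Tw − Dw) values
slightly outside [0, 1] are reported with a warning (clamping is opt-in),
since they arise from weighing noise. Transpiration rate E, stomatal
conductance gs, osmotic potential OP and carbon isotope discrimination CID
are consumed as measured numbers; no porometry or isotope physics is
modelled.

## Normalization

Block centering subtracts, per gene, the mean intensity of the samples in
each experimental block and adds back the gene's global mean, so block
shifts are removed while each gene's level (and hence non-negativity on the
log2 scale) is preserved. A one-sample block is legal and maps that sample to
the gene's global mean. Quantile normalization maps every sample's sorted
vector onto the mean sorted distribution; ties within a sample receive the
mean of the reference values across their tied ranks (the classic reference
behaviour). Operations run in that order, block centering first. By default
normalization is joint across scenarios, with a per-scenario flag; blocks
are always identified per (scenario, block) pair so blocks of different
scenarios are never mixed.

## Per-gene ANOVA

Each gene is fitted per scenario with
`expression ~ block + genotype + treatment + genotype:treatment`, all fixed
effects. On a balanced crossed design the factors are orthogonal, the
classical decomposition applies, and the fit is vectorised across genes; with
missing chips the implementation falls back to Type-II sums of squares
(statsmodels), which coincides with the classical decomposition when balance
holds. An empty genotype×treatment cell makes the interaction untestable and
raises.

Residual-variance pooling is an interpretation choice: Bartlett's test is
applied to the per-gene residual variances, and while it rejects at 5% the
largest-variance gene is removed, up to 25% of genes; the surviving
"homoscedastic set" shares the df-weighted mean residual variance and the
summed residual df as the F denominator, while trimmed genes keep their own.
Pooling concentrates the denominator df and mainly sharpens inference for
genes with underestimated variances.

Family-wise error is controlled per effect by Bonferroni with m = number of
genes tested in the scenario. Effect classes are the eight labels of the
(genotype, treatment, interaction) significance pattern; roll-ups ("at least
treatment", etc.) are always derived from the exclusive labels, never stored.
Tukey HSD uses all genotype×treatment cell pairs as the comparison family
(studentized range with k = number of cells) and reports the
treated-vs-control contrast within each genotype, using the pooled MSE
whenever the gene was pooled. Hierarchical clustering of genes and samples
uses 1 − Pearson distance with average linkage (both configurable); a
constant profile has undefined correlation and is assigned distance 1 with a
warning.

## Sparse PLS

The sPLS is written from scratch in regression mode. Columns of X (genes)
and Y (phenotypes) are centred and unit-variance scaled. Per component, the
weight pair is initialised from the leading singular vectors of M = X_hᵀY_h
and iterated: u ← soft-threshold(M v), v ← soft-threshold(Mᵀ u), each
renormalised, with the threshold set to the (keep+1)-th largest magnitude so
that exactly keepX (keepY) entries survive — a cardinality budget rather
than a continuous penalty, chosen for reproducibility (no λ tuning). Both
blocks are deflated on the X-variate, the asymmetric predict-Y-from-X
reading; this guarantees mutually orthogonal X-variates. Convergence: 1e-9
on the max absolute change of u, 500 iterations, warning on non-convergence.
Each component is oriented so its largest-|u| entry is positive, making fits
deterministic. Defaults: 3 components (the number of interpretable axes in
this design), keepX = 50 at the synthetic scale (100 suggested at full
microarray scale), keepY = all phenotypes. The dense limit (keep = all) is
checked against an SVD oracle, and the sparse fit against the mixOmics
reference implementation, in the test suite.

## Association network

The gene–phenotype association score is the latent-variate relevance
similarity score(i, j) = Σ_h cor(x_i, t_h)·cor(y_j, t_h), computed for every
gene (selected or not — sparsity selection is recorded as a flag but does
not gate scoring). This is documented as an interpretation: it is the
standard PLS relevance-network similarity and approaches the plain
gene–phenotype correlation as components accumulate. Scores may slightly
exceed 1 in magnitude with many components and are reported as-is with a
warning. Edges require |score| strictly above the threshold (default 0.65);
the scenario networks are merged by edge union with provenance tags, and
|FDS-only| + |shared| + |FIS-only| always equals the merged gene count.

## Enrichment

The hypergeometric pmf and upper tail use exact integer binomial
coefficients for universes up to 10⁴ (accurate to float rounding; this is
what lets pmf sums match 1 to 1e-12) and log-gamma evaluation in log space
beyond. Trait-link results report both the point probability — the statistic
conventionally printed for this test, displayed by truncation at three
decimals — and the upper tail, the statistically standard one-sided p. Term
enrichment tests every term with ≥ 1 query hit and ≥ 2 annotated universe
genes (the floor is configurable) and adjusts with Benjamini–Yekutieli, the
step-up procedure valid under arbitrary dependence. Annotations are consumed
as given; no ontology-graph propagation is performed.

## Synthetic benchmark

The generator reproduces the study design: 8 genotypes × 2 treatments × 3
blocks per scenario, 96 plants/chips. Water depletion follows a two-segment
transpiration response — full genotype-specific transpiration above FTSW 0.4,
linear decline below — with maximum daily depletion rates spread over
0.06–0.14 FTSW/day and ~8% per-plant lognormal jitter; with these rates the
FDS harvest lands around day 7 and the FIS harvests spread over the
following one to two weeks. TTSW defaults to 4000 g on an 18 kg pot.

Expression is baseline (N(8, 1) log2 units) plus additive effects plus
N(0, 0.5) noise. Planted effect classes populate all eight categories:
treatment shifts of 4 residual SD (a 4-fold change at this noise level, in
line with strong drought-responsive genes), balanced ±1 genotype contrasts
from a Hadamard basis, and zero-margin interaction patterns, with 4% / 8% /
2% / 4% of genes given treatment-only / genotype-only / interaction-only /
combination classes. Trait-linked genes couple to three latent axes — the
realized ITW (stress) axis and two orthogonal genotype contrasts — and each
non-ITW phenotype is the signed mean of its 15 planted genes plus N(0, 0.3)
noise; OP and E load negatively on the stress axis, so the negative OP–ITW
correlation structure of real drought data is reproduced. ITW itself comes
from the water simulation. The magnitudes of genotype vs treatment effects
are free parameters of the generator (the real study does not constrain
them); the defaults above were fixed once from the power analysis of the
design and are not calibrated to any real dataset.

Because phenotypes are driven by exactly three latent axes, the generative
gene–phenotype correlation structure has rank 3 and a 3-component sPLS can
represent it; real data need not be so kind, so recovery rates measured here
are an upper bound on what the pipeline achieves in practice. The truth
record stores, besides every planted element, the model-implied
gene–phenotype correlations (signal correlation attenuated by both noise
shares), and the network-recovery benchmark scores inferred edges against
the implied-correlation edge set at the same 0.65 threshold. Genes coupled
to phenotype axes are excluded from the effect-class agreement metric, since
their implied ANOVA class is a by-product of the axis they load on rather
than a planted label.

The generator does not emulate probe-level signal, RMA, hybridisation
artefacts, intensity-dependent variance, or correlated noise between genes;
conclusions from passing tests are about the statistical machinery, not
about microarray preprocessing.

## Problem sizes and determinism

Default synthetic runs use 2000 genes × 96 samples, small enough that a full
pipeline run takes on the order of a second; the acceptance script repeats
it over 20 seeds for the recovery estimates and over 200 simulated null
datasets (500 genes) for the FWER estimate. All randomness flows from a
single seed through `numpy.random.SeedSequence` spawns; identically
configured runs are bit-identical on serialized outputs, which the tests
assert.

## Known limitations

- The unbalanced (Type-II) ANOVA path fits gene by gene through statsmodels
  and is orders of magnitude slower than the balanced path; it is intended
  for a handful of missing chips, not heavily unbalanced designs.
- Bartlett-gated variance pooling is sensitive to heavy-tailed residuals;
  with strong departures from normality the trimming cap (25%) may leave a
  heteroscedastic pool (a warning is logged).
- Association scores are in-sample statistics; no cross-validation or
  stability selection is provided for the threshold or the sparsity budgets.
- The trait-link test conditions on the observed network; it does not
  propagate uncertainty in network construction.
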