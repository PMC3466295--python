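"""Per-gene two-way ANOVA and downstream effect classification.

Each gene is fitted, separately per drought scenario, with the fixed
effects model

    expression ~ block + genotype + treatment + genotype:treatment

On a balanced crossed design the factors are orthogonal and the classical
sum-of-squares decomposition applies; this path is vectorised across all
genes.  Unbalanced designs (missing chips) fall back to Type-II sums of
squares through statsmodels, gene by gene.

Residual variances may be pooled across genes: Bartlett's test is applied
to the per-gene residual variances, iteratively trimming the
largest-variance gene until homogeneity is accepted (capped at trimming
25% of genes); genes in the surviving homoscedastic set have their F
denominators recomputed with the common (df-weighted mean) residual
variance and the summed residual df.  Family-wise error across genes is
controlled per effect by Bonferroni, and each gene receives one of eight
effect-class labels from the significance pattern of (genotype,
treatment, genotype:treatment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

EFFECTS = ["block", "genotype", "treatment", "gxt"]

#: Effect-class vocabulary, from the 3-bit (genotype, treatment, gxt) pattern.
EFFECT_CLASSES = ["none", "t_o", "g_o", "g*t_o", "g_t", "g*t_g", "g*t_t", "All"]

_CLASS_MAP = {
    (0, 0, 0): "none",
    (0, 1, 0): "t_o",
    (1, 0, 0): "g_o",
    (0, 0, 1): "g*t_o",
    (1, 1, 0): "g_t",
    (1, 0, 1): "g*t_g",
    (0, 1, 1): "g*t_t",
    (1, 1, 1): "All",
}

#: Roll-up rows/columns of the scenario cross-tabulation.
ROLLUPS = {
    "Eff": ["t_o", "g_o", "g*t_o", "g_t", "g*t_g", "g*t_t", "All"],
    "t": ["t_o", "g_t", "g*t_t", "All"],
    "g": ["g_o", "g_t", "g*t_g", "All"],
    "g*t": ["g*t_o", "g*t_g", "g*t_t", "All"],
}


@dataclass
class AnovaResult:
    """Per-gene ANOVA table plus pooling metadata for one scenario."""

    table: pd.DataFrame  # index gene, columns F_/p_/p_bonf_/sig_ per effect
    pooled: pd.Series  # bool per gene: denominator used the pooled variance
    pooled_variance: float | None
    pooled_df: float | None
    residual_df: int

    @property
    def classes(self) -> pd.Series:
        return classify_effects(self.table)


def _is_balanced(design: pd.DataFrame) -> bool:
    counts = design.groupby(["block", "genotype", "treatment"], observed=True).size()
    full = (
        design["block"].nunique()
        * design["genotype"].nunique()
        * design["treatment"].nunique()
    )
    return len(counts) == full and counts.nunique() == 1


def _group_means(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-gene group means and counts for one factor coding. values: genes x n."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.zeros((values.shape[0], n_groups))
    np.add.at(sums.T, codes, values.T)
    return sums / counts, counts


def anova_balanced(values: np.ndarray, design: pd.DataFrame) -> dict[str, np.ndarray]:
    """Classical orthogonal decomposition, vectorised across genes.

    Returns per-effect sums of squares and dfs, plus residual SS/df.
    """
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    ss_total = ((values - grand) ** 2).sum(axis=1)

    ss = {}
    dfs = {}
    factor_codes = {}
    for factor in ["block", "genotype", "treatment"]:
        codes, uniques = pd.factorize(design[factor], sort=True)
        factor_codes[factor] = (codes, len(uniques))
        means, counts = _group_means(values, codes, len(uniques))
        ss[factor] = (counts * (means - grand) ** 2).sum(axis=1)
        dfs[factor] = len(uniques) - 1

    gcodes, ng = factor_codes["genotype"]
    tcodes, nt = factor_codes["treatment"]
    cell_codes = gcodes * nt + tcodes
    cell_means, cell_counts = _group_means(values, cell_codes, ng * nt)
    gmeans, _ = _group_means(values, gcodes, ng)
    tmeans, _ = _group_means(values, tcodes, nt)
    inter = (
        cell_means.reshape(-1, ng, nt)
        - gmeans[:, :, None]
        - tmeans[:, None, :]
        + grand[:, :, None]
    )
    ss["gxt"] = (cell_counts.reshape(ng, nt) * inter**2).sum(axis=(1, 2))
    dfs["gxt"] = (ng - 1) * (nt - 1)

    ss_model = sum(ss.values())
    ss_resid = np.maximum(ss_total - ss_model, 0.0)
    df_resid = n - 1 - sum(dfs.values())
    return {"ss": ss, "dfs": dfs, "ss_resid": ss_resid, "df_resid": df_resid}


def _anova_type2_gene(y: np.ndarray, design: pd.DataFrame) -> dict[str, tuple]:
    """Type-II sums of squares for one gene on an unbalanced design."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = design.copy()
    df["y"] = y
    model = smf.ols(
        "y ~ C(block) + C(genotype) + C(treatment) + C(genotype):C(treatment)", df
    ).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(block)": "block",
        "C(genotype)": "genotype",
        "C(treatment)": "treatment",
        "C(genotype):C(treatment)": "gxt",
    }
    out = {}
    for key, name in rename.items():
        out[name] = (tab.loc[key, "sum_sq"], tab.loc[key, "df"])
    out["resid"] = (tab.loc["Residual", "sum_sq"], tab.loc["Residual", "df"])
    return out


def fit_anova(
    values: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    pool: bool = True,
    bartlett_alpha: float = 0.05,
    max_trim: float = 0.25,
) -> AnovaResult:
    """Fit the per-gene model for one scenario and flag significant effects.

    ``values`` is genes x samples; ``design`` has one row per sample with
    columns block, genotype, treatment.  Bonferroni m = number of genes
    tested, applied per effect.
    """
    design = design.loc[values.columns]
    if design["genotype"].nunique() < 2 or design["treatment"].nunique() != 2:
        raise ValueError("design needs >=2 genotypes and exactly 2 treatments")
    cell_counts = design.groupby(["genotype", "treatment"], observed=True).size()
    n_cells = design["genotype"].nunique() * design["treatment"].nunique()
    if len(cell_counts) < n_cells:
        raise ValueError("empty genotype x treatment cell: design untestable")

    arr = values.to_numpy(dtype=float)
    genes = values.index
    m = len(genes)

    if _is_balanced(design):
        parts = anova_balanced(arr, design)
        ss, dfs = parts["ss"], parts["dfs"]
        ss_resid, df_resid = parts["ss_resid"], parts["df_resid"]
    else:
        logger.info("unbalanced design: falling back to per-gene Type-II fits")
        ss = {e: np.empty(m) for e in EFFECTS}
        dfs = {}
        ss_resid = np.empty(m)
        for i in range(m):
            res = _anova_type2_gene(arr[i], design)
            for e in EFFECTS:
                ss[e][i] = res[e][0]
                dfs[e] = int(res[e][1])
            ss_resid[i] = res["resid"][0]
        df_resid = int(res["resid"][1])

    resid_var = ss_resid / df_resid
    pooled_mask = np.zeros(m, dtype=bool)
    pooled_variance = pooled_df = None
    if pool and m >= 2:
        pooled_mask, pooled_variance, pooled_df = pool_residual_variance(
            resid_var, np.full(m, df_resid), alpha_bartlett=bartlett_alpha, max_trim=max_trim
        )
    elif pool:
        warnings.warn("fewer than 2 genes: residual variances not pooled", stacklevel=2)

    if pooled_variance is None:
        denom = resid_var
        denom_df = np.full(m, float(df_resid))
    else:
        denom = np.where(pooled_mask, pooled_variance, resid_var)
        denom_df = np.where(pooled_mask, pooled_df, float(df_resid))

    table = pd.DataFrame(index=genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        for e in EFFECTS:
            ms = ss[e] / dfs[e]
            f = np.where(denom > 0, ms / denom, np.where(ms > 0, np.inf, 0.0))
            p = stats.f.sf(f, dfs[e], denom_df)
            p = np.where(np.isnan(p), 1.0, p)
            table[f"F_{e}"] = f
            table[f"p_{e}"] = p
            table[f"p_bonf_{e}"] = adjust_bonferroni(p, m)
            table[f"sig_{e}"] = table[f"p_bonf_{e}"] < alpha
    table["resid_var"] = resid_var
    table["pooled"] = pooled_mask
    return AnovaResult(
        table=table,
        pooled=pd.Series(pooled_mask, index=genes),
        pooled_variance=pooled_variance,
        pooled_df=pooled_df,
        residual_df=df_resid,
    )


def _bartlett_from_variances(variances: np.ndarray, dfs: np.ndarray) -> float:
    """Bartlett's homogeneity p-value from per-group variances and dfs."""
    k = len(variances)
    if k < 2:
        return 1.0
    total_df = dfs.sum()
    sp2 = float((dfs * variances).sum() / total_df)
    if sp2 <= 0:
        return 1.0
    stat = total_df * np.log(sp2) - (dfs * np.log(variances)).sum()
    corr = 1.0 + ((1.0 / dfs).sum() - 1.0 / total_df) / (3.0 * (k - 1))
    return float(stats.chi2.sf(stat / corr, k - 1))


def pool_residual_variance(
    residual_variances: np.ndarray,
    residual_dfs: np.ndarray,
    alpha_bartlett: float = 0.05,
    max_trim: float = 0.25,
) -> tuple[np.ndarray, float, float]:
    """Find the homoscedastic gene set and its common residual variance.

    Bartlett's test is run on the candidate set; while it rejects, the
    gene with the largest residual variance is removed, up to ``max_trim``
    of the genes.  Returns (membership mask, pooled variance, pooled df).
    Genes with non-positive residual variance are excluded up front.
    """
    variances = np.asarray(residual_variances, dtype=float)
    dfs = np.asarray(residual_dfs, dtype=float)
    m = len(variances)
    alive = variances > 0
    order = np.argsort(variances)  # ascending; trim from the top
    order = order[alive[order]]
    max_removed = int(np.floor(max_trim * m))
    removed = 0
    while True:
        idx = order[: len(order) - removed] if removed else order
        p = _bartlett_from_variances(variances[idx], dfs[idx])
        if p >= alpha_bartlett or removed >= max_removed or len(idx) <= 2:
            if p < alpha_bartlett:
                logger.warning(
                    "Bartlett still rejects after trimming %d genes (p=%.3g); "
                    "pooling the surviving set",
                    removed,
                    p,
                )
            break
        removed += 1
    mask = np.zeros(m, dtype=bool)
    mask[idx] = True
    pooled_df = float(dfs[mask].sum())
    pooled_variance = float((dfs[mask] * variances[mask]).sum() / pooled_df)
    return mask, pooled_variance, pooled_df


def adjust_bonferroni(raw_p: np.ndarray, m: int) -> np.ndarray:
    """p_adj = min(1, p * m), with m the number of genes tested."""
    return np.minimum(1.0, np.asarray(raw_p, dtype=float) * m)


def tukey_hsd_by_genotype(
    expr_row: np.ndarray,
    design: pd.DataFrame,
    mse: float,
    df_resid: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Treated-vs-control HSD contrast within each genotype.

    The comparison family is all genotype x treatment cell pairs, so the
    studentized-range critical value uses k = number of cells with the
    model's (possibly pooled) MSE.  Log2 expression makes 2**difference
    the fold change.
    """
    if mse <= 0:
        raise ValueError("degenerate model: MSE must be positive for HSD")
    df = design.copy()
    df["y"] = np.asarray(expr_row, dtype=float)
    cells = df.groupby(["genotype", "treatment"], observed=True)["y"].agg(["mean", "size"])
    k = len(cells)
    treatments = sorted(design["treatment"].unique())
    control, treated = treatments[0], treatments[1]
    rows = []
    for g in sorted(design["genotype"].unique()):
        m_c, n_c = cells.loc[(g, control)]
        m_t, n_t = cells.loc[(g, treated)]
        diff = m_t - m_c
        se = np.sqrt(mse / 2.0 * (1.0 / n_c + 1.0 / n_t))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append(
            {
                "genotype": g,
                "difference": diff,
                "q": q,
                "p": p,
                "significant": p < alpha,
                "fold_change": 2.0**diff,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")


def classify_effects(anova_table: pd.DataFrame) -> pd.Series:
    """Map the (genotype, treatment, gxt) significance bits to effect classes."""
    sig_g = anova_table["sig_genotype"].astype(int)
    sig_t = anova_table["sig_treatment"].astype(int)
    sig_gt = anova_table["sig_gxt"].astype(int)
    labels = [
        _CLASS_MAP[(g, t, gt)] for g, t, gt in zip(sig_g, sig_t, sig_gt)
    ]
    return pd.Series(
        pd.Categorical(labels, categories=EFFECT_CLASSES), index=anova_table.index
    )


def cross_tabulate_scenarios(
    classes_fds: pd.Series, classes_fis: pd.Series
) -> pd.DataFrame:
    """Scenario-by-scenario contingency table with roll-up rows and columns.

    Rows are FIS classes, columns FDS classes; roll-ups (Eff, t, g, g*t)
    count genes belonging to any of their constituent exclusive classes.
    """
    if set(classes_fds.index) != set(classes_fis.index):
        raise ValueError("FDS and FIS classifications cover different gene sets")
    classes_fis = classes_fis.loc[classes_fds.index]
    member = {}
    for label in EFFECT_CLASSES:
        member[label] = [label]
    member.update(ROLLUPS)
    names = EFFECT_CLASSES + list(ROLLUPS)
    fds_sets = {k: classes_fds.isin(v).to_numpy() for k, v in member.items()}
    fis_sets = {k: classes_fis.isin(v).to_numpy() for k, v in member.items()}
    out = pd.DataFrame(
        {c: [int((fis_sets[r] & fds_sets[c]).sum()) for r in names] for c in names},
        index=pd.Index(names, name="FIS"),
    )
    out.columns.name = "FDS"
    return out


def hierarchical_bicluster(
    values: pd.DataFrame, method: str = "average"
) -> dict[str, object]:
    """Double hierarchical classification of genes and of samples.

    Distance is 1 - Pearson correlation with the given linkage (average by
    default); constant rows or columns have undefined correlation and get
    distance 1 with a warning.  Returns linkage matrices, leaf orders and
    Newick serializations.
    """
    if values.shape[0] < 1 or values.shape[1] < 2:
        raise ValueError("need at least 1 gene and 2 samples")

    def _cluster(mat: np.ndarray, labels) -> dict[str, object]:
        if mat.shape[0] == 1:
            return {"order": list(labels), "linkage": None, "newick": f"{labels[0]};"}
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat)
        if np.isnan(corr).any():
            warnings.warn("constant profile: correlation undefined, distance set to 1")
            corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        link = hierarchy.linkage(squareform(dist, checks=False), method=method)
        order = [labels[i] for i in hierarchy.leaves_list(link)]
        return {"order": order, "linkage": link, "newick": _to_newick(link, list(labels))}

    arr = values.to_numpy(dtype=float)
    return {
        "genes": _cluster(arr, list(values.index)),
        "samples": _cluster(arr.T, list(values.columns)),
    }


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
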