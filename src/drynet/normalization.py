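"""Post-summarization normalization of the expression matrix.

Two steps, applied to a genes x samples matrix of log2-scale intensities:

1. Block centering: per gene, subtract the mean intensity within each
   experimental block and add back the gene's global mean, removing
   block-to-block shifts while preserving the gene's overall level.
2. Quantile normalization: force every sample's empirical distribution
   onto the common reference distribution (the row-wise mean of the
   sorted sample vectors); ties within a sample receive the mean of the
   reference values at their tied ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def block_center(values: pd.DataFrame, blocks: pd.Series) -> pd.DataFrame:
    """Center each gene within blocks and restore its global mean.

    value'(g, s) = value(g, s) - mean_{block(s)} value(g, .) + mean value(g, .)

    ``blocks`` maps sample id -> block label and must cover every column.
    """
    blocks = blocks.reindex(values.columns)
    if blocks.isna().any():
        missing = list(values.columns[blocks.isna()])
        raise ValueError(f"samples without block annotation: {missing}")
    out = values.copy()
    global_mean = values.mean(axis=1)
    for _, cols in values.columns.to_series().groupby(blocks, sort=False):
        sub = values[cols]
        out[cols.index] = sub.sub(sub.mean(axis=1), axis=0).add(global_mean, axis=0)
    return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples against the mean sorted distribution.

    After the operation every column's sorted vector equals the row-wise
    mean of the sorted input columns.  Tied values within a sample are
    assigned the mean of the reference values spanning their tied ranks
    (the classic reference behavior).
    """
    arr = values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(n_samples):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_genes)
        ranked[order] = reference
        # ties: average the reference values over each run of equal inputs
        sorted_col = col[order]
        boundaries = np.nonzero(np.diff(sorted_col) != 0)[0] + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[order[s:e]] = reference[s:e].mean()
        out[:, j] = ranked
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample annotation CSV (sample, genotype, treatment, block, scenario)."""
    df = pd.read_csv(path)
    required = {"sample", "genotype", "treatment", "block", "scenario"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df.set_index("sample", drop=False)


def normalize_expression(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    per_scenario: bool = False,
) -> pd.DataFrame:
    """Block-center then quantile-normalize, jointly or per scenario.

    Block labels are taken per (scenario, block) pair so that blocks from
    different scenarios are never mixed during centering.
    """
    samples = samples.loc[values.columns]
    blocks = samples["scenario"].astype(str) + ":" + samples["block"].astype(str)
    if per_scenario:
        parts = []
        for scen in samples["scenario"].unique():
            cols = samples.index[samples["scenario"] == scen]
            parts.append(quantile_normalize(block_center(values[cols], blocks[cols])))
        return pd.concat(parts, axis=1)[values.columns]
    return quantile_normalize(block_center(values, blocks))
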