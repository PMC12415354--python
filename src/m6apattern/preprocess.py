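"""Unit conversions and cross-cohort harmonisation.

FPKM columns are renormalised to TPM (each sample sums to 1e6), TPM is
log2(x+1)-transformed, and cohorts are merged on their common genes
after per-cohort gene-wise z-standardisation so that RNA-seq and array
scales become comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: TPM_gj = FPKM_gj / sum_g FPKM_gj * 1e6."""
    m.require_unit("FPKM")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero or negative FPKM column sum for sample(s): {zero.index.tolist()[:5]}")
    tpm = m.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, unit="TPM", cohort=m.cohort)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1)."""
    m.require_unit("TPM")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative TPM value; cannot log-transform")
    return ExpressionMatrix(np.log2(m.values + 1.0), unit="log2TPM1", cohort=m.cohort)


def standardize_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise z-score across samples; constant genes map to 0."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1).replace(0.0, 1.0).fillna(1.0)
    return values.sub(mu, axis=0).div(sd, axis=0)


def merge_cohorts(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cohorts on their common genes after per-cohort z-scoring.

    Each input matrix is treated as one batch: its genes are standardised
    to mean 0, sd 1 within the cohort before concatenation.  The result
    carries unit ``zscore`` and retains per-sample cohort labels.
    """
    if not matrices:
        raise ValueError("no cohorts to merge")
    for m in matrices:
        m.require_unit("log2TPM1", "zscore")
    common = matrices[0].gene_ids
    for m in matrices[1:]:
        common = common.intersection(m.gene_ids)
    if len(common) == 0:
        raise ValueError("cohorts share no genes; cannot merge")
    blocks, cohorts = [], []
    for i, m in enumerate(matrices):
        z = standardize_genes(m.values.loc[common])
        blocks.append(z)
        labels = m.cohort.copy()
        if len(matrices) > 1 and (labels == "cohort").all():
            # disambiguate unlabelled inputs
            labels = pd.Series(f"cohort{i}", index=labels.index)
        cohorts.append(labels)
    merged = pd.concat(blocks, axis=1)
    cohort = pd.concat(cohorts)
    return ExpressionMatrix(merged, unit="zscore", cohort=cohort)
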