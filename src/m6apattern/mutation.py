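"""Tumor mutation burden and mutation-profile summaries.

A mutation table is a MAF-like record set (sample_id, gene,
variant_classification).  TMB counts nonsynonymous records per sample
(missense, nonsense, frameshift, splice), optionally per megabase of
exome; samples absent from the table carry TMB 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import survival as surv

logger = logging.getLogger(__name__)

NONSYNONYMOUS = {
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
}
SYNONYMOUS = {"Silent", "Synonymous"}
KNOWN_CLASSES = NONSYNONYMOUS | SYNONYMOUS

DEFAULT_EXOME_MB = 38.0


def _check_classes(mut: pd.DataFrame) -> None:
    unknown = set(mut["variant_classification"].unique()) - KNOWN_CLASSES
    if unknown:
        raise ValueError(f"unknown variant classification(s): {sorted(unknown)}")


def compute_tmb(mut: pd.DataFrame, samples, mode: str = "count",
                exome_mb: float = DEFAULT_EXOME_MB) -> pd.Series:
    """Per-sample TMB: nonsynonymous record count, or count / exome_mb."""
    if mode not in ("count", "per_mb"):
        raise ValueError(f"unknown TMB mode {mode!r}")
    samples = list(samples)
    if len(mut):
        _check_classes(mut)
        nonsyn = mut[mut["variant_classification"].isin(NONSYNONYMOUS)]
        counts = nonsyn.groupby("sample_id").size()
    else:
        counts = pd.Series(dtype=float)
    tmb = counts.reindex(samples).fillna(0.0).astype(float)
    if mode == "per_mb":
        if exome_mb <= 0:
            raise ValueError("exome_mb must be positive")
        tmb = tmb / exome_mb
    tmb.name = "tmb"
    return tmb


def regulator_mutation_frequency(mut: pd.DataFrame, regulator_genes,
                                 n_cohort: int) -> tuple[float, int]:
    """Fraction (percent) and count of samples with >= 1 nonsynonymous
    record in any regulator gene.

    A sample with only synonymous regulator records counts as
    non-mutated; duplicated identical records count once per sample.
    """
    if n_cohort <= 0:
        raise ValueError("cohort size must be positive")
    if len(mut) == 0:
        return 0.0, 0
    _check_classes(mut)
    reg = mut[
        mut["gene"].isin(set(regulator_genes))
        & mut["variant_classification"].isin(NONSYNONYMOUS)
    ]
    count = int(reg["sample_id"].nunique())
    fraction = round(100.0 * count / n_cohort, 2)
    return fraction, count


def mutated_sample_frequency(n_mutated: int, n_cohort: int) -> float:
    """Percent of a cohort carrying a mutation, rounded to 2 decimals."""
    if n_cohort <= 0:
        raise ValueError("cohort size must be positive")
    return round(100.0 * n_mutated / n_cohort, 2)


def tmb_median_split(tmb: pd.Series) -> pd.Series:
    """High/low TMB at the median; ties go to the low group."""
    if len(tmb) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(np.median(tmb.to_numpy(float)))
    if (tmb == tmb.iloc[0]).all():
        raise ValueError("all TMB values identical; no split exists")
    return pd.Series(np.where(tmb > med, "high", "low"), index=tmb.index, name="tmb_group")


def joint_strata(score_group: pd.Series, tmb_group: pd.Series,
                 times, events):
    """Cross-classify binary score and TMB groups; log-rank across strata.

    Empty strata are dropped from the test with a warning (the df
    adjusts accordingly).  Returns (stratum labels, LogrankResult).
    """
    for g, name in ((score_group, "score"), (tmb_group, "tmb")):
        if g.nunique() > 2:
            raise ValueError(f"{name} grouping must be binary")
    strata = score_group.astype(str) + "_score/" + tmb_group.reindex(score_group.index).astype(str) + "_tmb"
    counts = strata.value_counts()
    expected = {f"{s}_score/{t}_tmb" for s in score_group.unique() for t in tmb_group.unique()}
    missing = expected - set(counts.index)
    if missing:
        logger.warning("empty joint stratum(s) dropped: %s", sorted(missing))
    res = surv.logrank_test(np.asarray(times, float), np.asarray(events, int),
                            strata.to_numpy())
    return strata, res


def mutation_summary(mut: pd.DataFrame, n_cohort: int | None = None,
                     top_n: int = 10) -> pd.DataFrame:
    """Genes ranked by the fraction of samples with >= 1 nonsynonymous record."""
    if len(mut) == 0:
        return pd.DataFrame(columns=["gene", "n_samples", "fraction"]).set_index("gene")
    _check_classes(mut)
    nonsyn = mut[mut["variant_classification"].isin(NONSYNONYMOUS)]
    total = n_cohort if n_cohort is not None else mut["sample_id"].nunique()
    per_gene = nonsyn.groupby("gene")["sample_id"].nunique().sort_values(ascending=False)
    df = pd.DataFrame({"n_samples": per_gene, "fraction": per_gene / total})
    return df.head(top_n)
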