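"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices and clinical tables travel as TSV, gene sets as GMT,
and mutation records as a MAF-like TSV with columns ``sample_id``,
``gene`` and ``variant_classification``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


def read_expression(path: str | Path, unit: str, cohort: pd.Series | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Duplicate gene rows are collapsed by their mean (logged); duplicate
    sample columns and non-numeric cells are errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({s for s in header if header.count(s) > 1})
    if dups:
        raise ValueError(f"duplicate sample id(s) in {path}: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.any().any():
        gi, sj = next(zip(*bad.to_numpy().nonzero()))
        raise ValueError(
            f"non-numeric cell {df.iloc[gi, sj]!r} at gene {df.index[gi]!r}, "
            f"sample {df.columns[sj]!r} in {path}"
        )
    if num.isna().any().any():
        gi, sj = next(zip(*num.isna().to_numpy().nonzero()))
        raise ValueError(f"missing value at gene {df.index[gi]!r}, sample {df.columns[sj]!r} in {path}")
    if num.index.duplicated().any():
        dup_genes = num.index[num.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene row(s) by mean: %s",
                       len(dup_genes), dup_genes[:5])
        num = num.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(num, unit=unit, cohort=cohort)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV indexed by its first column (sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like TSV with columns sample_id, gene, variant_classification."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "gene", "variant_classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table {path} is missing column(s): {sorted(missing)}")
    return df


def write_mutations(mut: pd.DataFrame, path: str | Path) -> None:
    mut.to_csv(path, sep="\t", index=False)
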