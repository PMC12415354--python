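"""Core in-memory containers shared by every pipeline stage.

All containers are thin validated wrappers around pandas objects: an
expression matrix is genes x samples, a clinical table is indexed by
sample id, and a gene-set collection maps set names to member lists
(GMT semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised expression units. Transitions between them are explicit:
#: FPKM -> TPM (library-size renormalisation), TPM -> log2TPM1
#: (log2(x+1)), log2TPM1/zscore after per-cohort standardisation.
UNITS = ("FPKM", "TPM", "log2TPM1", "zscore")


class UnitError(ValueError):
    """An operation received expression values in the wrong unit."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    unit
        One of :data:`UNITS`.
    cohort
        Optional per-sample cohort label (Series indexed by sample id).
        Defaults to a single cohort named ``"cohort"``.
    """

    values: pd.DataFrame
    unit: str
    cohort: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnitError(f"unknown expression unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.cohort is None:
            self.cohort = pd.Series("cohort", index=self.values.columns)
        else:
            self.cohort = self.cohort.reindex(self.values.columns)
            if self.cohort.isna().any():
                missing = self.cohort.index[self.cohort.isna()].tolist()
                raise ValueError(f"samples missing a cohort label: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_unit(self, *units: str) -> None:
        if self.unit not in units:
            raise UnitError(f"operation requires unit in {units}, got {self.unit!r}")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.unit, self.cohort)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)], self.unit, self.cohort.loc[list(samples)]
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations, indexed by sample id.

    Required columns: ``time`` (survival time in days, > 0) and ``event``
    (1 = death, 0 = censored).  Optional columns: ``stage``, ``osahs``
    (binary), ``response`` (categorical) and arbitrary extra covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table is missing required column {col!r}")
        time = self.data["time"]
        if (time[time.notna()] <= 0).any():
            raise ValueError("survival times must be > 0")
        ev = self.data["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def aligned_to(self, sample_ids) -> "ClinicalTable":
        """Restrict and reorder to the given samples; all must be present."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples without clinical records: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restricted_to(self, genes, min_size: int = 2) -> "GeneSetCollection":
        """Drop members absent from `genes`; skip sets shrinking below `min_size`."""
        universe = set(genes)
        kept: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            present = [g for g in members if g in universe]
            if len(present) < min_size:
                logger.warning(
                    "gene set %r shrank to %d member(s) after intersection; skipped",
                    name, len(present),
                )
                continue
            kept[name] = present
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})
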