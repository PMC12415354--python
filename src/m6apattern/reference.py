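"""Reference constants: the m6A regulator panel and study cohort sizes."""

from __future__ import annotations

#: The 23-gene m6A regulator panel: 8 methyltransferases ("writers"),
#: 2 demethylases ("erasers"), and 13 RNA-binding readers.
M6A_WRITERS = [
    "METTL3", "METTL14", "METTL16", "RBM15", "RBM15B", "WTAP", "ZC3H13", "VIRMA",
]
M6A_ERASERS = ["FTO", "ALKBH5"]
M6A_READERS = [
    "YTHDC1", "YTHDC2", "YTHDF1", "YTHDF2", "YTHDF3", "LRPPRC", "IGF2BP1",
    "IGF2BP2", "IGF2BP3", "HNRNPC", "HNRNPA2B1", "FMR1", "RBMX",
]
M6A_REGULATORS = M6A_WRITERS + M6A_ERASERS + M6A_READERS

#: Case counts of the LUAD cohorts pooled in the reference analysis
#: (TCGA-LUAD plus six GEO series).
LUAD_COHORT_SIZES = {
    "TCGA-LUAD": 481,
    "GSE19188": 39,
    "GSE30219": 85,
    "GSE3141": 57,
    "GSE37745": 106,
    "GSE50081": 129,
    "GSE8894": 76,
}

#: Genes recurrently mutated in LUAD; default panel for the mutation simulator.
LUAD_MUTATION_PANEL = [
    "TP53", "CSMD3", "PCLO", "XIRP2", "ANK2", "TTN", "MUC16", "RYR2",
    "LRP1B", "ZFHX4", "USH2A", "KRAS", "FLG", "SPTA1", "NAV3",
]


def total_cases(cohort_sizes: dict[str, int] | None = None) -> int:
    """Total number of cases across the pooled cohorts."""
    sizes = LUAD_COHORT_SIZES if cohort_sizes is None else cohort_sizes
    return int(sum(sizes.values()))
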