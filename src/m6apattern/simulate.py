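"""Synthetic LUAD-like cohorts with planted structure and ground truth.

The generator emulates the statistical skeleton the analysis assumes:

* a 23-gene regulator panel whose expression separates two planted
  modification patterns (signed mean shifts of +-delta/2),
* signature genes with three cluster-specific mean profiles built from
  two orthogonal cluster contrasts, so the between-cluster variation
  spans two principal components,
* a planted per-sample score (a fixed linear combination of the
  signature-gene mean profiles) that drives proportional-hazards
  survival, a logistic OSAHS label, and a negative-binomial mutation
  burden,
* pure-noise genes.

Every generator is a deterministic function of the single seed; each
stage derives its own sub-stream from (stage tag, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.special import expit, logit

from .datatypes import ClinicalTable, ExpressionMatrix
from .reference import LUAD_MUTATION_PANEL, M6A_REGULATORS

#: cluster contrasts defining the signature-gene mean profiles; u1 and u2
#: are orthogonal under the cluster probabilities used below
U1 = {"A": -1.0, "B": 0.0, "C": 1.0}
U2 = {"A": 1.0, "B": -2.0, "C": 1.0}
#: weight of the second contrast in the planted score
SCORE_GAMMA = 0.8
#: gene-cluster distribution conditional on the m6A pattern.  The two are
#: coupled (as in a real cohort, where the downstream gene clusters are
#: derived from pattern DEGs) with marginal proportions (0.2, 0.4, 0.4),
#: an uneven A < B ~ C split.
CLUSTER_PROBS_BY_PATTERN = {
    "A": {"A": 0.30, "B": 0.55, "C": 0.15},
    "B": {"A": 0.10, "B": 0.25, "C": 0.65},
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the master seed."""
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng([tag, int(seed)])


@dataclass
class SimulationParams:
    """Generator settings; defaults define the standard study conditions."""

    n_samples: int = 500
    n_regulators: int = 23
    n_signature_genes: int = 60
    n_noise_genes: int = 100
    delta: float = 2.0               # mean shift between patterns, sd units
    baseline_hazard: float = 1.0 / 1000.0   # events per day at score 0
    hazard_beta: float = 1.0         # log-hazard per sd of planted score
    censoring_rate: float = 0.3
    osahs_p_high: float = 0.62       # target prevalence, top score half
    osahs_p_low: float = 0.46        # target prevalence, bottom score half
    osahs_intercept: float | None = None   # direct (a, b) override
    osahs_slope: float | None = None
    tmb_base_mean: float = 100.0     # nonsynonymous mutations at score 0
    tmb_slope: float = 0.5           # log-mean TMB per sd of score
    tmb_dispersion: float = 2.0      # negative-binomial size parameter
    synonymous_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_regulators", "n_signature_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class CohortTruth:
    """Planted ground truth used by recovery tests."""

    pattern_label: pd.Series          # per sample, {A, B}
    gene_cluster_label: pd.Series     # per sample, {A, B, C}
    true_score: pd.Series             # per sample, cluster-determined
    regulator_genes: list[str]
    signature_genes: list[str]
    noise_genes: list[str]
    signature_axis: pd.Series         # per signature gene: "u1" or "u2"
    hazard_beta: float = 0.0
    censoring_rate: float = 0.0
    osahs_logit_slope: float = 0.0
    osahs_logit_intercept: float = 0.0


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_expression(params: SimulationParams) -> tuple[ExpressionMatrix, CohortTruth]:
    """Expression matrix with planted patterns, gene clusters and score."""
    n = params.n_samples
    if n < 6:
        raise ValueError("need at least 6 samples (2 x number of gene clusters)")
    rng = stage_rng(params.seed, "expression")
    samples = [f"S{i:04d}" for i in range(n)]

    pattern = rng.choice(["A", "B"], size=n)
    clusters = np.empty(n, dtype="<U1")
    for pat, probs in CLUSTER_PROBS_BY_PATTERN.items():
        mask = pattern == pat
        clusters[mask] = rng.choice(list(probs), size=int(mask.sum()),
                                    p=list(probs.values()))

    # regulators: signed +-delta/2 shifts by pattern
    n_reg = params.n_regulators
    reg_names = (M6A_REGULATORS[:n_reg] if n_reg <= len(M6A_REGULATORS)
                 else M6A_REGULATORS + [f"REG{i}" for i in range(n_reg - len(M6A_REGULATORS))])
    reg_sign = np.where(np.arange(n_reg) % 2 == 0, 1.0, -1.0)
    pat_sign = np.where(pattern == "A", 1.0, -1.0)
    reg_mean = 0.5 * params.delta * np.outer(reg_sign, pat_sign)
    reg_vals = reg_mean + rng.standard_normal((n_reg, n))

    # signature genes: three cluster-specific mean profiles from two contrasts
    n_sig = params.n_signature_genes
    sig_names = [f"SIG{i:03d}" for i in range(n_sig)]
    n_u1 = int(round(0.6 * n_sig))
    axis = np.array(["u1"] * n_u1 + ["u2"] * (n_sig - n_u1))
    sig_sign = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
    u1_vec = np.array([U1[c] for c in clusters])
    u2_vec = np.array([U2[c] for c in clusters])
    amp = np.where(axis == "u1", 0.5 * params.delta, 0.35 * params.delta)
    contrast = np.where(axis[:, None] == "u1", u1_vec[None, :], u2_vec[None, :])
    sig_mean = (amp * sig_sign)[:, None] * contrast
    sig_vals = sig_mean + rng.standard_normal((n_sig, n))

    noise_names = [f"NOISE{i:03d}" for i in range(params.n_noise_genes)]
    noise_vals = rng.standard_normal((params.n_noise_genes, n))

    values = pd.DataFrame(
        np.vstack([reg_vals, sig_vals, noise_vals]),
        index=reg_names + sig_names + noise_names,
        columns=samples,
    )
    true_score = u1_vec + SCORE_GAMMA * u2_vec
    truth = CohortTruth(
        pattern_label=pd.Series(pattern, index=samples),
        gene_cluster_label=pd.Series(clusters, index=samples),
        true_score=pd.Series(true_score, index=samples),
        regulator_genes=list(reg_names),
        signature_genes=sig_names,
        noise_genes=noise_names,
        signature_axis=pd.Series(axis, index=sig_names),
        hazard_beta=params.hazard_beta,
        censoring_rate=params.censoring_rate,
    )
    return ExpressionMatrix(values, unit="log2TPM1"), truth


def simulate_survival(truth: CohortTruth, params: SimulationParams) -> ClinicalTable:
    """Exponential survival with hazard h0 * exp(beta * standardized score).

    Censoring times are uniform on (0, c_max) with c_max calibrated by
    bisection so the realised censoring fraction matches the target.
    """
    if params.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = stage_rng(params.seed, "survival")
    z = _standardize(truth.true_score.to_numpy())
    n = len(z)
    hazard = params.baseline_hazard * np.exp(params.hazard_beta * z)
    T = rng.exponential(1.0, size=n) / hazard
    if params.censoring_rate == 0:
        times, events = T, np.ones(n, int)
    else:
        u = rng.uniform(size=n)

        def censored_frac(cmax):
            return float((u * cmax < T).mean()) - params.censoring_rate

        lo, hi = T.min() * 1e-6, T.max() * 10
        if censored_frac(hi) > 0:
            cmax = hi
        else:
            cmax = brentq(censored_frac, lo, hi, xtol=1e-8 * hi)
        C = u * cmax
        events = (T <= C).astype(int)
        times = np.minimum(T, C)
    data = pd.DataFrame({"time": np.maximum(times, 1e-9), "event": events},
                        index=truth.true_score.index)
    return ClinicalTable(data)


def simulate_osahs(truth: CohortTruth, params: SimulationParams) -> pd.Series:
    """Binary OSAHS labels with P(osahs) = logistic(a + b * standardized score).

    (a, b) are either supplied directly or solved so that the top and
    bottom score halves have the target expected prevalences.
    """
    rng = stage_rng(params.seed, "osahs")
    z = _standardize(truth.true_score.to_numpy())
    if params.osahs_intercept is not None or params.osahs_slope is not None:
        a = params.osahs_intercept or 0.0
        b = params.osahs_slope or 0.0
    else:
        p_hi, p_lo = params.osahs_p_high, params.osahs_p_low
        for p in (p_hi, p_lo):
            if not 0 < p < 1:
                raise ValueError("target prevalences must lie strictly in (0, 1)")
        order = np.argsort(z, kind="stable")
        half = len(z) // 2
        z_lo, z_hi = z[order[:half]], z[order[half:]]

        def eqs(ab):
            a_, b_ = ab
            return [expit(a_ + b_ * z_hi).mean() - p_hi,
                    expit(a_ + b_ * z_lo).mean() - p_lo]

        sol = root(eqs, x0=[logit((p_hi + p_lo) / 2.0), 1.0])
        if not sol.success:
            raise RuntimeError("could not solve OSAHS logistic calibration")
        a, b = sol.x
    labels = rng.binomial(1, expit(a + b * z))
    truth.osahs_logit_intercept = float(a)
    truth.osahs_logit_slope = float(b)
    return pd.Series(labels, index=truth.true_score.index, name="osahs")


NONSYNONYMOUS_CLASSES = [
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "Splice_Site",
]
SYNONYMOUS_CLASS = "Silent"
_NONSYN_PROBS = [0.70, 0.10, 0.08, 0.05, 0.07]


def simulate_mutations(truth: CohortTruth, params: SimulationParams,
                       gene_panel: list[str] | None = None) -> pd.DataFrame:
    """MAF-like mutation records with a planted TMB-score link.

    Per-sample nonsynonymous counts follow a negative binomial whose log
    mean is linear in the standardized score; mutated genes are drawn
    from a recurrently-mutated LUAD panel with higher weight for the
    most common drivers; a synonymous fraction is added so that
    nonsynonymous filtering can be exercised downstream.
    """
    if gene_panel is None:
        # named recurrent drivers plus a passenger background, so that
        # per-gene mutated fractions are not saturated
        panel = LUAD_MUTATION_PANEL + [f"GENE{i:04d}" for i in range(1985)]
    else:
        panel = list(gene_panel)
    rng = stage_rng(params.seed, "mutations")
    z = _standardize(truth.true_score.to_numpy())
    mu = params.tmb_base_mean * np.exp(params.tmb_slope * z)
    r = params.tmb_dispersion
    counts = np.where(
        mu > 0, rng.negative_binomial(r, np.minimum(r / (r + mu), 1.0 - 1e-12)), 0
    )
    w = np.full(len(panel), 0.25)
    n_named = min(len(LUAD_MUTATION_PANEL), len(panel))
    w[:n_named] = 1.5
    w[: min(5, len(panel))] = [3.0, 2.5, 2.2, 2.0, 1.8][: min(5, len(panel))]
    w /= w.sum()
    rows = []
    for sample, c in zip(truth.true_score.index, counts):
        c = int(c)
        syn = rng.poisson(params.synonymous_fraction * c)
        genes = rng.choice(panel, size=c + syn, p=w)
        classes = list(rng.choice(NONSYNONYMOUS_CLASSES, size=c, p=_NONSYN_PROBS))
        classes += [SYNONYMOUS_CLASS] * syn
        for g, cls in zip(genes, classes):
            rows.append((sample, g, cls))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_classification"])


def simulate_cohort(params: SimulationParams):
    """Run every generator and return (expression, clinical, osahs, mutations, truth)."""
    expr, truth = simulate_expression(params)
    clinical = simulate_survival(truth, params)
    osahs = simulate_osahs(truth, params)
    clinical.data["osahs"] = osahs
    mutations = simulate_mutations(truth, params)
    return expr, clinical, mutations, truth
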