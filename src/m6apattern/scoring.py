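"""The m6A score: Cox-filtered PCA signature and bootstrap formula choice.

Candidate signature genes are screened with univariate Cox regression;
the retained genes are standardised and summarised by their first two
principal components.  Two score formulas are implemented:

* formula A: score_i = sum_{k=1,2} sum_j PC_{k,ij}, where
  PC_{k,ij} = z_ij * w_jk is the contribution of gene j to component k
  in sample i — i.e. the sum of the PC1 and PC2 projections;
* formula B: sum over genes with positive Cox coefficient of PC1
  contributions minus the sum over genes with negative coefficient.

The formula used downstream is chosen by bootstrap validation: repeated
stratified 70/30 train-test splits, refitting the signature on the
training part and comparing mean test-set Harrell C-indices.

PCA signs are arbitrary; each loading vector is oriented so that the
risk direction implied by the univariate Cox coefficients
(sum_j beta_j * w_jk) is positive, falling back to making the largest
absolute loading positive when no coefficients are available.  The
orientation is part of the model and applied consistently wherever the
loadings are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix
from . import survival as surv

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    genes: list[str]
    cox_coef: pd.Series              # univariate Cox beta per retained gene
    cox_p: pd.Series
    mean: pd.Series                  # standardisation constants
    sd: pd.Series
    w1: pd.Series                    # PC1 loadings (unit norm)
    w2: pd.Series                    # PC2 loadings (unit norm, orthogonal)
    explained_variance_ratio: tuple[float, float]
    formula: str = "A"

    @property
    def genes_positive(self) -> list[str]:
        return self.cox_coef.index[self.cox_coef > 0].tolist()

    @property
    def genes_negative(self) -> list[str]:
        return self.cox_coef.index[self.cox_coef < 0].tolist()


@dataclass
class ScoreTable:
    scores: pd.Series                # m6A score per sample
    group: pd.Series | None = None   # {high, low}
    cutpoint: float | None = None


def cox_filter(genes, m: ExpressionMatrix, clinical: ClinicalTable,
               p_threshold: float = 0.05):
    """Univariate Cox screen: keep genes with Wald p < threshold.

    Returns (kept gene list, beta Series, p Series) over the kept genes.
    Zero-variance genes are skipped with a warning.
    """
    genes = [g for g in genes if g in m.gene_ids]
    if not genes:
        raise ValueError("no candidate genes present in the expression matrix")
    clin = clinical.aligned_to(m.sample_ids)
    if clin.event.sum() < 1:
        raise ValueError("no events in the clinical data")
    X = m.values.loc[genes].to_numpy().T  # samples x genes
    sds = X.std(axis=0)
    usable = sds > 0
    skipped = [g for g, u in zip(genes, usable) if not u]
    if skipped:
        logger.warning("skipping %d zero-variance gene(s): %s", len(skipped), skipped[:5])
    genes = [g for g, u in zip(genes, usable) if u]
    if not genes:
        raise ValueError("all candidate genes have zero variance")
    beta, se, p = surv.cox_univariate_batch(clin.time, clin.event, X[:, usable])
    beta_s = pd.Series(beta, index=genes)
    p_s = pd.Series(p, index=genes)
    kept = p_s.index[p_s < p_threshold].tolist()
    if not kept:
        raise ValueError(
            f"no gene passes the univariate Cox screen at p < {p_threshold}; "
            "consider relaxing the threshold"
        )
    return kept, beta_s.loc[kept], p_s.loc[kept]


def fit_pca_signature(m: ExpressionMatrix, betas: pd.Series | None = None,
                      cox_p: pd.Series | None = None) -> SignatureModel:
    """PCA of the standardised signature genes; first two loading vectors.

    Genes are standardised to mean 0, sd 1 across samples (the constants
    are stored so new samples can be scored).  Requires >= 2 genes and
    >= 3 samples; effectively rank-1 data has no defined second
    component and raises.
    """
    genes = list(m.gene_ids)
    if len(genes) < 2:
        raise ValueError("PCA signature needs at least 2 genes")
    if m.n_samples < 3:
        raise ValueError("PCA signature needs at least 3 samples")
    X = m.values.to_numpy().T  # samples x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"zero-variance gene(s) in signature: {bad[:5]}")
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if len(S) < 2 or S[1] <= 1e-9 * S[0]:
        raise ValueError("signature matrix is effectively rank 1; PC2 is undefined")
    w1, w2 = Vt[0].copy(), Vt[1].copy()
    # orientation: risk direction positive if Cox betas known, else
    # largest-|loading| positive
    for w in (w1, w2):
        if betas is not None:
            proj = float(betas.reindex(genes).to_numpy() @ w)
        else:
            proj = 0.0
        if proj == 0.0:
            proj = w[int(np.argmax(np.abs(w)))]
        if proj < 0:
            w *= -1.0
    total_var = float((S ** 2).sum())
    evr = (float(S[0] ** 2 / total_var), float(S[1] ** 2 / total_var))
    if betas is None:
        betas = pd.Series(0.0, index=genes)
    if cox_p is None:
        cox_p = pd.Series(np.nan, index=genes)
    return SignatureModel(
        genes=genes,
        cox_coef=betas.reindex(genes),
        cox_p=cox_p.reindex(genes),
        mean=pd.Series(mu, index=genes),
        sd=pd.Series(sd, index=genes),
        w1=pd.Series(w1, index=genes),
        w2=pd.Series(w2, index=genes),
        explained_variance_ratio=evr,
    )


def _standardized(model: SignatureModel, m: ExpressionMatrix) -> pd.DataFrame:
    missing = [g for g in model.genes if g not in m.gene_ids]
    if missing:
        raise KeyError(f"sample matrix is missing signature gene(s): {missing[:5]}")
    X = m.values.loc[model.genes]
    return X.sub(model.mean, axis=0).div(model.sd, axis=0).T  # samples x genes


def score_formula_A(model: SignatureModel, m: ExpressionMatrix) -> pd.Series:
    """Sum of PC1 and PC2 gene contributions: score_i = z_i.w1 + z_i.w2."""
    Z = _standardized(model, m)
    s = Z.to_numpy() @ (model.w1.to_numpy() + model.w2.to_numpy())
    return pd.Series(s, index=m.sample_ids, name="m6a_score")


def score_formula_B(model: SignatureModel, m: ExpressionMatrix) -> pd.Series:
    """Sign-separated PC1 contributions: sum over G+ minus sum over G-."""
    gp, gn = model.genes_positive, model.genes_negative
    if not gp and not gn:
        raise ValueError("formula B needs at least one gene with a signed Cox coefficient")
    Z = _standardized(model, m)
    sign = pd.Series(0.0, index=model.genes)
    sign.loc[gp] = 1.0
    sign.loc[gn] = -1.0
    s = Z.to_numpy() @ (sign.to_numpy() * model.w1.to_numpy())
    return pd.Series(s, index=m.sample_ids, name="m6a_score")


def score_samples(model: SignatureModel, m: ExpressionMatrix) -> pd.Series:
    return (score_formula_A if model.formula == "A" else score_formula_B)(model, m)


def fit_signature(genes, m: ExpressionMatrix, clinical: ClinicalTable,
                  p_threshold: float = 0.05, cox_screen: bool = True) -> SignatureModel:
    """Cox screen (optional) followed by the PCA signature fit."""
    genes = [g for g in genes if g in m.gene_ids]
    if cox_screen:
        kept, betas, pvals = cox_filter(genes, m, clinical, p_threshold)
    else:
        clin = clinical.aligned_to(m.sample_ids)
        X = m.values.loc[genes].to_numpy().T
        b, se, p = surv.cox_univariate_batch(clin.time, clin.event, X)
        kept, betas, pvals = genes, pd.Series(b, index=genes), pd.Series(p, index=genes)
    return fit_pca_signature(m.subset_genes(kept), betas, pvals)


@dataclass
class BootstrapSelection:
    formula: str
    mean_cindex: dict[str, float]
    cindex_traces: dict[str, np.ndarray]
    n_completed: int
    n_skipped: int


def bootstrap_select_formula(
    genes,
    m: ExpressionMatrix,
    clinical: ClinicalTable,
    n_iter: int = 1000,
    split: float = 0.7,
    seed: int = 0,
    p_threshold: float = 0.05,
    min_events: int = 10,
) -> BootstrapSelection:
    """Choose the score formula by repeated train-test validation.

    Each iteration draws a stratified (on the event indicator) 70/30
    split, refits the Cox screen and PCA on the training part, scores
    the test part with both formulas and records the Harrell C-index.
    Iterations whose training part has fewer than ``min_events`` events,
    or where no gene survives the screen, are skipped and logged.  The
    cumulative C-index of a formula is its mean over completed
    iterations; the larger one wins.
    """
    rng = np.random.default_rng(seed)
    clin = clinical.aligned_to(m.sample_ids)
    times, events = clin.time, clin.event
    idx_event = np.nonzero(events == 1)[0]
    idx_cens = np.nonzero(events == 0)[0]
    traces = {"A": [], "B": []}
    skipped = 0
    for _ in range(n_iter):
        tr = np.concatenate([
            rng.permutation(idx_event)[: int(round(split * len(idx_event)))],
            rng.permutation(idx_cens)[: int(round(split * len(idx_cens)))],
        ])
        te = np.setdiff1d(np.arange(len(times)), tr)
        if events[tr].sum() < min_events or events[te].sum() < 1:
            skipped += 1
            continue
        samples_tr = m.sample_ids[tr]
        samples_te = m.sample_ids[te]
        try:
            model = fit_signature(genes, m.subset_samples(samples_tr),
                                  ClinicalTable(clin.data.iloc[tr]), p_threshold)
            m_te = m.subset_samples(samples_te)
            ca = surv.harrell_cindex(score_formula_A(model, m_te), times[te], events[te])
            cb = surv.harrell_cindex(score_formula_B(model, m_te), times[te], events[te])
        except ValueError as err:
            logger.debug("bootstrap iteration skipped: %s", err)
            skipped += 1
            continue
        traces["A"].append(ca)
        traces["B"].append(cb)
    n_done = len(traces["A"])
    if n_done < n_iter / 2:
        raise ValueError(f"too many skipped bootstrap iterations ({skipped}/{n_iter})")
    mean_c = {f: float(np.mean(traces[f])) for f in ("A", "B")}
    chosen = "A" if mean_c["A"] >= mean_c["B"] else "B"
    return BootstrapSelection(chosen, mean_c,
                              {f: np.asarray(v) for f, v in traces.items()},
                              n_done, skipped)


def regulator_network(m: ExpressionMatrix, clinical: ClinicalTable,
                      regulators=None, rho_threshold: float = 0.20,
                      p_threshold: float = 0.05):
    """Correlation network of the regulators plus per-gene prognostic calls.

    Edges are pairwise Spearman correlations kept at |rho| >= 0.20 and
    p < 0.05; each regulator is classified as a risk or favorable factor
    by a median-split log-rank test of its expression.
    Returns (edge DataFrame, per-gene annotation DataFrame).
    """
    genes = [g for g in (regulators if regulators is not None else m.gene_ids)
             if g in m.gene_ids]
    if len(genes) < 2:
        raise ValueError("regulator network needs at least 2 genes")
    clin = clinical.aligned_to(m.sample_ids)
    X = m.values.loc[genes]
    edges = []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            rho, p = surv.spearman(X.loc[gi], X.loc[gj])
            if abs(rho) >= rho_threshold and p < p_threshold:
                edges.append({"gene_a": gi, "gene_b": gj, "rho": rho, "p": p})
    annot = []
    for g in genes:
        x = X.loc[g].to_numpy()
        med = np.median(x)
        high = x > med
        if high.sum() == 0 or (~high).sum() == 0:
            annot.append({"gene": g, "role": "uninformative", "logrank_p": np.nan})
            continue
        res = surv.logrank_test(clin.time, clin.event, high.astype(int))
        # z > 0 means more observed than expected events in the low group
        worse_when_high = res.z is not None and res.z < 0
        annot.append({
            "gene": g,
            "role": "risk" if worse_when_high else "favorable",
            "logrank_p": res.p_value,
            "significant": res.p_value < p_threshold,
        })
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "rho", "p"])
    return edge_df, pd.DataFrame(annot).set_index("gene")
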