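"""Single-sample gene-set enrichment and over-representation analysis.

The ssGSEA statistic ranks the genes of one sample by expression and
accumulates the difference between a rank-weighted ECDF of the set
members and the uniform ECDF of non-members over the full ranked list
(the running-sum integral form).  Scores are rank-based, hence
invariant under strictly monotone transforms of the expression column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetCollection
from .de import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentParams:
    """ssGSEA tunables: rank-weight exponent alpha, normalisation, min set size."""

    alpha: float = 0.25
    normalization: str = "none"   # "none" or "range"
    min_size: int = 2

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.normalization not in ("none", "range"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class EnrichmentScores:
    scores: pd.DataFrame          # sets x samples
    params: EnrichmentParams


def _tie_averaged_increments(sorted_vals: np.ndarray, increments: np.ndarray) -> np.ndarray:
    """Spread each tied block's total increment evenly over its positions.

    Ensures the running sums depend on expression values only through
    their ranks: within a block of tied values the ECDF rises linearly,
    so gene order inside a tie cannot influence the score.
    """
    block_start = np.empty(len(sorted_vals), bool)
    block_start[0] = True
    block_start[1:] = sorted_vals[1:] != sorted_vals[:-1]
    block_id = np.cumsum(block_start) - 1
    n_blocks = block_id[-1] + 1
    block_tot = np.bincount(block_id, weights=increments, minlength=n_blocks)
    block_len = np.bincount(block_id, minlength=n_blocks)
    return (block_tot / block_len)[block_id]


def _running_sum_score(vals: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """The ssGSEA running-sum statistic for one sample and one set mask."""
    n = len(vals)
    order = np.lexsort((np.arange(n), -vals))
    ranks = stats.rankdata(vals, method="average")
    n_out = n - int(in_set.sum())
    sorted_vals = vals[order]
    in_sorted = in_set[order]
    w_inc = _tie_averaged_increments(
        sorted_vals, np.where(in_sorted, ranks[order] ** alpha, 0.0))
    p_in = np.cumsum(w_inc)
    if p_in[-1] > 0:
        p_in = p_in / p_in[-1]
    if n_out > 0:
        out_inc = _tie_averaged_increments(sorted_vals, (~in_sorted).astype(float))
        p_out = np.cumsum(out_inc) / n_out
    else:
        p_out = np.zeros(n)
    return float(np.sum(p_in - p_out))


def ssgsea_sample(expr: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    Walks the genes from highest to lowest expression; at each position
    the weighted in-set ECDF (member weights rank^alpha, normalised to
    sum 1) minus the uniform out-of-set ECDF is added to the score.
    Ties take average ranks and their ECDF increments are spread evenly
    across the tied block, so the score is a pure function of the ranks.
    If the set covers every gene the out-of-set ECDF is defined as 0
    and the (degenerate) score is flagged via a warning.
    """
    members = set(gene_set) & set(expr.index)
    if len(members) < 2:
        raise ValueError("gene set has fewer than 2 members in the expression vector")
    in_set = np.array([g in members for g in expr.index])
    if in_set.all():
        logger.warning("gene set covers the whole gene universe; out-of-set ECDF set to 0")
    return _running_sum_score(expr.to_numpy(float), in_set, alpha)


def score_matrix(m: ExpressionMatrix, sets: GeneSetCollection,
                 params: EnrichmentParams | None = None) -> EnrichmentScores:
    """ssGSEA scores for every set and sample; optional per-set range scaling."""
    params = params or EnrichmentParams()
    usable = sets.restricted_to(m.gene_ids, params.min_size)
    if len(usable) == 0:
        raise ValueError("no gene set has enough members in the expression matrix")
    n = m.n_genes
    genes = list(m.gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    vals = m.values.to_numpy(float)
    out = np.empty((len(usable), m.n_samples))
    set_masks = []
    for name, members in usable:
        mask = np.zeros(n, bool)
        mask[[gene_pos[g] for g in members]] = True
        set_masks.append(mask)
    for j in range(m.n_samples):
        col = vals[:, j]
        for si, mask in enumerate(set_masks):
            out[si, j] = _running_sum_score(col, mask, params.alpha)
    scores = pd.DataFrame(out, index=list(usable.sets), columns=m.sample_ids)
    if params.normalization == "range":
        rng = scores.max(axis=1) - scores.min(axis=1)
        rng = rng.replace(0.0, 1.0)
        scores = scores.sub(scores.min(axis=1), axis=0).div(rng, axis=0)
    return EnrichmentScores(scores, params)


def pathway_activity(m: ExpressionMatrix, sets: GeneSetCollection,
                     method: str = "ssgsea",
                     params: EnrichmentParams | None = None) -> EnrichmentScores:
    """Per-sample pathway activity by ssGSEA or a combined z-score.

    The ``zscore`` method standardises each gene across samples and
    scores a set as mean(z of members) * sqrt(set size) — a single-gene
    set reduces to that gene's z-score.
    """
    params = params or EnrichmentParams(min_size=1 if method == "zscore" else 2)
    if method == "ssgsea":
        return score_matrix(m, sets, params)
    if method != "zscore":
        raise ValueError(f"unknown pathway-activity method {method!r}")
    usable = sets.restricted_to(m.gene_ids, params.min_size)
    if len(usable) == 0:
        raise ValueError("no usable gene set")
    vals = m.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = vals.sub(mu, axis=0).div(sd, axis=0)
    rows = {}
    for name, members in usable:
        rows[name] = z.loc[members].mean(axis=0) * np.sqrt(len(members))
    scores = pd.DataFrame(rows).T
    scores.columns = m.sample_ids
    return EnrichmentScores(scores, params)


def ora_hypergeometric(hits, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in `hits`.

    ``hits`` must be a subset of ``universe``; each set is intersected
    with the universe first, disjoint sets are skipped with a warning.
    Returns a DataFrame with overlap counts, raw and BH-adjusted p, and
    a significance flag at adjusted p < 0.05.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    hits = list(dict.fromkeys(hits))
    if not universe or not hits:
        raise ValueError("hits and universe must be non-empty")
    stray = [h for h in hits if h not in uset]
    if stray:
        raise ValueError(f"hits not contained in universe: {stray[:5]}")
    N = len(universe)
    n_hits = len(hits)
    hitset = set(hits)
    rows = []
    for name, members in sets:
        in_universe = [g for g in members if g in uset]
        if not in_universe:
            logger.warning("gene set %r is disjoint from the universe; skipped", name)
            continue
        K = len(in_universe)
        k = len(hitset.intersection(in_universe))
        p = float(stats.hypergeom.sf(k - 1, N, K, n_hits))
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows).set_index("set")
    df["adj_p"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["adj_p"] < 0.05
    return df
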