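"""Moderated two-group differential expression with BH FDR control.

Per gene, the two-group mean difference on the log2 scale (log2FC) is
tested with an empirical-Bayes moderated t-statistic: the gene-wise
residual variance s_g^2 is shrunk towards a prior s0^2 estimated from
the whole collection of genes,

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and t = log2FC / (s_tilde * sqrt(1/n1 + 1/n2)) is referred to a
t-distribution on d0 + d_g degrees of freedom.  The prior (d0, s0^2) is
estimated by method of moments from the scaled-F distribution of the
log sample variances.

Two selection regimes are provided: ``phenotype`` (adjusted p < 0.01
only) and ``group`` (|log2FC| > 1 and adjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

PHENOTYPE_ADJP = 0.01
GROUP_ADJP = 0.05
GROUP_LFC = 1.0


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: degrees of freedom d0 and variance s0^2."""

    d0: float
    s0_sq: float


@dataclass
class DEResult:
    table: pd.DataFrame          # per gene: log2fc, s2, df, t, p, adj_p
    moderation: ModerationParams
    thresholds: dict | None = None


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Method-of-moments fit of the scaled-F prior for gene variances.

    Works on z = log(s^2): E[z] and Var[z] have closed forms in terms of
    digamma/trigamma functions of d_g/2 and d0/2, which are matched to the
    empirical mean and variance.  A non-positive excess variance means no
    evidence of variance heterogeneity beyond sampling: d0 = +inf and
    s0^2 is the (log-scale) pooled variance.
    """
    ok = (s2 > 0) & (df > 0)
    s2 = s2[ok]
    df = df[ok]
    if s2.size < 2:
        return ModerationParams(np.inf, float(np.median(s2)) if s2.size else 1.0)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (n - 1) - np.mean(polygamma(1, df / 2.0))
    if evar <= 0:
        return ModerationParams(np.inf, float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(float(d0), s0_sq)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def moderated_de(m: ExpressionMatrix, groups, d0_override: float | None = None) -> DEResult:
    """Two-group moderated differential expression on log-scale data.

    ``groups`` is a per-sample two-level labelling (aligned to the
    matrix columns); log2FC is mean(group2) - mean(group1) with groups
    in sorted label order.  ``d0_override`` forces the prior degrees of
    freedom (0 recovers the ordinary equal-variance t-test).
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"moderated_de needs exactly 2 groups, got {len(labels)}")
    mask2 = groups == labels[1]
    n1 = int((~mask2).sum())
    n2 = int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    X = m.values.to_numpy()
    x1 = X[:, ~mask2]
    x2 = X[:, mask2]
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    lfc = mean2 - mean1
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    df = np.full(X.shape[0], n1 + n2 - 2, float)
    s2 = ss / df

    mod = estimate_moderation(s2, df)
    if d0_override is not None:
        mod = ModerationParams(float(d0_override), mod.s0_sq)
    d0 = mod.d0
    if np.isinf(d0):
        s2_post = np.full_like(s2, mod.s0_sq)
        df_total = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * mod.s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    sed = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))

    # a gene constant within both groups at the same level carries no
    # information: flagged, p pinned to 1
    degenerate = (s2 <= 0) & (lfc == 0)
    degenerate |= s2_post <= 0
    t = np.zeros_like(lfc)
    p = np.ones_like(lfc)
    okv = ~degenerate
    t[okv] = lfc[okv] / sed[okv]
    finite_df = np.isfinite(df_total)
    use_t = okv & finite_df
    p[use_t] = 2.0 * stats.t.sf(np.abs(t[use_t]), df_total[use_t])
    use_z = okv & ~finite_df
    p[use_z] = 2.0 * stats.norm.sf(np.abs(t[use_z]))
    if degenerate.any():
        logger.warning("%d gene(s) with zero variance in both groups: p set to 1", degenerate.sum())

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "s2": s2,
            "df": df,
            "t": t,
            "p": p,
            "adj_p": bh_fdr(p),
            "zero_variance": degenerate,
        },
        index=m.gene_ids,
    )
    return DEResult(table, mod)


def select_degs(de: DEResult, mode: str) -> list[str]:
    """Apply one of the two threshold regimes to a DE result."""
    t = de.table
    if mode == "phenotype":
        mask = t["adj_p"] < PHENOTYPE_ADJP
    elif mode == "group":
        mask = (t["log2fc"].abs() > GROUP_LFC) & (t["adj_p"] < GROUP_ADJP)
    else:
        raise ValueError(f"unknown DEG selection mode {mode!r}; use 'phenotype' or 'group'")
    return t.index[mask].tolist()


def multiclass_degs(m: ExpressionMatrix, labels, mode: str = "phenotype",
                    combine: str = "intersection"):
    """One-vs-rest DEGs across >= 3 classes.

    Each class is contrasted against all remaining samples with
    :func:`moderated_de`; the per-class DEG sets are combined by
    ``intersection`` (genes differential in every contrast, the default)
    or ``union``.  Returns (gene list, per-class DEResult dict).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 3:
        raise ValueError("multiclass_degs needs >= 3 classes; use moderated_de for 2 groups")
    per_class: dict = {}
    sets: list[set[str]] = []
    for c in classes:
        onevrest = np.where(labels == c, "this", "rest")
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        res = moderated_de(m, onevrest)
        per_class[c] = res
        sets.append(set(select_degs(res, mode)))
    if combine == "intersection":
        genes = set.intersection(*sets)
    elif combine == "union":
        genes = set.union(*sets)
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return [g for g in m.gene_ids if g in genes], per_class
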