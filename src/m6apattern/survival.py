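"""Survival and association statistics implemented from first principles.

Every downstream claim of the pipeline (pattern survival differences,
score stratification, TMB strata, OSAHS contrasts) runs through this
module: the Kaplan-Meier product-limit estimator, the k-group log-rank
test, Cox proportional-hazards regression (Newton-Raphson on the partial
likelihood with Efron tie correction), Harrell's concordance index,
maximally selected rank-statistic cutpoints, rank-based AUC, Spearman
correlation, and the standard group-comparison tests.

Tie conventions: at tied times events precede censorings (censored-at-t
subjects remain at risk at t); tied risk scores contribute 0.5 to the
concordance count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate on the grid of distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # subjects at risk at each event time
    events: np.ndarray      # deaths at each event time

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; nan if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else float("nan")


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator. Censored-at-t subjects count as at risk at t."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return SurvivalCurve(np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int))
    at_risk = np.array([(times >= t).sum() for t in event_times])
    deaths = np.array([((times == t) & (events == 1)).sum() for t in event_times])
    surv = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(event_times, surv, at_risk, deaths)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    z: float | None = None   # standardized (O-E)/sqrt(V), two groups only


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test: O-E over event times with hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels, gidx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        if n <= 1:
            O += np.bincount(gidx[(times == t) & (events == 1)], minlength=k)
            E += d * np.bincount(gidx[at_risk], minlength=k) / max(n, 1)
            continue
        n_j = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_j = np.bincount(gidx[(times == t) & (events == 1)], minlength=k).astype(float)
        O += d_j
        E += d * n_j / n
        frac = n_j / n
        mult = d * (n - d) / (n - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    z = None
    if k == 2:
        v11 = V[0, 0]
        z = float((O[0] - E[0]) / np.sqrt(v11)) if v11 > 0 else 0.0
        if v11 <= 0:
            stat, p = 0.0, 1.0
    return LogrankResult(stat, df, p, O, E, z)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron / Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    separation_flag: bool = False

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


def _cox_loglik_derivs(beta, X, times, events, ties):
    """Log partial likelihood, score vector and information matrix.

    Samples must be sorted by ascending time.  Efron's correction handles
    tied event times; ``ties='breslow'`` selects the cruder variant.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; constant cancels in ratios
    theta = np.exp(eta)
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    # iterate distinct times from latest to earliest, maintaining suffix
    # risk-set sums S0 = sum theta, S1 = sum theta*x, S2 = sum theta*xx'
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    uniq_times = np.unique(times)
    for t in uniq_times[::-1]:
        while i >= 0 and times[i] >= t:
            if times[i] == t:
                S0 += theta[i]
                S1 += theta[i] * X[i]
                S2 += theta[i] * np.outer(X[i], X[i])
                i -= 1
            else:  # pragma: no cover - times sorted, loop structure
                break
        mask = (times == t) & (events == 1)
        d = int(mask.sum())
        if d == 0:
            continue
        xd = X[mask]
        td = theta[mask]
        s0_tie = td.sum()
        s1_tie = td @ xd
        s2_tie = np.einsum("i,ij,ik->jk", td, xd, xd)
        loglik += float(eta[mask].sum())
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            denom = S0 - frac * s0_tie
            num1 = S1 - frac * s1_tie
            num2 = S2 - frac * s2_tie
            loglik -= np.log(denom)
            mean = num1 / denom
            score -= mean
            info += num2 / denom - np.outer(mean, mean)
        score += xd.sum(axis=0)
    return loglik, score, info


def cox_fit(times, events, covariates, ties: str = "efron",
            max_iter: int = 50, tol: float = 1e-8) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    covariates
        (n, p) array or 1-D array for a single covariate.
    ties
        ``"efron"`` (default) or ``"breslow"``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if events.sum() < 1:
        raise ValueError("Cox model needs at least one event")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if (X.std(axis=0) == 0).any():
        j = int(np.nonzero(X.std(axis=0) == 0)[0][0])
        raise ValueError(f"covariate {j} has zero variance")
    # center columns for numerical stability (beta unaffected)
    Xc = X - X.mean(axis=0)
    order = np.argsort(times, kind="stable")
    Xs, ts, es = Xc[order], times[order], events[order]

    beta = np.zeros(p)
    loglik, score, info = _cox_loglik_derivs(beta, Xs, ts, es, ties)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular information matrix in Cox fit")
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik_derivs(new_beta, Xs, ts, es, ties)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik_derivs(new_beta, Xs, ts, es, ties)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 20:
            separation = True
            beta = np.clip(beta, -20, 20)
            logger.warning("possible monotone partial likelihood; coefficients capped at |20|")
            break
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxResult(beta, se, z, pvals, float(loglik), it, converged, separation)


def cox_univariate_batch(times, events, X, ties: str = "efron",
                         max_iter: int = 25, tol: float = 1e-8):
    """Univariate Cox fits for many covariates at once.

    ``X`` is (n, G): one fit per column, vectorised across columns.
    Returns (beta, se, p) arrays of length G.  Intended for per-gene
    prognostic screens where thousands of single-covariate models are
    fitted; equivalent to calling :func:`cox_fit` per column.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, G = X.shape
    order = np.argsort(times, kind="stable")
    Xs = X[order] - X.mean(axis=0)
    ts, es = times[order], events[order]
    # tie-group structure, computed once: groups of equal times, their
    # first row (where the suffix risk-set sum is evaluated), event counts
    uniq, first_idx, inv = np.unique(ts, return_index=True, return_inverse=True)
    ev_mask = es == 1
    d_group = np.bincount(inv[ev_mask], minlength=len(uniq))
    has_events = np.nonzero(d_group > 0)[0]
    vector_groups = has_events[(d_group[has_events] == 1) | (ties == "breslow")]
    tied_groups = [g for g in has_events if g not in set(vector_groups)]
    tied_members = {g: np.nonzero(ev_mask & (inv == g))[0] for g in tied_groups}
    vg_first = first_idx[vector_groups]
    vg_d = d_group[vector_groups].astype(float)[:, None]

    beta = np.zeros(G)
    active = np.ones(G, bool)
    x_event_sum = Xs[ev_mask].sum(axis=0)

    def derivs(b):
        eta = Xs * b  # (n, G)
        eta = eta - eta.max(axis=0)
        theta = np.exp(eta)
        tx = theta * Xs
        tx2 = tx * Xs
        S0 = np.cumsum(theta[::-1], axis=0)[::-1]
        S1 = np.cumsum(tx[::-1], axis=0)[::-1]
        S2 = np.cumsum(tx2[::-1], axis=0)[::-1]
        grad = x_event_sum.copy()
        hess = np.zeros(G)
        if len(vg_first):
            s0 = np.maximum(S0[vg_first], 1e-300)
            mean = S1[vg_first] / s0
            grad -= (vg_d * mean).sum(axis=0)
            hess += (vg_d * (S2[vg_first] / s0 - mean ** 2)).sum(axis=0)
        for g in tied_groups:  # Efron correction, tied event times only
            ev_members = tied_members[g]
            d = len(ev_members)
            first = first_idx[g]
            s0, s1, s2 = S0[first], S1[first], S2[first]
            t0 = theta[ev_members].sum(axis=0)
            t1 = tx[ev_members].sum(axis=0)
            t2 = tx2[ev_members].sum(axis=0)
            for ell in range(d):
                f = ell / d
                denom = np.maximum(s0 - f * t0, 1e-300)
                mean = (s1 - f * t1) / denom
                grad -= mean
                hess += (s2 - f * t2) / denom - mean ** 2
        return grad, hess

    for _ in range(max_iter):
        if not active.any():
            break
        grad, hess = derivs(beta)
        step = np.where(hess > 0, grad / np.maximum(hess, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.where(active, beta + step, beta)
        active = active & (np.abs(grad) >= tol)
        beta = np.clip(beta, -20, 20)
    grad, hess = derivs(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(hess > 0, 1.0 / np.sqrt(hess), np.nan)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, p


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def harrell_cindex(score, times, events) -> float:
    """Harrell's C: usable pairs (t_i < t_j, event_i = 1); score ties count 0.5."""
    score = np.asarray(score, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ti = times[:, None]
    tj = times[None, :]
    usable = (ti < tj) & (events[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    si = score[:, None]
    sj = score[None, :]
    concordant = (si > sj) & usable
    tied = (si == sj) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


# ---------------------------------------------------------------------------
# Maximally selected rank cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    cutpoint: float
    best_statistic: float
    candidates: np.ndarray
    statistics: np.ndarray
    minprop: float

    def groups(self, score) -> np.ndarray:
        """'high'/'low' labels for a score vector at the selected cutpoint."""
        return np.where(np.asarray(score, float) > self.cutpoint, "high", "low")


def max_rank_cutpoint(score, times, events, minprop: float = 0.1) -> CutpointResult:
    """Cutpoint maximising the standardized two-group log-rank statistic.

    Candidates are midpoints between consecutive distinct score values
    that leave at least ``minprop`` of the cohort on each side; ties in
    |statistic| resolve to the lower cutpoint.
    """
    score = np.asarray(score, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(score)
    distinct = np.unique(score)
    if distinct.size < 2:
        raise ValueError("all scores identical; no cutpoint exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo_counts = np.array([(score <= c).sum() for c in mids])
    keep = (lo_counts >= minprop * n) & ((n - lo_counts) >= minprop * n)
    candidates = mids[keep]
    if candidates.size == 0:
        raise ValueError("no candidate cutpoint satisfies the minprop constraint")
    zs = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        grp = score > c
        res = logrank_test(times, events, grp.astype(int))
        zs[i] = abs(res.z) if res.z is not None else 0.0
    best = int(np.argmax(zs))  # argmax returns first maximum -> lower cutpoint
    return CutpointResult(float(candidates[best]), float(zs[best]), candidates, zs, minprop)


# ---------------------------------------------------------------------------
# AUC, Spearman, group comparisons
# ---------------------------------------------------------------------------

def auc_mannwhitney(score, label):
    """AUC via the Mann-Whitney statistic with a Hanley-McNeil normal CI.

    Returns (auc, (lo, hi)).
    """
    score = np.asarray(score, float)
    label = np.asarray(label, int)
    n1 = int((label == 1).sum())
    n0 = int((label == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)
    r1 = ranks[label == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2) + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    zq = stats.norm.ppf(0.975)
    return float(auc), (float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se)))


def spearman(x, y):
    """Spearman rho: Pearson on average ranks; p via t on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float((rx * ry).sum() / denom)
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) whose point probability does not exceed the observed one.
    Returns (odds_ratio, p).
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("Fisher test needs a 2x2 table of non-negative counts")
    a, b, c, d = t.ravel()
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def log_pmf(x):
        return (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
                + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
                - (gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1)))

    lo = max(0, int(c1 - r2))
    hi = int(min(r1, c1))
    xs = np.arange(lo, hi + 1)
    logs = np.array([log_pmf(x) for x in xs])
    obs = log_pmf(a)
    p = float(np.exp(logs[logs <= obs + 1e-7]).sum())
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return float(odds), min(p, 1.0)


def group_compare(values, groups, test: str):
    """Standard two-or-more group comparisons.

    ``test`` is one of ``wilcoxon`` (rank-sum for two independent
    groups), ``kruskal``, ``anova``, ``chisq`` (contingency of two
    categorical vectors) or ``fisher`` (2x2 exact).  For ``chisq`` and
    ``fisher``, ``values`` and ``groups`` are categorical vectors, or
    ``values`` may be a precomputed contingency table with ``groups=None``.
    Returns (statistic, p).
    """
    if test in ("chisq", "fisher"):
        if groups is None:
            table = np.asarray(values, float)
        else:
            table = np.asarray(pd.crosstab(pd.Series(groups), pd.Series(values))).astype(float)
        if test == "fisher":
            odds, p = fisher_exact_2x2(table)
            return odds, p
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    samples = [values[groups == lab] for lab in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if test == "wilcoxon":
        if len(samples) != 2:
            raise ValueError("wilcoxon rank-sum needs exactly 2 groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = stats.kruskal(*samples)
            except ValueError:  # all values identical
                return 0.0, 1.0
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        res = stats.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
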