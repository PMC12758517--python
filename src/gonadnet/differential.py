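"""Differential expression (Wilcoxon rank-sum) and accessibility (LR) testing.

Both tests follow the marker-detection conventions of standard single-cell
toolkits: features are pre-filtered on detection fraction (``min_pct``) and
absolute log2 fold change (``logfc_threshold``) before testing, and p-values
are Bonferroni-adjusted with the *total* number of features in the matrix as
denominator (not the post-filter count).

log2 fold change is ``log2((mean1 + 1) / (mean2 + 1))`` on normalized values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

#: maximum number of group-assignment combinations for the exact Wilcoxon path
EXACT_COMBINATION_CAP = 200_000


@dataclass
class DifferentialResult:
    feature_id: str
    log2_fc: float
    pct_1: float
    pct_2: float
    p_value: float
    p_adjusted: float
    direction: str
    convergence_flag: str = "ok"


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(p_values, method: str = "bonferroni", m: int | None = None) -> np.ndarray:
    """Bonferroni (min(1, p*m), m may exceed len(p)) or Benjamini-Hochberg."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"denominator m={m} smaller than number of p-values {len(p)}")
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "BH":
        if len(p) == 0:
            return p
        # step-up over the m hypotheses; untested hypotheses treated as p=1,
        # which cannot alter the adjusted values of the tested ones
        adj = multipletests(p, method="fdr_bh")[1]
        return np.minimum(1.0, adj * (m / len(p))) if m != len(p) else adj
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses tie-aware exact enumeration over all C(n1+n2, n1) group assignments
    when that count is small enough, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    n1, n2 = len(x), len(y)
    if math.comb(n1 + n2, n1) <= EXACT_COMBINATION_CAP:
        return _exact_rank_sum_p(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating group assignments of the pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_deg(expr: np.ndarray, feature_ids: list[str],
                 group1: np.ndarray, group2: np.ndarray,
                 min_pct: float = 0.25, logfc_threshold: float = 0.25,
                 adjust_method: str = "bonferroni") -> list[DifferentialResult]:
    """Wilcoxon rank-sum DEG test between two cell groups.

    ``expr`` is a dense normalized features × cells array; ``group1``/``group2``
    are disjoint column-index arrays (each >= 2 cells).  Features are tested
    only if ``max(pct_1, pct_2) >= min_pct`` and ``|log2_fc| >= logfc_threshold``;
    adjustment denominator is the total feature count.
    """
    group1 = np.asarray(group1)
    group2 = np.asarray(group2)
    _check_groups(group1, group2)
    e1, e2 = expr[:, group1], expr[:, group2]
    pct1 = (e1 > 0).mean(axis=1)
    pct2 = (e2 > 0).mean(axis=1)
    lfc = np.log2((e1.mean(axis=1) + 1.0) / (e2.mean(axis=1) + 1.0))
    testable = np.flatnonzero((np.maximum(pct1, pct2) >= min_pct) &
                              (np.abs(lfc) >= logfc_threshold))
    pvals = np.array([wilcoxon_rank_sum(e1[i], e2[i]) for i in testable])
    padj = adjust_pvalues(pvals, method=adjust_method, m=len(feature_ids))
    return [
        DifferentialResult(
            feature_id=feature_ids[i],
            log2_fc=float(lfc[i]),
            pct_1=float(pct1[i]),
            pct_2=float(pct2[i]),
            p_value=float(p),
            p_adjusted=float(pa),
            direction="up_in_1" if lfc[i] > 0 else "up_in_2",
        )
        for i, p, pa in zip(testable, pvals, padj)
    ]


def _check_groups(group1: np.ndarray, group2: np.ndarray) -> None:
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >= 2 cells")
    if set(group1.tolist()) & set(group2.tolist()):
        raise ValueError("groups overlap")


# ---------------------------------------------------------------------------
# Logistic-regression likelihood-ratio test
# ---------------------------------------------------------------------------

def _logistic_loglik(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    eta = beta[0] + (beta[1] * x if len(beta) > 1 else 0.0)
    # log(1+e^eta) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 100,
                  tol: float = 1e-10) -> tuple[np.ndarray, float, str]:
    """Newton-Raphson fit of y ~ 1 + x; returns (beta, loglik, flag).

    The covariate is standardized internally (the LR statistic is invariant
    under affine transforms of x).
    """
    x = (x - x.mean()) / x.std()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    flag = "ok"
    ll_prev = _logistic_loglik(beta, x, y)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        if w.max() < 1e-12:
            flag = "separation"
            break
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            flag = "singular"
            break
        beta = beta + step
        ll = _logistic_loglik(beta, X[:, 1], y)
        if abs(beta[1]) > 30 or ll > -1e-8 * len(y):
            # diverging slope / likelihood at its supremum: separation
            ll_prev = max(ll, ll_prev)
            flag = "separation"
            break
        if abs(ll - ll_prev) < tol:
            ll_prev = ll
            break
        ll_prev = ll
    else:
        flag = "not_converged"
    return beta, ll_prev, flag


def lr_dap(acc: np.ndarray, feature_ids: list[str],
           group1: np.ndarray, group2: np.ndarray,
           min_pct: float = 0.05, logfc_threshold: float = 0.25,
           adjust_method: str = "bonferroni") -> list[DifferentialResult]:
    """Likelihood-ratio DAP test between two cell groups.

    Per peak, group membership is regressed on the peak's normalized
    accessibility (full model: intercept + accessibility; null: intercept
    only); the statistic 2(l_full - l_null) is referred to chi-square with
    1 df.  Under separation the full log-likelihood is capped at 0, bounding
    the statistic by the null deviance, and flagged.
    """
    group1 = np.asarray(group1)
    group2 = np.asarray(group2)
    _check_groups(group1, group2)
    a1, a2 = acc[:, group1], acc[:, group2]
    pct1 = (a1 > 0).mean(axis=1)
    pct2 = (a2 > 0).mean(axis=1)
    lfc = np.log2((a1.mean(axis=1) + 1.0) / (a2.mean(axis=1) + 1.0))
    testable = np.flatnonzero((np.maximum(pct1, pct2) >= min_pct) &
                              (np.abs(lfc) >= logfc_threshold))

    y = np.concatenate([np.ones(len(group1)), np.zeros(len(group2))])
    n = len(y)
    p_null = y.mean()
    ll_null = n * (p_null * np.log(p_null) + (1 - p_null) * np.log(1 - p_null))

    pvals, flags = [], []
    xmat = np.concatenate([a1, a2], axis=1)
    for i in testable:
        x = xmat[i]
        if np.ptp(x) == 0:
            pvals.append(1.0)
            flags.append("constant")
            continue
        _, ll_full, flag = _fit_logistic(x, y)
        if flag == "separation":
            ll_full = 0.0  # perfect fit bound
        stat = max(0.0, 2.0 * (ll_full - ll_null))
        pvals.append(float(chi2.sf(stat, df=1)))
        flags.append(flag)
    padj = adjust_pvalues(np.array(pvals), method=adjust_method, m=len(feature_ids))
    return [
        DifferentialResult(
            feature_id=feature_ids[i],
            log2_fc=float(lfc[i]),
            pct_1=float(pct1[i]),
            pct_2=float(pct2[i]),
            p_value=float(p),
            p_adjusted=float(pa),
            direction="up_in_1" if lfc[i] > 0 else "up_in_2",
            convergence_flag=fl,
        )
        for i, p, pa, fl in zip(testable, pvals, padj, flags)
    ]


def find_markers_all(expr: np.ndarray, feature_ids: list[str],
                     labels: np.ndarray, test: str = "wilcoxon",
                     **kwargs) -> pd.DataFrame:
    """One-vs-rest marker detection looping over label values."""
    frames = []
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        g1 = np.flatnonzero(labels == lab)
        g2 = np.flatnonzero(labels != lab)
        fn = wilcoxon_deg if test == "wilcoxon" else lr_dap
        res = results_to_frame(fn(expr, feature_ids, g1, g2, **kwargs))
        res["group"] = lab
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
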