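"""Brute-force reference implementations used to validate the fast paths.

Everything here is deliberately naive — exhaustive enumeration and direct
formula transcription — and stays independent of the package internals.
"""

from itertools import combinations, product

import numpy as np


def auc_pairs(scores, labels) -> float:
    """Mean over all presence x absence pairs of 1(s_p > s_a) + 0.5·1(=)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) != 1]
    total = 0.0
    for p in pos:
        for a in neg:
            total += 1.0 if p > a else (0.5 if p == a else 0.0)
    return total / (len(pos) * len(neg))


def tss_exhaustive(scores, labels) -> float:
    """Max over every candidate cut of sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    best = -np.inf
    for cut in set(scores.tolist()) | {0.0, 1.0}:
        sens = np.mean(pos >= cut)
        spec = np.mean(neg < cut)
        best = max(best, sens + spec - 1.0)
    return float(best)


def schoeners_d_direct(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    p = a / a.sum()
    q = b / b.sum()
    return float(1.0 - 0.5 * sum(abs(pi - qi) for pi, qi in zip(p, q)))


def occc_direct(x, y) -> float:
    """Lin's concordance with population moments, written out longhand."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = sum((xi - mx) ** 2 for xi in x) / n
    sy = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return float(2.0 * sxy / (sx + sy + (mx - my) ** 2))


def vif_ols(X) -> np.ndarray:
    """VIF per column via explicit OLS of each column on the rest."""
    X = np.asarray(X, dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack([X[:, k] for k in range(p) if k != j])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if 1.0 - r2 < 1e-10 else 1.0 / (1.0 - r2)
    return out


def signed_rank_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Assumes no zero differences and no tied absolute values.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    ws = [
        float(sum(r for r, s in zip(ranks, signs) if s))
        for signs in product([0, 1], repeat=len(d))
    ]
    total = len(ws)
    p_le = sum(w <= w_obs for w in ws) / total
    p_ge = sum(w >= w_obs for w in ws) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all label assignments.

    Assumes no ties across the pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(a)
    w_obs = float(ranks[:n1].sum())
    ws = [
        float(sum(ranks[list(idx)]))
        for idx in combinations(range(len(pooled)), n1)
    ]
    total = len(ws)
    p_le = sum(w <= w_obs for w in ws) / total
    p_ge = sum(w >= w_obs for w in ws) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
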