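"""Independent oracles used only by the test suite.

These deliberately avoid the package's code paths: the Tucker oracle uses
einsum contractions and eigendecompositions of mode covariance matrices
(rather than SVDs of unfoldings via moveaxis/tensordot), the AUC oracle
counts pairs, and the Fisher oracle enumerates tables with plain Python
fractions of factorials.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Tucker fit oracle (3-way only)
# ---------------------------------------------------------------------------

def oracle_tucker_rel_error(tensor: np.ndarray, ranks, n_iter: int = 500,
                            tol: float = 1e-12) -> float:
    """Relative Tucker reconstruction error by alternating eigendecomposition.

    Initializes each factor from the eigenvectors of its mode covariance and
    alternates until the fit stops improving.
    """
    T = np.asarray(tensor, dtype=float)
    r1, r2, r3 = ranks

    def mode_cov_eig(M, r):
        S = M @ M.T
        w, v = np.linalg.eigh(S)
        return v[:, ::-1][:, :r]

    A = mode_cov_eig(np.einsum("ijk->ijk", T).reshape(T.shape[0], -1), r1)
    B = mode_cov_eig(np.transpose(T, (1, 0, 2)).reshape(T.shape[1], -1), r2)
    C = mode_cov_eig(np.transpose(T, (2, 0, 1)).reshape(T.shape[2], -1), r3)

    norm = np.linalg.norm(T)
    prev = -1.0
    for _ in range(n_iter):
        Y = np.einsum("ijk,jb,kc->ibc", T, B, C, optimize=True)
        A = mode_cov_eig(Y.reshape(T.shape[0], -1), r1)
        Y = np.einsum("ijk,ia,kc->ajc", T, A, C, optimize=True)
        B = mode_cov_eig(np.transpose(Y, (1, 0, 2)).reshape(T.shape[1], -1), r2)
        Y = np.einsum("ijk,ia,jb->abk", T, A, B, optimize=True)
        C = mode_cov_eig(np.transpose(Y, (2, 0, 1)).reshape(T.shape[2], -1), r3)
        core = np.einsum("ijk,ia,jb,kc->abc", T, A, B, C, optimize=True)
        fit = np.linalg.norm(core) / norm
        if fit - prev < tol:
            break
        prev = fit
    core = np.einsum("ijk,ia,jb,kc->abc", T, A, B, C, optimize=True)
    err_sq = max(norm**2 - np.sum(core**2), 0.0)
    return float(np.sqrt(err_sq) / norm)


def oracle_hosvd_rel_error(tensor: np.ndarray, ranks) -> float:
    """Truncated-HOSVD error via eigendecompositions, no iteration."""
    T = np.asarray(tensor, dtype=float)
    facs = []
    for mode, r in enumerate(ranks):
        M = np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)
        w, v = np.linalg.eigh(M @ M.T)
        facs.append(v[:, ::-1][:, :r])
    core = np.einsum("ijk,ia,jb,kc->abc", T, *facs, optimize=True)
    norm = np.linalg.norm(T)
    return float(np.sqrt(max(norm**2 - np.sum(core**2), 0.0)) / norm)


# ---------------------------------------------------------------------------
# AUC by brute-force pair counting (Mann-Whitney statistic)
# ---------------------------------------------------------------------------

def oracle_auc_pairs(values_pos, values_neg) -> float:
    wins = ties = 0
    for vp in values_pos:
        for vn in values_neg:
            if vp > vn:
                wins += 1
            elif vp == vn:
                ties += 1
    return (wins + 0.5 * ties) / (len(values_pos) * len(values_neg))


# ---------------------------------------------------------------------------
# Fisher exact two-sided p by exact rational enumeration
# ---------------------------------------------------------------------------

def oracle_fisher_two_sided(table) -> float:
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return (
            Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return float(total)


# ---------------------------------------------------------------------------
# Independent full enumeration of judge assemblies (no bounds, plain loops)
# ---------------------------------------------------------------------------

def oracle_best_assembly_score(P: np.ndarray, truth: np.ndarray, fold_id: np.ndarray,
                               committee_indices, gate_indices) -> float:
    """Max mean per-fold MCC over all (gate, pos-committee, neg-committee)
    assemblies with distinct members within a committee."""

    def mcc(pred, t):
        tp = np.sum(pred & t)
        fp = np.sum(pred & ~t)
        fn = np.sum(~pred & t)
        tn = np.sum(~pred & ~t)
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        return 0.0 if den == 0 else (tp * tn - fp * fn) / math.sqrt(den)

    folds = np.unique(fold_id)
    best = -np.inf
    combos = list(itertools.combinations(committee_indices, 3))
    for g in gate_indices:
        route = P[:, g] >= 0
        for pos_c in combos:
            pos_mean = P[:, list(pos_c)].mean(axis=1)
            for neg_c in combos:
                neg_mean = P[:, list(neg_c)].mean(axis=1)
                vals = np.where(route, pos_mean, neg_mean)
                pred = vals >= 0
                score = np.mean([mcc(pred[fold_id == f], truth[fold_id == f]) for f in folds])
                best = max(best, score)
    return float(best)
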