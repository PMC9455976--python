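"""Independent reference implementations used only to cross-check results.

These are deliberately written in a different style (and a different
algorithm where possible) from the package code: SIMPLS instead of NIPALS,
and literal step-by-step transcriptions of the VIP and selectivity-ratio
formulas instead of vectorised linear algebra.
"""

from __future__ import annotations

import numpy as np


def simpls_coefficients(Xc: np.ndarray, Yc: np.ndarray, A: int) -> np.ndarray:
    """de Jong's SIMPLS regression matrix for centred X and Y."""
    n, p = Xc.shape
    S = Xc.T @ Yc
    R = np.zeros((p, A))
    V = np.zeros((p, A))
    Q = np.zeros((Yc.shape[1], A))
    for a in range(A):
        u, s, vt = np.linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        t = Xc @ r
        nt = np.linalg.norm(t)
        t = t / nt
        r = r / nt
        p_load = Xc.T @ t
        q = Yc.T @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a] = r
        V[:, a] = v
        Q[:, a] = q
    return R @ Q.T


def vip_literal(W: np.ndarray, T: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Literal per-variable transcription of the VIP formula."""
    p, A = W.shape
    ssy = []
    for a in range(A):
        t_a = T[:, a]
        q_a = Q[:, a]
        ssy.append(float(q_a @ q_a) * float(t_a @ t_a))
    total = sum(ssy)
    out = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for a in range(A):
            w_a = W[:, a]
            acc += ssy[a] * (W[j, a] / np.linalg.norm(w_a)) ** 2
        out[j] = np.sqrt(p * acc / total)
    return out


def selectivity_ratio_literal(Xs: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Literal per-variable, per-class transcription of the selectivity ratio."""
    n, p = Xs.shape
    c = B.shape[1]
    out = np.zeros((p, c))
    for k in range(c):
        b = B[:, k]
        t = Xs @ b / np.linalg.norm(b)
        tt = float(t @ t)
        for j in range(p):
            p_tp_j = float(Xs[:, j] @ t) / tt
            ss_expl = p_tp_j ** 2 * tt
            ss_tot = float(Xs[:, j] @ Xs[:, j])
            ss_res = ss_tot - ss_expl
            out[j, k] = ss_expl / ss_res if ss_res > 1e-12 * max(ss_tot, 1e-300) else 1e12
    return out


def roc_auc_brute(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC by exhaustive comparison of all positive/negative pairs."""
    pos = scores[truth.astype(bool)]
    neg = scores[~truth.astype(bool)]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
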