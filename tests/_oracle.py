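"""Independent straight-line oracles, deliberately sharing no code with
the package: explicit loops, explicit matrix inversion, two-pass Pearson.
Used to cross-check the production pipeline on tiny instances.
"""

import numpy as np


def oracle_pearson(x, y):
    """Two-pass textbook Pearson r; constant input -> 0."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for i in range(n):
        sxy += (x[i] - mx) * (y[i] - my)
        sxx += (x[i] - mx) ** 2
        syy += (y[i] - my) ** 2
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    return sxy / (sxx**0.5 * syy**0.5)


def oracle_normalize_symmetric(S):
    n = S.shape[0]
    W = np.zeros((n, n))
    row_sums = [sum(S[i]) for i in range(n)]
    for i in range(n):
        for j in range(n):
            W[i, j] = S[i, j] / (row_sums[i] ** 0.5 * row_sums[j] ** 0.5)
    return W


def oracle_propagate(S, q, alpha):
    """f = (1-alpha) (I - alpha W)^-1 q via explicit inverse."""
    W = oracle_normalize_symmetric(S)
    n = S.shape[0]
    M = np.linalg.inv(np.eye(n) - alpha * W)
    return (1.0 - alpha) * (M @ np.asarray(q, dtype=float))


def oracle_rank_targets(D, P, A, query_idx, alpha, beta, variant, mask_query_row):
    """Score every protein for one query drug; returns the score array.

    Mirrors the full pipeline (symmetric normalization only) with explicit
    per-protein loops.
    """
    n, m = A.shape
    d = [0.0] * n
    d[query_idx] = 1.0
    f_d = oracle_propagate(D, d, alpha)
    Awork = A.astype(float).copy()
    if mask_query_row:
        for j in range(m):
            Awork[query_idx, j] = 0.0
    scores = np.zeros(m)
    for j in range(m):
        p = [0.0] * m
        p[j] = 1.0
        f_p = oracle_propagate(P, p, beta)
        if variant == "drug_side":
            proj = [sum(Awork[i, k] * f_p[k] for k in range(m)) for i in range(n)]
            scores[j] = oracle_pearson(list(f_d), proj)
        else:
            proj = [sum(Awork[i, k] * f_d[i] for i in range(n)) for k in range(m)]
            scores[j] = oracle_pearson(list(f_p), proj)
    return scores


def oracle_auc(scores, labels):
    """Exhaustive concordant/tied pair counting."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_dataset(rng, n, m):
    """Random valid (D, P, A) arrays: symmetric similarities in [0,1] with
    unit diagonal, binary interactions with at least one 1 and one 0."""
    D = rng.random((n, n))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 1.0)
    P = rng.random((m, m))
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 1.0)
    A = (rng.random((n, m)) < 0.4).astype(np.int8)
    if A.sum() == 0:
        A[0, 0] = 1
    if A.sum() == A.size:
        A[-1, -1] = 0
    return D, P, A
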