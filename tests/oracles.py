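"""Independent brute-force oracles used by the test suite.

These re-derive expected values by direct enumeration or generic
numerical optimisation, deliberately sharing no code with the package's
vectorised implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# cell-population LD profile: direct enumeration of the neighbourhood sets


def brute_force_ld_profile(positions, c1, c2, phased, edges, symmetrize=True):
    """Two-/three-locus cosegregation scores by explicit set enumeration."""
    edges = np.asarray(edges, dtype=float)
    n_bins = len(edges) - 1
    germ = [i for i in range(len(positions)) if phased[i]]
    tot2 = [0] * n_bins
    cos2 = [0] * n_bins
    tot3 = [0] * n_bins
    cos3 = [0] * n_bins
    n_cells = c1.shape[1]

    def covered(i, j):
        return c1[i, j] + c2[i, j] > 0

    def bin_of(d):
        for b in range(n_bins):
            if edges[b] <= d < edges[b + 1]:
                return b
        raise AssertionError

    for j in range(n_cells):
        for a, k in enumerate(germ):
            for i in germ[a + 1:]:
                if not (covered(k, j) and covered(i, j)):
                    continue
                if any(covered(l, j) for l in germ if k < l < i):
                    continue
                b = bin_of(positions[i] - positions[k])
                tot2[b] += 1
                if (c1[k, j] > 0 and c1[i, j] > 0) or (c2[k, j] > 0 and c2[i, j] > 0):
                    cos2[b] += 1
        for a, k in enumerate(germ):
            for bidx, i in enumerate(germ[a + 1:], start=a + 1):
                for l in germ[bidx + 1:]:
                    if not (covered(k, j) and covered(i, j) and covered(l, j)):
                        continue
                    if any(covered(x, j) for x in germ if k < x < i):
                        continue
                    if any(covered(x, j) for x in germ if i < x < l):
                        continue
                    b = bin_of(positions[i] - positions[k])
                    if c1[k, j] > 0 and c1[l, j] > 0:
                        tot3[b] += 1
                        if c1[i, j] > 0:
                            cos3[b] += 1
                    if symmetrize and c2[k, j] > 0 and c2[l, j] > 0:
                        tot3[b] += 1
                        if c2[i, j] > 0:
                            cos3[b] += 1

    score2 = [1.0 - cos2[b] / tot2[b] if tot2[b] else float("nan") for b in range(n_bins)]
    score3 = [1.0 - cos3[b] / tot3[b] if tot3[b] else float("nan") for b in range(n_bins)]
    return np.array(score2), np.array(tot2), np.array(score3), np.array(tot3)


# ---------------------------------------------------------------------------
# diploid haplotype-copying HMM: naive state-space dynamic programming


def naive_diploid_hmm_posteriors(H, pos, logL, theta, rho_scale):
    """Genotype posteriors by explicit summation over all K^2 pair states.

    Transition/emission probabilities are computed entry by entry from
    their definitions; no factorisation tricks.
    """
    H = np.asarray(H)
    K, M = H.shape[0], len(pos)
    states = list(product(range(K), range(K)))
    lin = np.exp(logL - np.max(logL, axis=1, keepdims=True))
    lin = lin / lin.sum(axis=1, keepdims=True)

    def chain_T(d):
        r = 1.0 - np.exp(-d / rho_scale)
        return [[(1 - r) + r / K if a == b else r / K for b in range(K)] for a in range(K)]

    def emit_w(h, m):
        return 1.0 - theta if H[h, m] == 1 else theta

    def emission(m, h1, h2):
        w1, w2 = emit_w(h1, m), emit_w(h2, m)
        total = 0.0
        for a1 in (0, 1):
            for a2 in (0, 1):
                p1 = w1 if a1 else 1 - w1
                p2 = w2 if a2 else 1 - w2
                total += p1 * p2 * lin[m, a1 + a2]
        return total

    # forward
    alpha = [{} for _ in range(M)]
    for s in states:
        alpha[0][s] = emission(0, *s) / (K * K)
    for m in range(1, M):
        T = chain_T(float(pos[m] - pos[m - 1]))
        for s in states:
            acc = 0.0
            for sp in states:
                acc += alpha[m - 1][sp] * T[sp[0]][s[0]] * T[sp[1]][s[1]]
            alpha[m][s] = acc * emission(m, *s)
        norm = sum(alpha[m].values())
        for s in states:
            alpha[m][s] /= norm
    # backward
    beta = [{} for _ in range(M)]
    for s in states:
        beta[M - 1][s] = 1.0
    for m in range(M - 2, -1, -1):
        T = chain_T(float(pos[m + 1] - pos[m]))
        for s in states:
            acc = 0.0
            for sn in states:
                acc += T[s[0]][sn[0]] * T[s[1]][sn[1]] * emission(m + 1, *sn) * beta[m + 1][sn]
            beta[m][s] = acc
        norm = max(beta[m].values())
        for s in states:
            beta[m][s] /= norm

    post_g = np.zeros((M, 3))
    for m in range(M):
        z = 0.0
        for s in states:
            p_state = alpha[m][s] * beta[m][s]
            z += p_state
            w1, w2 = emit_w(s[0], m), emit_w(s[1], m)
            gd = np.array([
                (1 - w1) * (1 - w2) * lin[m, 0],
                (w1 * (1 - w2) + (1 - w1) * w2) * lin[m, 1],
                w1 * w2 * lin[m, 2],
            ])
            post_g[m] += p_state * gd / gd.sum()
        post_g[m] /= z
    return post_g


# ---------------------------------------------------------------------------
# projection Procrustes: generic numerical minimisation


def numeric_procrustes_objective(Y, Z, n_restarts=2, seed=0):
    """min_{rho, A orthonormal} ||rho Z A - Y||_F^2 by L-BFGS over an
    unconstrained matrix mapped to orthonormal columns via QR."""
    Kp = Z.shape[1]
    K = Y.shape[1]
    rng = np.random.default_rng(seed)

    def unpack(x):
        B = x[:-1].reshape(Kp, K)
        Q, R = np.linalg.qr(B)
        Q = Q * np.sign(np.diag(R))  # make the map continuous-ish
        return Q, x[-1]

    def obj(x):
        A, rho = unpack(x)
        return float(np.sum((rho * Z @ A - Y) ** 2))

    best = np.inf
    for _ in range(n_restarts):
        x0 = np.concatenate([rng.normal(size=Kp * K), [1.0]])
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        best = min(best, float(res.fun))
    return best
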