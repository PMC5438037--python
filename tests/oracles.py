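"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain loops and textbook
formulas, independent of the package's implementation paths.
"""

import math
from math import comb

import numpy as np


def mi_oracle(x, y) -> float:
    """Plug-in MI (bits) by explicit summation over the empirical joint table."""
    x, y = np.asarray(x), np.asarray(y)
    keep = (x != -1) & (y != -1)
    x, y = x[keep], y[keep]
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                total += pxy * math.log2(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return total


def mrmr_oracle(X, y, k, criterion):
    """Step-by-step greedy mRmR re-implementation with plain loops."""
    p = X.shape[1]
    rel = [mi_oracle(X[:, j], y) for j in range(p)]
    selected = [int(np.argmax(rel))]
    while len(selected) < min(k, p):
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            red = np.mean([mi_oracle(X[:, j], X[:, s]) for s in selected])
            if criterion == "difference":
                score = rel[j] - red
            else:
                score = rel[j] / max(red, 1e-12)
            if score > best_score:  # strict: ties keep the lowest index
                best, best_score = j, score
        selected.append(best)
    return selected


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test by direct enumeration with binomial coefficients."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # copies of allele a

    def prob(h):
        if (na - h) % 2:
            return 0.0
        haa = (na - h) // 2
        hbb = n - h - haa
        if haa < 0 or hbb < 0:
            return 0.0
        return comb(n, haa) * comb(n - haa, h) * 2**h / comb(2 * n, na)

    probs = [prob(h) for h in range(0, min(na, 2 * n - na) + 1)]
    p_obs = prob(n_ab)
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-12)))


def bh_oracle(ps):
    """Hand step-up BH: adjusted_i = min over sorted tail of m*p/rank, capped."""
    ps = list(ps)
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * ps[i] / rank_from_top)
        adj[i] = running
    return adj


def logistic_loglik(y, x, b0, b1):
    eta = b0 + b1 * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def nagelkerke_grid_oracle(y, x):
    """Nagelkerke R² by nested-grid maximization of the logistic likelihood."""
    n = len(y)
    p1 = y.mean()
    ll0 = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    b0c, b1c, width = 0.0, 0.0, 8.0
    best = (-np.inf, 0.0, 0.0)
    for _ in range(8):
        for b0 in np.linspace(b0c - width, b0c + width, 41):
            for b1 in np.linspace(b1c - width, b1c + width, 41):
                ll = logistic_loglik(y, x, b0, b1)
                if ll > best[0]:
                    best = (ll, b0, b1)
        _, b0c, b1c = best
        width /= 5.0
    ll1 = best[0]
    cs = 1 - np.exp(2 * (ll0 - ll1) / n)
    return cs / (1 - np.exp(2 * ll0 / n))
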