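"""Brute-force enumeration oracles, written independently of the package.

Each oracle recomputes a null distribution from first principles
(itertools enumeration, direct counting) and is deliberately naive; the
package's optimized implementations are checked against these on small
samples where enumeration is exhaustive.
"""

import itertools
import math

import numpy as np
from scipy.special import comb


def mw_u_direct(x, y):
    """U statistic by direct pair counting (count x_i > y_j, ties half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = mw_u_direct(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(mw_u_direct(xs, ys))
    us = np.asarray(us)
    tol = 1e-9
    p = 2 * min((us <= u_obs + tol).mean(), (us >= u_obs - tol).mean())
    return min(1.0, p)


def signed_rank_exact_p(before, after):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=m):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    tol = 1e-9
    p = 2 * min((ws <= w_obs + tol).mean(), (ws >= w_obs - tol).mean())
    return min(1.0, p)


def spearman_exact_p(x, y):
    """Two-sided exact permutation p for Spearman's rho, naive enumeration."""
    from scipy.stats import spearmanr

    rho_obs = spearmanr(x, y).statistic
    n = len(y)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = spearmanr(x, [y[i] for i in perm]).statistic
        hits += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


def fisher_exact_p(table):
    """Two-sided Fisher p: hypergeometric enumeration, prob-mass rule."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def icc_21_variance_components(m):
    """ICC(2,1) via direct variance-component estimates (oracle form)."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        / ((n - 1) * (k - 1))
    )
    var_r = (msr - mse) / k
    var_c = (msc - mse) / n
    return var_r / (var_r + var_c + mse)


def polygon_area_mc(vertices, n_points=1_000_000, seed=0):
    """Monte-Carlo area of a polygon by point-in-polygon rejection."""
    v = np.asarray(vertices, float)
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    # ray casting, vectorized over edges
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(n_points, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y)) & (
            x < (x2 - x1) * (y - y1) / (y2 - y1) + x1
        )
        inside ^= crosses
    box = np.prod(hi - lo)
    return inside.mean() * box
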