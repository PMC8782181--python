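"""Independent oracle implementations used only by the test suite.

These deliberately use naive loops / enumeration / numerical integration
and share no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats


def fcm_reference(x, c, m, u0, n_iter=200, tol=1e-9):
    """Literal fuzzy c-means update equations, python loops throughout."""
    x = np.asarray(x, float)
    n, d = x.shape
    u = np.array(u0, float).copy()
    for _ in range(n_iter):
        v = np.zeros((c, d))
        for i in range(c):
            num = np.zeros(d)
            den = 0.0
            for j in range(n):
                w = u[j, i] ** m
                num += w * x[j]
                den += w
            v[i] = num / den
        u_new = np.zeros_like(u)
        for j in range(n):
            dists = [math.dist(x[j], v[i]) for i in range(c)]
            if any(dd == 0.0 for dd in dists):
                hits = [i for i, dd in enumerate(dists) if dd == 0.0]
                for i in hits:
                    u_new[j, i] = 1.0 / len(hits)
                continue
            for i in range(c):
                s = 0.0
                for k in range(c):
                    s += (dists[i] / dists[k]) ** (2.0 / (m - 1.0))
                u_new[j, i] = 1.0 / s
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return v, u


def bh_bruteforce(pvals):
    """Benjamini-Hochberg by the textbook sorted p*n/rank + cummin recipe."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p)
    adj_sorted = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def mannwhitney_u(x, y):
    """U statistic of x over y by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mannwhitney_exact_p(x, y):
    """Two-sided exact p by full enumeration over group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = mannwhitney_u(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        sel = set(combo)
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(mannwhitney_u(xs, ys))
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def hypergeom_enum_p(n_universe, n_term, n_query, k):
    """P(overlap >= k) by enumeration of all C(N, n) draws."""
    marked = set(range(n_term))
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n_universe), n_query):
        total += 1
        if len(marked.intersection(combo)) >= k:
            hits += 1
    return hits / total


def welch_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return (a.mean() - b.mean()) / se


def censored_tail_mean(mu, sigma, cut):
    """E[X | X < cut] for X ~ N(mu, sigma^2), by numerical integration."""
    pdf = lambda t: stats.norm.pdf(t, mu, sigma)  # noqa: E731
    num, _ = integrate.quad(lambda t: t * pdf(t), mu - 12 * sigma, cut)
    den, _ = integrate.quad(pdf, mu - 12 * sigma, cut)
    return num / den


def schwammle_jensen_m(n, d):
    """Fuzzifier formula evaluated independently (different code path)."""
    term1 = (1418.0 / n + 22.05) * math.pow(d, -2.0)
    term2 = (12.33 / n + 0.243) * math.pow(
        d, -0.0406 * math.log(n) - 0.1134
    )
    return 1.0 + term1 + term2
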