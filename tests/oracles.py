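"""Brute-force oracles, coded independently of the library implementations.

Used by the unit and acceptance tests to verify statistical primitives by
direct enumeration / direct formula evaluation.
"""

import itertools
import math

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg by the literal step-up definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj


def hypergeom_ge(k, pop, successes, draws):
    """P(X >= k) for X ~ Hypergeom(pop, successes, draws), by enumeration."""
    total = math.comb(pop, draws)
    lo = max(k, 0)
    hi = min(successes, draws)
    if lo > hi:
        return 0.0
    return sum(math.comb(successes, x) * math.comb(pop - successes, draws - x)
               for x in range(lo, hi + 1)) / total


def fisher_greater_p(table):
    """One-sided (enrichment) Fisher exact p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    return hypergeom_ge(a, a + b + c + d, a + b, a + c)


def spearman_rho_d2(x, y):
    """Spearman rho by the 1 - 6*sum(d^2)/(n(n^2-1)) formula (no ties)."""
    n = len(x)
    rx = {v: r for r, v in enumerate(sorted(x), start=1)}
    ry = {v: r for r, v in enumerate(sorted(y), start=1)}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))


def flat_prior_moderation(matrix, groups, contrast):
    """Direct flat-prior (count-free) empirical-Bayes moderated t.

    ``matrix``: proteins x samples ndarray; ``groups``: list of column-index
    lists per group; ``contrast``: (i, j) group indices. Prior variance is
    the constant exp(mean(log s2)); prior df by log-F moment matching with
    its own trigamma inversion (scipy brentq), independent of the library.
    """
    from scipy import optimize, special

    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = n_total - k
    rss = np.zeros(matrix.shape[0])
    means = []
    for cols in groups:
        sub = matrix[:, cols]
        mu = sub.mean(axis=1)
        means.append(mu)
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    logs2 = np.log(np.maximum(s2, 1e-12))
    # chi-square log bias: E[log s2] = log sigma2 + digamma(df/2) - log(df/2)
    bias = special.digamma(df / 2) - np.log(df / 2)
    s0 = float(np.exp(logs2.mean() - bias))
    z = np.log(np.maximum(s2, 1e-12) / s0)
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        d0 = np.inf
        s2_post = np.full_like(s2, s0)
    else:
        d0 = 2 * optimize.brentq(
            lambda v: special.polygamma(1, v) - evar, 1e-6, 1e8)
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
    i, j = contrast
    n1, n2 = len(groups[i]), len(groups[j])
    lfc = means[i] - means[j]
    t = lfc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    return t, d0


def exact_spearman_perm_p(x, y):
    """Two-sided permutation p for Spearman rho by full enumeration."""
    from scipy import stats

    rho_obs, _ = stats.spearmanr(x, y)
    ry = stats.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(ry):
        rho, _ = stats.spearmanr(x, np.asarray(perm))
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total
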