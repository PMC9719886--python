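"""Independent brute-force oracles used to verify the fast implementations.

Each oracle recomputes a statistic by direct enumeration or all-pairs
counting, sharing no code path with the routines it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def mw_u(a, b) -> float:
    """U statistic of sample ``a`` by direct pairwise counting."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def mw_exact_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all labelings.

    Valid for tie-free pooled samples: the null distribution of U is
    symmetric about n1*n2/2, so the two-sided p doubles the smaller tail
    (with the observed point included on both sides).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    u_obs = mw_u(a, b)
    m = n1 * b.size
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    total = 0
    count = 0
    for idx in combinations(range(pooled.size), n1):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        u = mw_u(pooled[mask], pooled[~mask])
        total += 1
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            count += 1
    return min(count / total, 1.0)


def fisher_exact_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    (a, b), (c, d) = np.asarray(table, int)
    r1, c1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def spearman_rho(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks."""

    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        sv = v[order]
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def auc_concordance(scores, labels, higher_is_positive=True) -> float:
    """AUC by all-pairs concordance counting (ties count one half)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    if not higher_is_positive:
        pos, neg = -pos, -neg
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))


def roi_members_bruteforce(shape, center, radius):
    """Disk membership by checking every pixel centre's distance."""
    out = np.zeros(shape, bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                out[r, c] = True
    return out
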