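"""Brute-force reference implementations, independent of the package code.

Each oracle recomputes a statistic from its definition (explicit ranks,
closed-form t formulas, dense eigendecompositions) so agreement with the
pipeline is a genuine two-route check.
"""

import numpy as np
from scipy.special import stdtr


def shannon_oracle(counts, base=2.0):
    """Direct summation over the definition, no vectorization tricks."""
    total = float(sum(c for c in counts if c > 0))
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p) / np.log(base)
    return h


def midranks(values):
    """Average ranks (1-based) with midrank tie handling, by enumeration."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / np.sqrt(sxx * syy)


def spearman_oracle(x, y):
    """rho = Pearson correlation of midranks; two-sided p from the
    t-approximation with n − 2 degrees of freedom."""
    rx, ry = midranks(x), midranks(y)
    rho = pearson_oracle(rx, ry)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * (1.0 - stdtr(n - 2, abs(t)))
    return rho, p


def paired_t_oracle(x, y):
    """One-sample t on the differences, from the closed form."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    md = sum(d) / n
    var = sum((v - md) ** 2 for v in d) / (n - 1)
    if var == 0:
        return 0.0, n - 1, 1.0
    t = md / np.sqrt(var / n)
    p = 2.0 * (1.0 - stdtr(n - 1, abs(t)))
    return t, n - 1, p


def kruskal_oracle(groups):
    """H with the midrank tie correction, computed by enumeration."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        i += len(g)
        h += len(g) * (sum(r) / len(g) - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    ties = sum(c**3 - c for c in counts.values())
    denom = 1.0 - ties / float(n**3 - n)
    return h / denom


def ca_eigenvalues_oracle(matrix):
    """CA eigenvalues via a dense eigendecomposition of the
    reciprocal-averaging transition matrix D_r^{-1} P D_c^{-1} Pᵀ
    (its spectrum is {1, λ₁, λ₂, …}) — an independent route from the
    SVD of the standardized residuals."""
    M = np.asarray(matrix, dtype=float)
    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    T = (P / r[:, None]) @ (P.T / c[:, None])  # D_r^-1 P D_c^-1 P^T
    eig = np.linalg.eigvals(T)
    eig = np.sort(eig.real)[::-1]
    # drop the trivial unit eigenvalue
    assert abs(eig[0] - 1.0) < 1e-8
    return eig[1:]
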