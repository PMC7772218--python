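"""Independent brute-force reference implementations used across tests.

These share no code with the package: each is a direct transcription of
the defining formula or algorithm, used only to check the optimized
implementations.
"""

import math

import numpy as np


def wc84_oracle(counts_a, counts_b):
    """Two-population Weir-Cockerham theta-hat from first principles."""
    pops = []
    for n0, n1, n2 in (counts_a, counts_b):
        n = n0 + n1 + n2
        pops.append((n, (n1 + 2.0 * n2) / (2 * n), n1 / n))
    r = 2
    nbar = sum(p[0] for p in pops) / r
    nc = (r * nbar - sum(p[0] ** 2 for p in pops) / (r * nbar)) / (r - 1)
    pbar = sum(p[0] * p[1] for p in pops) / (r * nbar)
    s2 = sum(p[0] * (p[1] - pbar) ** 2 for p in pops) / ((r - 1) * nbar)
    hbar = sum(p[0] * p[2] for p in pops) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return math.nan
    return a / (a + b + c)


def ward_oracle(X):
    """Exhaustive Ward agglomeration (lowest-index ties).

    Merge heights follow the linkage convention
    d(u, v) = sqrt(2 |u||v| / (|u|+|v|)) * ||centroid_u - centroid_v||.
    """
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights)


def bh_oracle(p, alpha):
    """Exhaustive Benjamini-Hochberg step-up rejection set."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject
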