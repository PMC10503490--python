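"""Independent brute-force implementations used as test oracles.

Everything here is written from the printed textbook formulas with plain
loops, deliberately sharing no code with the package.
"""

import math

import numpy as np


def wc_oracle(pops):
    """Weir-Cockerham variance components for one locus.

    ``pops`` is a list of per-subsample genotype lists [(a1, a2), ...]
    (complete calls only).  Returns (a, b, c) summed over alleles.
    """
    pops = [p for p in pops if len(p)]
    r = len(pops)
    n_i = [len(p) for p in pops]
    nbar = sum(n_i) / r
    if r == 1:
        nc = nbar
    else:
        nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    alleles = sorted({a for p in pops for g in p for a in g})
    A = B = C = 0.0
    for al in alleles:
        p_i, h_i = [], []
        for pop in pops:
            n = len(pop)
            copies = sum(int(g[0] == al) + int(g[1] == al) for g in pop)
            hets = sum(1 for g in pop
                       if bool(g[0] == al) != bool(g[1] == al))
            p_i.append(copies / (2 * n))
            h_i.append(hets / n)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        if r == 1:
            s2 = 0.0
            a = 0.0
        else:
            s2 = sum(n * (p - pbar) ** 2
                     for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                               * (pbar * (1 - pbar)
                                  - (r - 1) / r * s2 - hbar / 4.0))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        A, B, C = A + a, B + b, C + c
    return A, B, C


def g_oracle(table):
    """G = 2 sum O ln(O/E) over nonzero cells of a contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    g = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            o = table[i, j]
            if o > 0:
                e = table[i].sum() * table[:, j].sum() / n
                g += 2 * o * math.log(o / e)
    return g


def by_oracle(ps):
    """Benjamini-Yekutieli step-up adjustment by the printed rule."""
    ps = list(ps)
    m = len(ps)
    if m == 0:
        return []
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, ps[i] * m * c_m / rank)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return adj


def nei_oracle(pop_genotypes):
    """(H_S, H_T) for one locus from per-subsample genotype lists."""
    per_pop_h, per_pop_freqs = [], []
    alleles = sorted({a for p in pop_genotypes for g in p for a in g})
    for pop in pop_genotypes:
        if not pop:
            continue
        ng = 2 * len(pop)
        counts = {al: sum(int(g[0] == al) + int(g[1] == al) for g in pop)
                  for al in alleles}
        p = {al: counts[al] / ng for al in alleles}
        ss = sum(v * v for v in p.values())
        per_pop_h.append(ng / (ng - 1) * (1 - ss) if ng > 1 else 0.0)
        per_pop_freqs.append(p)
    hs = sum(per_pop_h) / len(per_pop_h)
    k = len(per_pop_freqs)
    pbar = {al: sum(f[al] for f in per_pop_freqs) / k for al in alleles}
    ht = 1 - sum(v * v for v in pbar.values())
    return hs, ht


def chord_oracle(fx, fy):
    """(2/pi) sqrt(2 (1 - sum sqrt(x y))) by direct loops."""
    alleles = set(fx) | set(fy)
    s = 0.0
    for a in alleles:
        s += math.sqrt(fx.get(a, 0.0) * fy.get(a, 0.0))
    return (2.0 / math.pi) * math.sqrt(2.0 * max(1.0 - s, 0.0))


def broken_stick_oracle(lams, k=10):
    lams = list(lams)
    p = len(lams)
    total = sum(lams)
    count = 0
    for i in range(1, min(k, p) + 1):
        b_i = sum(1.0 / j for j in range(i, p + 1)) / p
        if lams[i - 1] / total > b_i:
            count += 1
        else:
            break
    return count


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths.

    Returns ``(labels, dist)`` where dist is the exact patristic
    (path-length) distance matrix — an additive matrix by construction.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    dist = np.zeros((n_taxa, n_taxa))
    # cluster -> (leaf members, leaf -> distance to cluster root)
    clusters = [([i], {i: 0.0}) for i in range(n_taxa)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (ma, da), (mb, db) = clusters[j], clusters[i]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for x in ma:
            for y in mb:
                d = da[x] + la + lb + db[y]
                dist[x, y] = dist[y, x] = d
        merged = ({**{x: da[x] + la for x in ma},
                   **{y: db[y] + lb for y in mb}})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((ma + mb, merged))
    return labels, dist
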