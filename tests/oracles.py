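"""Independent brute-force oracles used only by the tests.

Every function here re-derives a quantity from its definition (explicit
enumeration, hand-style step-by-step arithmetic, exhaustive search) without
touching the package's implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(x) -> list[float]:
    """Ranks with average tie handling, by explicit sorting."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y) -> float:
    """Pearson correlation of average ranks, from the definition."""
    rx, ry = average_ranks(x), average_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def bh_brute(pvalues) -> list[float]:
    """BH step-up from the definition: q_i = min over j>=rank_i of n*p_(j)/j."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    for pos, idx in enumerate(order):
        candidates = [
            min(1.0, n * pvalues[order[j]] / (j + 1)) for j in range(pos, n)
        ]
        q[idx] = min(candidates)
    return q


def tmm_brute(counts: np.ndarray, sample: int, ref: int,
              trim_logratio: float = 0.3, trim_abs: float = 0.05) -> float:
    """Step-by-step trimmed weighted mean of M-values for one sample.

    Written independently: explicit sort-based double trimming instead of
    rank thresholds.
    """
    lib = counts.sum(axis=0)
    rows = []
    for g in range(counts.shape[0]):
        o, r = counts[g, sample], counts[g, ref]
        if o == 0 or r == 0:
            continue
        po, pr = o / lib[sample], r / lib[ref]
        m = math.log2(po / pr)
        a = (math.log2(po) + math.log2(pr)) / 2.0
        w = (lib[sample] - o) / (lib[sample] * o) + (lib[ref] - r) / (lib[ref] * r)
        rows.append((m, a, w))
    if not rows:
        return 1.0
    if max(abs(m) for m, _, _ in rows) < 1e-6:
        return 1.0
    n = len(rows)
    lo_m = math.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_abs) + 1
    hi_a = n + 1 - lo_a
    rank_m = average_ranks([m for m, _, _ in rows])
    rank_a = average_ranks([a for _, a, _ in rows])
    num = den = 0.0
    for (m, _, w), rm, ra in zip(rows, rank_m, rank_a):
        if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
            num += m / w
            den += 1.0 / w
    return 2.0 ** (num / den)


def pam_exhaustive_cost(d: np.ndarray, k: int) -> float:
    """Global minimum of the k-medoids objective by exhaustive search."""
    n = d.shape[0]
    best = math.inf
    for medoids in itertools.combinations(range(n), k):
        cost = sum(min(d[i, m] for m in medoids) for i in range(n))
        best = min(best, cost)
    return best


def ward2_merge_heights(d: np.ndarray) -> list[float]:
    """Agglomerative ward.D2 merge heights via the Lance-Williams update.

    d(k, i+j) = sqrt( ((n_i+n_k) d_ki^2 + (n_j+n_k) d_kj^2 - n_k d_ij^2)
                      / (n_i + n_j + n_k) ).
    """
    clusters = {i: 1 for i in range(d.shape[0])}
    dist = {
        frozenset((i, j)): float(d[i, j])
        for i in range(d.shape[0])
        for j in range(i + 1, d.shape[0])
    }
    heights = []
    next_id = d.shape[0]
    while len(clusters) > 1:
        (i, j), h = min(
            ((tuple(sorted(p)), v) for p, v in dist.items()), key=lambda t: (t[1], t[0])
        )
        heights.append(h)
        ni, nj = clusters.pop(i), clusters.pop(j)
        new_dist = {}
        for k in clusters:
            nk = clusters[k]
            dki = dist[frozenset((k, i))]
            dkj = dist[frozenset((k, j))]
            dij = h
            val = math.sqrt(
                ((ni + nk) * dki**2 + (nj + nk) * dkj**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            new_dist[frozenset((k, next_id))] = val
        dist = {
            p: v for p, v in dist.items() if not (p & {i, j})
        }
        dist.update(new_dist)
        clusters[next_id] = ni + nj
        next_id += 1
    return heights


def silhouette_brute(d: np.ndarray, labels) -> list[float]:
    """s(i) = (b - a)/max(a, b) from the definition; singletons get 0."""
    labels = list(labels)
    out = []
    for i in range(len(labels)):
        own = [j for j in range(len(labels)) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = sum(d[i, j] for j in own) / len(own)
        b = math.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(len(labels)) if labels[j] == c]
            b = min(b, sum(d[i, j] for j in other) / len(other))
        out.append((b - a) / max(a, b))
    return out


def gsea_es_brute(genes, scores, gene_set, weight: float = 1.0) -> float:
    """Running-sum ES by explicit iteration over the ranked list."""
    members = set(gene_set)
    hits = [g in members for g in genes]
    n, m = len(genes), sum(hits)
    denom = sum(abs(s) ** weight for g, s in zip(genes, scores) if g in members)
    running = 0.0
    best = 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            running += (abs(s) ** weight / denom) if denom > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


def assortativity_brute(edges, labels) -> float:
    """(sum e_ii - sum a_i b_i) / (1 - sum a_i b_i) from the mixing matrix."""
    cats = sorted({labels[v] for e in edges for v in e})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in edges:
        e[idx[labels[u]], idx[labels[v]]] += 1
        e[idx[labels[v]], idx[labels[u]]] += 1
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    return (np.trace(e) - float(a @ b)) / (1.0 - float(a @ b))


def fisher_or_brute(table) -> float:
    (a, b), (c, d) = table
    return (a * d) / (b * c)


def fisher_p_brute(table) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def point(x):
        return (
            math.comb(r1, x)
            * math.comb(n - r1, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = point(a)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-9))


def cosine_brute(x, y) -> float:
    num = sum(a * b for a, b in zip(x, y))
    return num / (math.sqrt(sum(a * a for a in x)) * math.sqrt(sum(b * b for b in y)))


def cosine_perm_pvalue_exhaustive(x, y) -> float:
    """Two-sided cosine permutation p over all permutations of y (small n)."""
    obs = abs(cosine_brute(x, y))
    perms = list(itertools.permutations(y))
    n_ge = sum(1 for p in perms if abs(cosine_brute(x, p)) >= obs - 1e-12)
    return n_ge / len(perms)


def core_numbers_brute(adj: dict) -> dict:
    """k-core numbers by iterative peeling from the definition."""
    core = {}
    remaining = {v: set(ns) for v, ns in adj.items()}
    k = 0
    while remaining:
        while True:
            peel = [v for v, ns in remaining.items() if len(ns) <= k]
            if not peel:
                break
            for v in peel:
                core[v] = k
                for u in remaining[v]:
                    remaining[u].discard(v)
                del remaining[v]
        if remaining:
            k += 1
    return core
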