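"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written directly from first principles (plain Python
loops, no shared code with the package) so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math


def qg_brute(genotypes_x, genotypes_y, freqs) -> float | None:
    """Queller-Goodnight relatedness for one dyad, straight from the formula.

    ``genotypes_x``/``genotypes_y``: list per locus of (allele, allele) or
    None; ``freqs``: list per locus of {allele: frequency}.  Ratio of sums
    pooled over both directions and all mutually typed loci.
    """
    num = 0.0
    den = 0.0
    shared = 0
    for gx, gy, p in zip(genotypes_x, genotypes_y, freqs):
        if gx is None or gy is None:
            continue
        shared += 1
        for focal, partner in ((gx, gy), (gy, gx)):
            a, b = focal
            c, d = partner
            for allele in (a, b):
                share_partner = 0.5 * ((1.0 if c == allele else 0.0) + (1.0 if d == allele else 0.0))
                share_own = 0.5 * ((1.0 if a == allele else 0.0) + (1.0 if b == allele else 0.0))
                num += share_partner - p[allele]
                den += share_own - p[allele]
    if shared == 0 or abs(den) < 1e-12:
        return None
    return num / den


def betweenness_brute(nodes, edges) -> dict:
    """Normalised weighted betweenness by exhaustive simple-path enumeration.

    ``edges``: {(u, v): weight}; path length is the sum of 1/weight.  Each
    node's score sums, over ordered pairs (s, t) excluding it, the fraction
    of shortest s-t paths passing through it, divided by (n-1)(n-2)/2 for
    the undirected convention.
    """
    nodes = list(nodes)
    n = len(nodes)
    length = {}
    for (u, v), w in edges.items():
        length[(u, v)] = length[(v, u)] = 1.0 / w

    def all_paths(s, t):
        found = []
        others = [x for x in nodes if x not in (s, t)]
        for k in range(len(others) + 1):
            for mid in itertools.permutations(others, k):
                seq = (s, *mid, t)
                total = 0.0
                ok = True
                for a, b in zip(seq, seq[1:]):
                    if (a, b) not in length:
                        ok = False
                        break
                    total += length[(a, b)]
                if ok:
                    found.append((total, seq))
        return found

    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        best = min(total for total, _ in paths)
        shortest = [seq for total, seq in paths if total <= best * (1 + 1e-12) + 1e-12]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for seq in shortest if v in seq[1:-1])
            score[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2.0
    return {v: (score[v] / norm if norm > 0 else 0.0) for v in nodes}


def modularity_brute(edges, partition) -> float:
    """Weighted modularity Q = sum_c (e_cc - a_c^2) from edge-weight fractions."""
    total = sum(edges.values())
    group = {}
    for i, part in enumerate(partition):
        for v in part:
            group[v] = i
    k = len(partition)
    e = [[0.0] * k for _ in range(k)]
    for (u, v), w in edges.items():
        gu, gv = group[u], group[v]
        if gu == gv:
            e[gu][gu] += w / total
        else:
            e[gu][gv] += 0.5 * w / total
            e[gv][gu] += 0.5 * w / total
    q = 0.0
    for i in range(k):
        a_i = e[i][i] + sum(e[i][j] for j in range(k) if j != i)
        q += e[i][i] - a_i**2
    return q


def spearman_brute(x, y) -> float:
    """Spearman rho via average ranks and the Pearson formula, by hand."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for kk in range(i, j + 1):
                r[order[kk]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    vy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return cov / (vx * vy)


def bh_brute(pvals, alpha):
    """Benjamini-Hochberg flags by explicit step-up over the sorted p-values."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(indexed, start=1):
        if pvals[i] <= alpha * rank / m:
            k_star = rank
    flags = [False] * m
    for rank, i in enumerate(indexed, start=1):
        if rank <= k_star:
            flags[i] = True
    return flags


def signed_rank_exact_p(values, mu, alternative="greater"):
    """Exact one-sample signed-rank p by full 2^n sign enumeration (n small)."""
    d = [v - mu for v in values if v != mu]
    n = len(d)
    mags = sorted(abs(x) for x in d)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and mags[j + 1] == mags[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        ranks[mags[i]] = avg
        i = j + 1
    rank_list = [ranks[abs(x)] for x in d]
    v_obs = sum(r for x, r in zip(d, rank_list) if x > 0)
    count_ge = count_le = 0
    for signs in itertools.product((0, 1), repeat=n):
        v = sum(r for s, r in zip(signs, rank_list) if s)
        if v >= v_obs - 1e-12:
            count_ge += 1
        if v <= v_obs + 1e-12:
            count_le += 1
    total = 2**n
    if alternative == "greater":
        return v_obs, count_ge / total
    if alternative == "less":
        return v_obs, count_le / total
    return v_obs, min(1.0, 2 * min(count_ge, count_le) / total)
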