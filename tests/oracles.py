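"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written as straightforward loops, sharing
no code with the package, so that agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def ehh_pair_counting(alleles: np.ndarray, core: int, core_allele: int,
                      direction: str, truncation: float = 0.05) -> list[tuple[int, float]]:
    """EHH by exhaustive pair enumeration over carrier haplotypes."""
    carriers = [i for i in range(alleles.shape[0])
                if alleles[i, core] == core_allele]
    n_c = len(carriers)
    assert n_c >= 2
    n_pairs = n_c * (n_c - 1) // 2
    out = [(core, 1.0)]
    step = 1 if direction == "right" else -1
    j = core + step
    while 0 <= j < alleles.shape[1]:
        lo, hi = min(core, j), max(core, j)
        same = 0
        for a, b in itertools.combinations(carriers, 2):
            if np.array_equal(alleles[a, lo:hi + 1], alleles[b, lo:hi + 1]):
                same += 1
        val = same / n_pairs
        out.append((j, val))
        if val < truncation:
            break
        j += step
    return out


def trapezoid_ies(positions: np.ndarray, seqs) -> float:
    """Trapezoid area from one or more (site_index, ehh) sequences."""
    total = 0.0
    for seq in seqs:
        for (i1, e1), (i2, e2) in zip(seq, seq[1:]):
            total += abs(int(positions[i2]) - int(positions[i1])) * (e1 + e2) / 2
    return total


def window_merge(positions: list[int], slop: int) -> list[list[int]]:
    """O(n^2) transitive merge of +/- slop windows around each position."""
    positions = sorted(positions)
    n = len(positions)
    # adjacency: windows overlap or touch
    adj = [[abs(positions[i] - positions[j]) <= 2 * slop
            for j in range(n)] for i in range(n)]
    seen = [False] * n
    groups = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if adj[u][v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        groups.append(sorted(positions[u] for u in comp))
    groups.sort(key=lambda g: g[0])
    return groups


def size_factors_naive(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors by direct formula."""
    n_genes, n_samples = counts.shape
    ref = []
    usable = []
    for g in range(n_genes):
        if all(counts[g, j] > 0 for j in range(n_samples)):
            logs = [np.log(counts[g, j]) for j in range(n_samples)]
            ref.append(np.exp(sum(logs) / n_samples))
            usable.append(g)
    assert usable, "no all-positive gene"
    factors = []
    for j in range(n_samples):
        ratios = [counts[g, j] / ref[i] for i, g in enumerate(usable)]
        factors.append(float(np.median(ratios)))
    return np.array(factors)


def bh_naive(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def complete_linkage_labels(x: np.ndarray, k: int) -> np.ndarray:
    """O(n^3) agglomerative complete-linkage clustering cut at k clusters."""
    n = x.shape[0]
    clusters = [[i] for i in range(n)]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    while len(clusters) > k:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if dist < best[0]:
                    best = (dist, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters, start=1):
        for i in members:
            labels[i] = lab
    return labels


def xpehh_straightline(alleles_a: np.ndarray, alleles_b: np.ndarray,
                       positions: np.ndarray, truncation: float = 0.05):
    """Straight-line xpEHH raw values for tiny panels (no shared helpers).

    Returns (positions_scanned, raw_values); sites with < 2 carriers of
    allele 1 in either panel or zero area are skipped.
    """
    def area(alleles, core):
        carriers = [i for i in range(alleles.shape[0]) if alleles[i, core] == 1]
        if len(carriers) < 2:
            return None
        n_pairs = len(carriers) * (len(carriers) - 1) / 2
        total = 0.0
        for step in (-1, 1):
            prev_e, prev_j = 1.0, core
            j = core + step
            while 0 <= j < alleles.shape[1]:
                lo, hi = min(core, j), max(core, j)
                same = sum(
                    1 for a, b in itertools.combinations(carriers, 2)
                    if np.array_equal(alleles[a, lo:hi + 1],
                                      alleles[b, lo:hi + 1]))
                e = same / n_pairs
                total += abs(int(positions[j]) - int(positions[prev_j])) * (prev_e + e) / 2
                prev_e, prev_j = e, j
                if e < truncation:
                    break
                j += step
        return total

    pos_out, raw_out = [], []
    for core in range(alleles_a.shape[1]):
        ia = area(alleles_a, core)
        ib = area(alleles_b, core)
        if ia is None or ib is None or ia == 0 or ib == 0:
            continue
        pos_out.append(int(positions[core]))
        raw_out.append(np.log(ia / ib))
    return pos_out, raw_out
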