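"""Brute-force reference implementations, independent of the package's code.

Each oracle is written the slow, literal way -- explicit loops, sorted lists,
textbook formulas -- so that it shares no shortcuts with the implementation
it checks.
"""

from __future__ import annotations

import itertools
import math


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted values: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def midranks(values: list[float]) -> list[float]:
    """Average ranks (1-based), ties sharing the mean of their positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # mean of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman(x: list[float], y: list[float]) -> float:
    """Pearson correlation of mid-ranks, computed longhand."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def jaccard_matrix(sets: dict[str, set]) -> dict[tuple[str, str], float]:
    """Double-loop Jaccard over every ordered pair of labelled sets."""
    out = {}
    for a, sa in sets.items():
        for b, sb in sets.items():
            union = sa | sb
            out[(a, b)] = 1.0 if not union else len(sa & sb) / len(union)
    return out


def tmm_factor_pair(
    obs: list[float],
    ref: list[float],
    trim_logratio: float = 0.3,
    trim_abundance: float = 0.05,
) -> float:
    """One column's log2 TMM factor against a reference, straight from the
    published formula: gene-wise log ratios M and abundances A over genes
    expressed in both columns, double rank-trim, then the mean of the
    surviving M weighted by inverse delta-method variances."""
    n_obs, n_ref = sum(obs), sum(ref)
    ms, as_, ws = [], [], []
    for y, r in zip(obs, ref):
        if y > 0 and r > 0:
            ms.append(math.log2((y / n_obs) / (r / n_ref)))
            as_.append(0.5 * math.log2((y / n_obs) * (r / n_ref)))
            ws.append((n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r))
    n = len(ms)
    rank_m = midranks(ms)
    rank_a = midranks(as_)
    lo_m = math.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_abundance) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for m, rm, ra, w in zip(ms, rank_m, rank_a, ws):
        if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
            num += m / w
            den += 1.0 / w
    f = num / den
    return 0.0 if abs(f) < 1e-6 else f


def complete_linkage_merges(
    dist: dict[tuple[str, str], float], labels: list[str]
) -> list[tuple[str, str, float]]:
    """Merge history of complete-linkage clustering via frozensets.

    Same tie-break contract as the implementation (lexicographic on the pair
    of smallest member labels), arrived at through an entirely different
    bookkeeping: clusters as frozensets in a set, distances recomputed from
    scratch each round with itertools.
    """
    clusters = {frozenset([lab]) for lab in labels}
    merges = []
    while len(clusters) > 1:
        candidates = []
        for ca, cb in itertools.combinations(sorted(clusters, key=lambda c: min(c)), 2):
            d = max(dist[(x, y)] for x in ca for y in cb)
            candidates.append((d, tuple(sorted((min(ca), min(cb)))), ca, cb))
        d, pair, ca, cb = min(candidates, key=lambda t: t[:2])
        merges.append((pair[0], pair[1], d))
        clusters.remove(ca)
        clusters.remove(cb)
        clusters.add(ca | cb)
    return merges
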