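"""Independent brute-force oracles the tests compare the package against.

Deliberately naive: plain nested loops and textbook formulas, sharing no
code path with the implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2 as chi2_dist


def rc_matrix_bruteforce(genes, repeats, window_bp, classes=None):
    """Direct O(n*m) interval scan + log10(Nr*Lr/Le) recomputation.

    Returns (rows, floor) where rows maps gene_id -> {class: RC} for genes
    with at least one hit among the analyzed classes.
    """
    floor = math.log10(1.0 / (2 * window_bp))
    rows = {}
    for g in genes:
        if g.strand == "+":
            ps, pe = g.tss - window_bp, g.tss
        else:
            ps, pe = g.tss + 1, g.tss + 1 + window_bp
        ps = max(ps, 0)
        counts: dict[str, int] = {}
        lengths: dict[str, int] = {}
        for r in repeats:
            if classes is not None and r.repeat_class not in classes:
                continue
            if r.contig != g.contig:
                continue
            lo, hi = max(ps, r.start), min(pe, r.end)
            if hi > lo:
                counts[r.repeat_class] = counts.get(r.repeat_class, 0) + 1
                lengths[r.repeat_class] = lengths.get(r.repeat_class, 0) + (hi - lo)
        if counts:
            rows[g.gene_id] = {
                c: math.log10(counts[c] * lengths[c] / window_bp) for c in counts
            }
    return rows, floor


def complete_linkage_merge_heights(dist: np.ndarray) -> list[float]:
    """Naive complete-linkage agglomeration; returns the n-1 merge heights."""
    clusters = {i: {i} for i in range(len(dist))}
    heights = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, i in enumerate(keys):
            for j in keys[ai + 1:]:
                h = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(float(h))
        clusters[i] |= clusters.pop(j)
    return heights


def km_product_limit(times, events):
    """Hand product-limit: returns (event_times, survival) at observed events."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_bruteforce(times, events, in_group_a):
    """Two-group log-rank over pooled event times with hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    in_group_a = np.asarray(in_group_a, dtype=bool)
    observed = expected = variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n, na = int(at_risk.sum()), int((at_risk & in_group_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        da = int(((times == t) & (events == 1) & in_group_a).sum())
        observed += da
        expected += d * na / n
        if n > 1:
            variance += d * (n - d) * na * (n - na) / (n * n * (n - 1))
    statistic = (observed - expected) ** 2 / variance
    return statistic, float(chi2_dist.sf(statistic, 1))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI from the contingency table, written out from its definition."""
    a_vals = {v: i for i, v in enumerate(dict.fromkeys(labels_a))}
    b_vals = {v: i for i, v in enumerate(dict.fromkeys(labels_b))}
    table = np.zeros((len(a_vals), len(b_vals)), dtype=np.int64)
    for x, y in zip(labels_a, labels_b):
        table[a_vals[x], b_vals[y]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = sum(comb2(n) for n in table.ravel())
    sum_a = sum(comb2(n) for n in table.sum(axis=1))
    sum_b = sum(comb2(n) for n in table.sum(axis=0))
    total = comb2(table.sum())
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)
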