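"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration) and shares no code with the package, so agreement between
package output and these references is meaningful evidence.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_merge(intervals, max_gap):
    """Union-with-gap by repeated pairwise scanning.

    ``intervals`` is a list of (start, end) on one chrom/strand; returns
    the sorted list of merged (start, end, support) where support is the
    number of input intervals absorbed.
    """
    groups = [[iv] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                si = min(s for s, _ in gi)
                ei = max(e for _, e in gi)
                sj = min(s for s, _ in gj)
                ej = max(e for _, e in gj)
                gap = max(si, sj) - min(ei, ej)
                if gap <= max_gap:
                    groups[i] = gi + gj
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    out = []
    for g in groups:
        out.append((min(s for s, _ in g), max(e for _, e in g), len(g)))
    return sorted(out)


def brute_intersect(query, subject, strandedness="ignore"):
    """All-vs-all overlap pairs.  query/subject: lists of
    (chrom, start, end, strand); returns {(qi, si): width}."""
    out = {}
    for qi, (qc, qs, qe, qstr) in enumerate(query):
        for si, (sc, ss, se, sstr) in enumerate(subject):
            if qc != sc or not (qs < se and ss < qe):
                continue
            if strandedness == "same" and qstr != sstr:
                continue
            if strandedness == "opposite" and qstr == sstr:
                continue
            out[(qi, si)] = min(qe, se) - max(qs, ss)
    return out


def brute_count(features, reads, policy="all"):
    """Per-feature overlap counts by all-pairs scanning."""
    counts = [0] * len(features)
    for (rc, rs, re_, rstr) in reads:
        hits = [fi for fi, (fc, fs, fe, fstr) in enumerate(features)
                if fc == rc and fs < re_ and rs < fe]
        if policy == "unique" and len(hits) != 1:
            continue
        for fi in hits:
            counts[fi] += 1
    return counts


def brute_complete_linkage(points):
    """Exhaustive complete-linkage agglomeration.

    Returns the merge sequence [(frozenset_a, frozenset_b, height), ...]
    merging the lowest-index pair on exact ties.
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    points = np.asarray(points, dtype=float)

    def cdist(a, b):
        return max(np.linalg.norm(points[i] - points[j])
                   for i in a for j in b)

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def brute_nb_exact(k_a, k_b, s_a, s_b, s2_a, s2_b, alpha):
    """Exact conditional NB test by direct probability enumeration."""
    K = k_a + k_b
    if K == 0:
        return 1.0
    q = K / (s_a + s_b)

    def pmf(k, s_sum, s2_sum):
        mu = q * s_sum
        var = mu + alpha * q * q * s2_sum
        if var <= mu:
            return stats.poisson.pmf(k, mu)
        size = mu * mu / (var - mu)
        return stats.nbinom.pmf(k, size, size / (size + mu))

    ps = np.array([pmf(a, s_a, s2_a) * pmf(K - a, s_b, s2_b)
                   for a in range(K + 1)])
    return float(ps[ps <= ps[k_a]].sum() / ps.sum())


def brute_bh(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def binomial_ci(p, n, level=0.99):
    """Two-sided normal-approximation binomial CI for a proportion."""
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
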