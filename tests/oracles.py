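"""Naive reference implementations used as independent oracles.

Every function here is a direct, unoptimized transcription of the
corresponding rule: nested loops, no vectorization, recomputation from
scratch at every step.  They must stay independent of the package's
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_r2(x, y) -> float:
    """Plain pairwise-complete squared Pearson correlation."""
    pairs = [(a, b) for a, b in zip(x, y)
             if not (math.isnan(a) or math.isnan(b))]
    if len(pairs) < 3:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    if sxx == 0 or syy == 0:
        return float("nan")
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    return sxy * sxy / (sxx * syy)


def density_keep(positions, chroms, window_bp, min_other) -> list[bool]:
    """SNP kept iff strictly more than min_other OTHER significant SNPs lie
    within +/- window_bp/2 on the same chromosome."""
    half = window_bp / 2.0
    keep = []
    for i, (p, c) in enumerate(zip(positions, chroms)):
        n = 0
        for j, (q, d) in enumerate(zip(positions, chroms)):
            if i != j and c == d and abs(p - q) <= half:
                n += 1
        keep.append(n > min_other)
    return keep


def cluster_ids(positions, chroms, gap_bp) -> list[int]:
    """Cluster id per SNP: union of <= gap_bp adjacency along sorted input."""
    ids = []
    cid = -1
    for i, (p, c) in enumerate(zip(positions, chroms)):
        if i == 0 or c != chroms[i - 1] or p - positions[i - 1] > gap_bp:
            cid += 1
        ids.append(cid)
    return ids


def representative(members) -> str:
    """members: list of (snp_id, pos, p); argmin p, ties smaller pos then id."""
    return min(members, key=lambda m: (m[2], m[1], m[0]))[0]


def dedup_greedy(reps, dosage_by_id, r2_min) -> list[str]:
    """reps: list of (snp_id, pos, p).  Greedy by increasing p (ties: pos,
    id); accept a representative only if r^2 < r2_min with every accepted."""
    order = sorted(reps, key=lambda m: (m[2], m[1], m[0]))
    accepted = []
    for snp_id, _, _ in order:
        ok = True
        for prev in accepted:
            r2 = pearson_r2(dosage_by_id[snp_id], dosage_by_id[prev])
            if not math.isnan(r2) and r2 >= r2_min:
                ok = False
                break
        if ok:
            accepted.append(snp_id)
    return accepted


def prune_windowed(dosage, positions, mafs, window, step, r2_max) -> list[int]:
    """Windowed pruning: returns surviving column indices.

    Windows of `window` SNPs over the original order, advancing by `step`.
    Within a window, repeatedly find the first pair (scanned in position
    order) with r^2 > r2_max and remove its lower-MAF member (ties: larger
    position).
    """
    n = dosage.shape[1]
    removed = set()
    w_start = 0
    while True:
        idx = [i for i in range(w_start, min(w_start + window, n))
               if i not in removed]
        changed = True
        while changed:
            changed = False
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = idx[a], idx[b]
                    if i in removed or j in removed:
                        continue
                    r2 = pearson_r2(dosage[:, i], dosage[:, j])
                    if not math.isnan(r2) and r2 > r2_max:
                        if (mafs[i], -positions[i]) < (mafs[j], -positions[j]):
                            removed.add(i)
                        else:
                            removed.add(j)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                idx = [i for i in idx if i not in removed]
        if w_start + window >= n:
            break
        w_start += step
    return [i for i in range(n) if i not in removed]


def fisher_two_sided(a, b, c, d) -> float:
    """Exact two-sided hypergeometric p by full enumeration (point
    probability rule: sum over tables with probability <= observed)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_comb(nn, kk):
        return (math.lgamma(nn + 1) - math.lgamma(kk + 1)
                - math.lgamma(nn - kk + 1))

    def prob(x):
        # P(X = x) for X ~ Hypergeometric(n, col1, row1)
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0.0
        return math.exp(log_comb(row1, x) + log_comb(row2, col1 - x)
                        - log_comb(n, col1))

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def interval_membership(pos_1based, chrom, intervals) -> bool:
    """intervals: list of (chrom, start, end) 0-based half-open."""
    p0 = pos_1based - 1
    return any(c == chrom and s <= p0 < e for c, s, e in intervals)


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up, written longhand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
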