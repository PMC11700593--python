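"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its literal definition
with plain Python loops, sharing no code path with the package.
"""
from __future__ import annotations

import itertools

import numpy as np


def brute_roh(pos, dos, params):
    """Literal window-vote ROH caller. Returns (start, end, n_snps, n_het)."""
    pos = list(map(int, pos))
    dos = list(map(int, dos))
    n = len(pos)
    w = params.window_snps
    if n < w:
        return []
    accepted = []
    for s in range(n - w + 1):
        win = dos[s:s + w]
        n_het = sum(1 for x in win if x == 1)
        n_mis = sum(1 for x in win if x == -1)
        accepted.append(
            n_het <= params.window_het_max and n_mis <= params.window_missing_max
        )
    eligible = []
    for k in range(n):
        lo = max(0, k - w + 1)
        hi = min(k, n - w)
        hits = sum(1 for x in range(lo, hi + 1) if accepted[x])
        eligible.append(hits / (hi - lo + 1) >= params.hit_threshold)
    runs = []
    start = None
    for i in range(n + 1):
        in_run = i < n and eligible[i]
        if in_run and start is not None and pos[i] - pos[i - 1] > params.gap_kb * 1000:
            runs.append((start, i - 1))
            start = i
        elif in_run and start is None:
            start = i
        elif not in_run and start is not None:
            runs.append((start, i - 1))
            start = None
    out = []
    for a, b in runs:
        length = pos[b] - pos[a] + 1
        n_snps = b - a + 1
        if length < params.min_kb * 1000:
            continue
        if n_snps < params.min_snps:
            continue
        if length / n_snps > params.max_kb_per_snp * 1000:
            continue
        out.append(
            (pos[a], pos[b], n_snps, sum(1 for x in dos[a:b + 1] if x == 1))
        )
    return out


def brute_site_pi(alleles):
    """Fraction of differing pairs among an explicit allele list."""
    n = len(alleles)
    diff = pairs = 0
    for x in range(n):
        for y in range(x + 1, n):
            pairs += 1
            if alleles[x] != alleles[y]:
                diff += 1
    return diff / pairs if pairs else 0.0


def brute_window_pi(site_allele_lists, window_bp):
    """Sum of per-site pairwise diversity over a window / window length."""
    return sum(brute_site_pi(a) for a in site_allele_lists) / window_bp


def mwu_exact_pairwise(a, b):
    """Exact two-tailed rank-test p with U from direct pairwise comparisons
    (wins + half-ties), enumerating all group assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n = len(a)

    def ustat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = ustat(a, b)
    le = ge = total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n):
        s = set(combo)
        ga = [pooled[k] for k in combo]
        gb = [pooled[k] for k in idx if k not in s]
        u = ustat(ga, gb)
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def brute_pair_counts(a, b):
    """Naive IBS0/het counts over pairwise-complete sites."""
    ibs0 = hethet = het_i = het_j = n = 0
    for x, y in zip(a, b):
        if x < 0 or y < 0:
            continue
        n += 1
        if (x == 0 and y == 2) or (x == 2 and y == 0):
            ibs0 += 1
        if x == 1 and y == 1:
            hethet += 1
        if x == 1:
            het_i += 1
        if y == 1:
            het_j += 1
    return n, ibs0, hethet, het_i, het_j


def brute_load_recount(dosage_col, retained, categories):
    """Naive masked/realized recount for one sample over retained sites."""
    out = {}
    for cat in ("LOW", "MOD-TOL", "MOD-DEL", "HIGH"):
        masked = realized = callable_n = 0
        for k in range(len(dosage_col)):
            if not retained[k] or categories[k] != cat:
                continue
            d = int(dosage_col[k])
            if d < 0:
                continue
            callable_n += 1
            if d == 1:
                masked += 1
            elif d == 2:
                realized += 1
        out[cat] = (masked, realized, masked + realized, callable_n)
    return out
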