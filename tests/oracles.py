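"""Independent straight-line oracles used to cross-check the package.

Everything here is deliberately naive (explicit loops, no vectorisation)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats


def naive_bh(p):
    """Benjamini–Hochberg step-up by direct definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = min(val, 1.0)
        prev = val
    return q


def brute_force_es(scores, member_flags, exponent):
    """Running-sum ES by walking the full list one gene at a time."""
    n = len(scores)
    n_hit = sum(member_flags)
    denom = sum(abs(scores[i]) ** exponent for i in range(n) if member_flags[i])
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for i in range(n):
        if member_flags[i]:
            if denom == 0:
                running += 1.0 / n_hit
            else:
                running += abs(scores[i]) ** exponent / denom
        else:
            running -= 1.0 / (n - n_hit)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg else best_neg


def ks_oracle(tag_ranks, n):
    """Connectivity KS statistic by looping over every step position."""
    v = sorted(tag_ranks)
    t = len(v)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def naive_tmm_pair(obs, ref, n_obs, n_ref, trim_m=0.30, trim_a=0.05):
    """Weighted trimmed mean of M-values, computed gene by gene."""
    triples = []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m = math.log2((o / n_obs) / (r / n_ref))
            a = 0.5 * math.log2((o / n_obs) * (r / n_ref))
            w = 1.0 / (1.0 / o - 1.0 / n_obs + 1.0 / r - 1.0 / n_ref)
            triples.append((m, a, w))
    n = len(triples)
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    ms = sorted(range(n), key=lambda i: triples[i][0])
    as_ = sorted(range(n), key=lambda i: triples[i][1])
    rank_m = {idx: k + 1 for k, idx in enumerate(ms)}
    rank_a = {idx: k + 1 for k, idx in enumerate(as_)}
    num = den = 0.0
    for i, (m, a, w) in enumerate(triples):
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
            num += w * m
            den += w
    return num / den


def _trigamma_inv_oracle(y):
    x = 0.5 + 1.0 / y
    for _ in range(200):
        step = (special.polygamma(1, x) - y) / special.polygamma(2, x)
        x -= step
        if abs(step) < 1e-13:
            break
    return x


def straight_line_moderated_t(x, ctrl_idx, trt_idx):
    """Per-gene two-group fit + EB shrinkage, written as explicit loops.

    Returns dict with logFC, s2, t, p, d0, s0_2 (lists / floats).
    """
    n_genes = x.shape[0]
    n1, n2 = len(ctrl_idx), len(trt_idx)
    df = n1 + n2 - 2
    logfc, s2 = [], []
    for g in range(n_genes):
        mc = sum(x[g, i] for i in ctrl_idx) / n1
        mt = sum(x[g, i] for i in trt_idx) / n2
        rss = sum((x[g, i] - mc) ** 2 for i in ctrl_idx) + \
              sum((x[g, i] - mt) ** 2 for i in trt_idx)
        logfc.append(mt - mc)
        s2.append(rss / df)
    e = [math.log(v) - special.digamma(df / 2) + math.log(df / 2)
         for v in s2 if v > 0]
    e_mean = sum(e) / len(e)
    e_var = sum((v - e_mean) ** 2 for v in e) / (len(e) - 1) - special.polygamma(1, df / 2)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inv_oracle(e_var)
        s0_2 = math.exp(e_mean + special.digamma(d0 / 2) - math.log(d0 / 2))
    else:
        d0 = math.inf
        s0_2 = math.exp(e_mean)
    c = 1.0 / n1 + 1.0 / n2
    t, p = [], []
    for g in range(n_genes):
        if math.isinf(d0):
            post = s0_2
        else:
            post = (d0 * s0_2 + df * s2[g]) / (d0 + df)
        tg = logfc[g] / math.sqrt(post * c)
        t.append(tg)
        if math.isinf(d0):
            pg = 2 * stats.norm.sf(abs(tg))
        else:
            pg = 2 * stats.t.sf(abs(tg), d0 + df)
        p.append(pg)
    return {"logFC": logfc, "s2": s2, "t": t, "p": p, "d0": d0, "s0_2": s0_2}


def venn_regions_brute(groups):
    """Region counts by enumerating every pathway's exact membership pattern."""
    union = set()
    for s in groups.values():
        union |= s
    counts = {}
    for pathway in union:
        member = tuple(sorted(g for g, s in groups.items() if pathway in s))
        counts[member] = counts.get(member, 0) + 1
    return counts
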