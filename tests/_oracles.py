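"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python loops and
per-iteration re-sorting, so they can serve as oracles for the vectorized
and pointer-based paths they check.
"""

from __future__ import annotations

import math


def pearson_r2_oracle(x, y):
    """Textbook Pearson r² over pairwise-complete entries; None if undefined."""
    pairs = [(a, b) for a, b in zip(x, y)
             if a is not None and b is not None
             and not (isinstance(a, float) and math.isnan(a))
             and not (isinstance(b, float) and math.isnan(b))]
    n = len(pairs)
    if n < 2:
        return None
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    if sxx <= 0 or syy <= 0:
        return None
    return (sxy * sxy) / (sxx * syy)


def concordance_oracle(g1, g2, include_het=True):
    num = den = 0
    for a, b in zip(g1, g2):
        if a is None or b is None:
            continue
        if isinstance(a, float) and math.isnan(a):
            continue
        if isinstance(b, float) and math.isnan(b):
            continue
        if not include_het and (a == 1 or b == 1):
            continue
        den += 1
        if a == b:
            num += 1
    return num / den if den else None


def corr2_oracle(g1, g2, include_het=True):
    xs, ys = [], []
    for a, b in zip(g1, g2):
        if a is None or b is None:
            continue
        if isinstance(a, float) and math.isnan(a):
            continue
        if isinstance(b, float) and math.isnan(b):
            continue
        if not include_het and (a == 1 or b == 1):
            continue
        xs.append(a)
        ys.append(b)
    return pearson_r2_oracle(xs, ys)


def wc_theta_oracle(genos1, genos2):
    """Two-population Weir-Cockerham theta from genotype lists (0/1/2/None).

    Scalar transcription of the 1984 variance-component estimator for
    r = 2 populations: a (among populations), b (among individuals within
    populations), c (within individuals); theta = a / (a + b + c).
    """
    def group_stats(genos):
        called = [g for g in genos if g is not None]
        n = len(called)
        if n < 2:
            return None
        p = sum(called) / (2.0 * n)
        h = sum(1 for g in called if g == 1) / n
        return n, p, h

    s1, s2 = group_stats(genos1), group_stats(genos2)
    if s1 is None or s2 is None:
        return None
    (n1, p1, h1), (n2, p2, h2) = s1, s2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2v = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2v - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2v - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2v
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


def greedy_trace_oracle(tag_sets, F, m, tiers, r2_lookup, locus):
    """Brute-force greedy selection that re-sorts every iteration.

    Parameters
    ----------
    tag_sets : dict focal -> frozenset of members (focal included)
    F : set of eligible focal/member SNPs
    m : minimum set size
    tiers : sequence of (min_size, total_tags), descending thresholds
    r2_lookup : dict frozenset({a, b}) -> r2
    locus : dict snp -> (chromosome, position) for tie-breaking

    Returns the ordered list of (snp_id, category, tag_set_id).
    """
    remaining = dict(tag_sets)
    chosen = []
    chosen_ids = set()
    while True:
        eligible = [f for f in remaining if f in F and len(remaining[f]) >= m]
        if not eligible:
            break
        head = sorted(
            eligible,
            key=lambda f: (-len(remaining[f]), locus[f][0], locus[f][1], f),
        )[0]
        T = remaining[head]
        chosen.append((head, "tag_strict", head))
        chosen_ids.add(head)
        n_total = 1
        for threshold, n in tiers:
            if len(T) >= threshold:
                n_total = n
                break
        extras = [
            s for s in T
            if s != head and s in F and s not in chosen_ids
        ]
        extras.sort(
            key=lambda s: (-r2_lookup.get(frozenset((head, s)), 0.0),
                           locus[s][1], s)
        )
        for s in extras[: n_total - 1]:
            chosen.append((s, "tag_redundant", head))
            chosen_ids.add(s)
        remaining = {f: S for f, S in remaining.items() if not (S & T)}
    return chosen
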