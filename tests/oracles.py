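"""Independent brute-force reference implementations.

Deliberately naive (loops, Fractions, full enumeration) and written
directly from the defining formulas so they share no code path with the
package.
"""

from fractions import Fraction
from math import comb, log, sqrt

import numpy as np


def hwe_enum_p(n_AA, n_Aa, n_aa):
    """Exact HWE p by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa

    def weight(het):
        hom_A = (nA - het) // 2
        hom_a = n - het - hom_A
        if hom_A < 0 or hom_a < 0 or (nA - het) % 2:
            return Fraction(0)
        # multinomial count of genotype assignments x 2^het orderings
        return Fraction(
            comb(n, het) * comb(n - het, hom_A) * 2**het
        )

    total = sum(weight(h) for h in range(n + 1))
    probs = {h: weight(h) / total for h in range(n + 1) if weight(h) > 0}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def site_pi_value(column):
    """Mean pairwise difference at one site, naive double loop."""
    alleles = [a for a in column if a >= 0]
    n = len(alleles)
    if n < 2:
        return np.nan
    diff = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diff += alleles[i] != alleles[j]
    return diff / pairs


def tajimas_d_value(matrix):
    """Tajima's D for one bin of sites (rows = haplotypes), from the
    defining formula with naive pairwise differences."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    S = 0
    for col in matrix.T:
        vals = set(int(a) for a in col if a >= 0)
        if len(vals) > 1:
            S += 1
    if S == 0:
        return 0.0
    pi_hat = 0.0
    for col in matrix.T:
        v = site_pi_value(col)
        if not np.isnan(v):
            pi_hat += v
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_hat - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def h1_h12_values(window):
    """H1/H12 from one window (rows = haplotypes), dict counting."""
    counts = {}
    for row in np.asarray(window):
        if (row < 0).any():
            continue
        key = tuple(int(a) for a in row)
        counts[key] = counts.get(key, 0) + 1
    tot = sum(counts.values())
    freqs = sorted((c / tot for c in counts.values()), reverse=True)
    h1 = sum(f * f for f in freqs)
    top2 = sum(freqs[:2])
    h12 = top2 * top2 + sum(f * f for f in freqs[2:])
    return h1, h12


def wc_fst_value(g1, g2):
    """Weir-Cockerham theta for one SNP from two genotype vectors
    (dosages 0/1/2, -1 missing); direct transcription of the variance
    components for r = 2 diploid populations."""
    pops = []
    for g in (g1, g2):
        g = [x for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        pops.append((n, p, h))
    r = 2
    nbar = sum(n for n, _, _ in pops) / r
    nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r
        - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    if a + b + c == 0:
        return np.nan
    return a / (a + b + c)


def fractional_rank_p(values, tail):
    """Rank p-values by explicit counting (ties averaged)."""
    values = list(values)
    n = len(values)
    out = []
    for v in values:
        less = sum(1 for x in values if x < v)
        equal = sum(1 for x in values if x == v)
        rank = less + (equal + 1) / 2
        left = rank / (n + 1)
        right = (n + 1 - rank) / (n + 1)
        if tail == "left":
            out.append(left)
        elif tail == "right":
            out.append(right)
        else:
            out.append(min(2 * min(left, right), n / (n + 1)))
    return np.array(out)


def bh_qvalues(pvals):
    """Benjamini-Hochberg step-up, literal definition."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return np.array(q)


def running_median_constant(x, k):
    """Centered running median with constant end rule, naive loops."""
    x = [0.0 if (v != v) else float(v) for v in x]
    L = len(x)
    if L == 0:
        return np.array(x)
    kk = min(k, L if L % 2 else L - 1)
    if kk < 3:
        return np.array(x)
    h = kk // 2
    med = [float(np.median(x[i - h:i + h + 1])) for i in range(h, L - h)]
    return np.array([med[0]] * h + med + [med[-1]] * h)


def overlaps_bruteforce(regions, features):
    """O(n*m) double loop interval intersection (1-based inclusive)."""
    out = {}
    for i, r in enumerate(regions):
        hits = []
        for f in features:
            if f.chrom == r.chrom and f.start <= r.end_pos and r.start_pos <= f.end:
                hits.append(f)
        out[i] = sorted(hits, key=lambda f: (f.chrom, f.start, f.name))
    return out
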