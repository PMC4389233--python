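"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: interval algebra is
checked against per-base bitmaps on a toy chromosome, the NB exact test
against an lgamma-based enumeration over all splits of the pooled total, and
the hypergeometric/binomial tails against combinatorial enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from ernaflow.intervals import GenomicInterval

TOY_CHROM_BP = 100_000


def bitmap(intervals, chroms=("chrA", "chrB"), size=TOY_CHROM_BP):
    """Per-base occupancy bitmaps, one per toy chromosome."""
    maps = {c: np.zeros(size, dtype=bool) for c in chroms}
    for iv in intervals:
        maps[iv.chrom][iv.start : iv.end] = True
    return maps


def bitmap_to_intervals(maps):
    """Maximal runs of covered bases -> sorted disjoint intervals."""
    out = []
    for chrom in sorted(maps):
        m = maps[chrom]
        padded = np.concatenate([[False], m, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def nb_logpmf(k: int, mean: float, size: float) -> float:
    """log NB(mean, size) pmf via lgamma (no scipy)."""
    if mean == 0.0:
        return 0.0 if k == 0 else -math.inf
    p = size / (size + mean)
    return (
        math.lgamma(k + size)
        - math.lgamma(size)
        - math.lgamma(k + 1)
        + size * math.log(p)
        + k * math.log1p(-p)
    )


def poisson_logpmf(k: int, mean: float) -> float:
    if mean == 0.0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(mean) - mean - math.lgamma(k + 1)


def exact_test_enumeration(
    counts_a, counts_b, libs_a, libs_b, dispersion: float
) -> float:
    """Enumerate every split of the pooled (scaled, rounded) total and sum
    the conditional probabilities of splits no more likely than observed."""
    libs = list(libs_a) + list(libs_b)
    common = math.exp(sum(math.log(x) for x in libs) / len(libs))
    s_a = round(sum(c * common / l for c, l in zip(counts_a, libs_a)))
    s_b = round(sum(c * common / l for c, l in zip(counts_b, libs_b)))
    total = s_a + s_b
    if total == 0:
        return 1.0
    n_a, n_b = len(counts_a), len(counts_b)
    mean = total / (n_a + n_b)
    logp = []
    for k in range(total + 1):
        if dispersion == 0.0:
            la = poisson_logpmf(k, n_a * mean)
            lb = poisson_logpmf(total - k, n_b * mean)
        else:
            la = nb_logpmf(k, n_a * mean, n_a / dispersion)
            lb = nb_logpmf(total - k, n_b * mean, n_b / dispersion)
        logp.append(la + lb)
    mx = max(logp)
    probs = [math.exp(v - mx) for v in logp]
    z = sum(probs)
    cond = [p / z for p in probs]
    p_obs = cond[s_a]
    return min(1.0, sum(p for p in cond if p <= p_obs * (1 + 1e-12)))


def hypergeom_upper_tail_enumeration(pop: int, successes: int, draws: int, k: int) -> float:
    """P(X >= k) by enumerating all draw subsets of a small population."""
    items = [1] * successes + [0] * (pop - successes)
    hits = total = 0
    for combo in combinations(range(pop), draws):
        total += 1
        if sum(items[i] for i in combo) >= k:
            hits += 1
    return hits / total


def binom_upper_tail_enumeration(n: int, p: float, k: int) -> float:
    """P(X >= k) by enumerating all 2^n outcome vectors (n <= 12)."""
    prob = 0.0
    for mask in range(2**n):
        ones = bin(mask).count("1")
        if ones >= k:
            prob += p**ones * (1 - p) ** (n - ones)
    return prob


def pearson_chi2_rc(table: np.ndarray) -> float:
    """Generic r x c Pearson chi-square statistic."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
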