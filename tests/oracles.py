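"""Independent brute-force oracles, deliberately coded apart from the
production (vectorized) implementations.

Everything here works on plain Python scalars and explicit loops so that a
numerical agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def brute_site_pi(alleles: list[int]) -> float:
    """Average pairwise difference over all C(n,2) allele pairs."""
    pairs = list(combinations(alleles, 2))
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def brute_wc_site(pop1: list[int], pop2: list[int]):
    """Weir & Cockerham (1984) a, b, c for one biallelic site, two diploid
    populations given as per-individual alt-allele dosages (missing
    excluded by the caller). Returns None when either population has fewer
    than two called individuals.
    """
    r = 2
    pops = [pop1, pop2]
    n = [len(p) for p in pops]
    if min(n) < 2:
        return None
    p = [sum(pop) / (2.0 * len(pop)) for pop in pops]
    h = [sum(1 for g in pop if g == 1) / len(pop) for pop in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def brute_windowed_fst(sites: list[tuple[list[int], list[int]]]) -> float:
    """Ratio-of-sums theta-hat over per-site (pop1, pop2) dosage lists."""
    num = den = 0.0
    for pop1, pop2 in sites:
        abc = brute_wc_site(pop1, pop2)
        if abc is None:
            continue
        a, b, c = abc
        num += a
        den += a + b + c
    return num / den


def brute_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail mass by direct summation of the pmf."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )


def brute_bh(pvals: list[float]) -> list[float]:
    """Step-up BH by the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj
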