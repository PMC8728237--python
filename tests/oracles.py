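"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) of the package
implementation: exact rational arithmetic for the distribution tails,
bitmask enumeration of hypergeometric draws, and a naive column-by-column
enumeration of all admissible duplex structures.
"""

from fractions import Fraction
from math import comb

PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def exact_binomial_tail(k: int, n: int, L: int, l: int) -> Fraction:
    """Sum_{x=k..n} C(n,x) p^x (1-p)^(n-x) with p = 1/(L-l+1), exact."""
    p = Fraction(1, L - l + 1)
    return sum(
        (comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1)),
        start=Fraction(0),
    )


def exact_binomial_tails_all_k(n: int, L: int, l: int) -> list:
    """Exact upper tails for every k in 0..n (suffix sums of the pmf)."""
    p = Fraction(1, L - l + 1)
    pmf = [comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(n + 1)]
    tails = [Fraction(0)] * (n + 2)
    for x in range(n, -1, -1):
        tails[x] = tails[x + 1] + pmf[x]
    return tails[: n + 1]


def exact_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Sum_{i=k..min(K,n)} C(K,i) C(N-K,n-i) / C(N,n), exact."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


def hypergeom_tails_by_enumeration(N: int, K: int):
    """counts[n][k] = number of n-subsets of [0,N) overlapping the first K
    elements in exactly k positions, by full 2^N draw enumeration."""
    kmask = (1 << K) - 1
    counts = [[0] * (N + 1) for _ in range(N + 1)]
    for mask in range(1 << N):
        n = mask.bit_count()
        k = (mask & kmask).bit_count()
        counts[n][k] += 1
    return counts


def brute_force_duplex(ts, tg, max_mismatch=2, max_bulge_tsrna=2,
                       max_bulge_target=2, seed_span=(2, 7), energy_cutoff=-10.0):
    """Exhaustive enumeration of every admissible duplex structure.

    Returns the minimising (score, -n_pairs, target site start) key, or None
    if no structure scores at or below the cutoff. Structures are anchored
    on a contiguous fully paired seed helix and extended column by column
    (pair / mismatch / tsRNA bulge / target bulge), terminal columns pairs.
    """
    ts = ts.upper().replace("U", "T")
    tg = tg.upper().replace("U", "T")
    s0, s1 = seed_span
    w = s1 - s0 + 1
    n, m = len(ts), len(tg)
    if n < s1 + 1 or n < 8:
        return None
    candidates = []

    def right(i, jr, mm, bt, bg, score, pairs):
        candidates.append((score, -len(pairs), min(j for _, j in pairs)))
        if i <= n and jr >= 1:
            wgt = PAIR_WEIGHT.get((ts[i - 1], tg[jr - 1]))
            if wgt is not None:
                right(i + 1, jr - 1, mm, bt, bg, score - wgt, pairs + [(i, jr)])
            if mm < max_mismatch:
                advance(i + 1, jr - 1, mm + 1, bt, bg, score + 1, pairs)
        if i <= n and bt < max_bulge_tsrna:
            advance(i + 1, jr, mm, bt + 1, bg, score + 1, pairs)
        if jr >= 1 and bg < max_bulge_target:
            advance(i, jr - 1, mm, bt, bg + 1, score + 1, pairs)

    def advance(i, jr, mm, bt, bg, score, pairs):
        # last column was not a pair: keep extending, no candidate recorded
        if i <= n and jr >= 1:
            wgt = PAIR_WEIGHT.get((ts[i - 1], tg[jr - 1]))
            if wgt is not None:
                right(i + 1, jr - 1, mm, bt, bg, score - wgt, pairs + [(i, jr)])
            if mm < max_mismatch:
                advance(i + 1, jr - 1, mm + 1, bt, bg, score + 1, pairs)
        if i <= n and bt < max_bulge_tsrna:
            advance(i + 1, jr, mm, bt + 1, bg, score + 1, pairs)
        if jr >= 1 and bg < max_bulge_target:
            advance(i, jr - 1, mm, bt, bg + 1, score + 1, pairs)

    def lefts(j_anchor):
        out = [(0, 0.0, [], 0, 0, 0)]

        def lrec(i, jl, mm, bt, bg, dscore, pairs, last_pair):
            if last_pair and pairs:
                out.append((len(pairs), dscore, list(pairs), mm, bt, bg))
            if i >= 1 and jl <= m:
                wgt = PAIR_WEIGHT.get((ts[i - 1], tg[jl - 1]))
                if wgt is not None:
                    lrec(i - 1, jl + 1, mm, bt, bg, dscore - wgt,
                         pairs + [(i, jl)], True)
                if mm < max_mismatch:
                    lrec(i - 1, jl + 1, mm + 1, bt, bg, dscore + 1, pairs, False)
            if i >= 1 and bt < max_bulge_tsrna:
                lrec(i - 1, jl, mm, bt + 1, bg, dscore + 1, pairs, False)
            if jl <= m and bg < max_bulge_target:
                lrec(i, jl + 1, mm, bt, bg + 1, dscore + 1, pairs, False)

        lrec(s0 - 1, j_anchor + 1, 0, 0, 0, 0.0, [], True)
        return out

    for j in range(w, m + 1):
        weights = []
        for d in range(w):
            wgt = PAIR_WEIGHT.get((ts[s0 - 1 + d], tg[j - 1 - d]))
            if wgt is None:
                break
            weights.append(wgt)
        if len(weights) < w:
            continue
        anchor_pairs = [(s0 + d, j - d) for d in range(w)]
        for _, dscore, lpairs, mm, bt, bg in lefts(j):
            right(s1 + 1, j - w, mm, bt, bg,
                  -float(sum(weights)) + dscore, lpairs + anchor_pairs)

    if not candidates:
        return None
    best = min(candidates)
    if best[0] > energy_cutoff:
        return None
    return best
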