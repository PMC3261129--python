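"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's prefix/suffix arithmetic: every
expected value here comes from exhaustive enumeration, so they stay valid
checks of the production code paths.
"""

from math import comb


def deletion_placements(wt: str, mut: str) -> list[int]:
    """Every start at which deleting ``len(wt)-len(mut)`` bases yields ``mut``."""
    d = len(wt) - len(mut)
    assert d >= 1
    return [p for p in range(len(wt) - d + 1) if wt[:p] + wt[p + d :] == mut]


def insertion_placements(wt: str, mut: str) -> list[int]:
    """Every start at which inserting ``mut[p:p+d]`` into ``wt`` yields ``mut``."""
    d = len(mut) - len(wt)
    assert d >= 1
    return [
        p
        for p in range(len(wt) + 1)
        if wt[:p] + mut[p : p + d] + wt[p:] == mut
    ]


def binom_tail_upper(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def binom_tail_lower(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by hypergeometric sums."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x: int) -> float:
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    observed = pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= observed * (1 + 1e-12))


def rearrangement_anchor_lengths(
    joined: str, donor_left: str, donor_right: str
) -> tuple[int, int]:
    """Maximal joined-read prefix/suffix present in each donor, by trying
    every length at every donor offset."""

    def occurs(fragment: str, donor: str) -> bool:
        return any(
            donor[i : i + len(fragment)] == fragment
            for i in range(len(donor) - len(fragment) + 1)
        )

    prefix = max(
        (L for L in range(len(joined) + 1) if occurs(joined[:L], donor_left)),
        default=0,
    )
    suffix = max(
        (L for L in range(len(joined) + 1) if occurs(joined[len(joined) - L :], donor_right)),
        default=0,
    )
    return prefix, suffix
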