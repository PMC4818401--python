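"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p by exhaustive fixed-margin enumeration.

    Each candidate table's probability is computed from the factorial
    formula n1! n2! m1! m2! / (N! a! b! c! d!) in exact rational arithmetic;
    tables whose probability does not exceed the observed one are summed.
    Independent of the package's integer-weight implementation.
    """
    n1, n2, m1 = a + b, c + d, a + c
    big_n = n1 + n2
    if big_n == 0:
        return 1.0

    def prob(x: int) -> Fraction | None:
        bb, cc, dd = n1 - x, m1 - x, n2 - (m1 - x)
        if min(x, bb, cc, dd) < 0:
            return None
        return Fraction(
            factorial(n1) * factorial(n2) * factorial(m1) * factorial(big_n - m1),
            factorial(big_n) * factorial(x) * factorial(bb) * factorial(cc) * factorial(dd),
        )

    p_obs = prob(a)
    assert p_obs is not None
    total = Fraction(0)
    for x in range(0, m1 + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


@pytest.fixture(scope="session")
def fisher_oracle():
    return fisher_enumeration_oracle


def overlap_components_oracle(calls):
    """O(n^2) connected components of the pairwise-overlap graph, grouped by
    (chromosome, CNV type). Returns a set of frozensets of call indices."""
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.chrom != b.chrom or a.cnv_type != b.cnv_type:
                continue
            if a.start <= b.end and b.start <= a.end:
                union(i, j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}


@pytest.fixture(scope="session")
def overlap_oracle():
    return overlap_components_oracle
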