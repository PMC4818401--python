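"""Carrier-based case-control association statistics.

All tests operate on the 2x2 carriership table

    =========  ========  ============
               carrier   non-carrier
    =========  ========  ============
    cases      a         b
    controls   c         d
    =========  ========  ============

The two-sided Fisher exact p-value uses the minimum-likelihood convention:
the sum, over all tables with the observed margins, of the probabilities of
tables no more probable than the observed one. It is computed in exact
integer arithmetic (binomial weights over a common hypergeometric
denominator), so there is no floating-point tie tolerance; ties — e.g. the
mirror table of a symmetric margin set — are included exactly.

Odds ratios are unconditional sample ORs a*d / (b*c); confidence intervals
use the Woolf log-OR normal approximation, with a Haldane–Anscombe +0.5
applied to every cell only when some cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class CarrierTable:
    """Carrier/non-carrier counts for one panel."""

    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    panel_id: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def case_carrier_freq(self) -> float:
        return self.a / self.n_cases if self.n_cases else math.nan

    @property
    def control_carrier_freq(self) -> float:
        return self.c / self.n_controls if self.n_controls else math.nan


@dataclass
class AssociationResult:
    """Exact test + odds ratio summary for one carrier table."""

    table: CarrierTable
    p_two_sided: float
    odds_ratio: float  # may be +inf; nan when undefined (a == c == 0)
    ci_low: float
    ci_high: float
    method: str = "fisher_two_sided_minlike"
    or_method: str = "sample_or_woolf_ci"
    bonferroni_m: Optional[int] = None
    p_bonferroni: Optional[float] = None


def fisher_two_sided(table: CarrierTable) -> float:
    """Two-sided Fisher exact p-value, minimum-likelihood convention.

    Exact integer arithmetic: for margins (n1 cases, n2 controls, m1
    carriers), table probabilities are proportional to
    C(n1, a') * C(n2, m1 - a'); the p-value sums the weights of every a' in
    the support whose weight does not exceed the observed one, divided by
    C(n1 + n2, m1). Any zero margin forces a single possible table and p = 1.
    """
    a, n1, n2, m1 = table.a, table.n_cases, table.n_controls, table.a + table.c
    n = n1 + n2
    if n == 0:
        return 1.0
    lo = max(0, m1 - n2)
    hi = min(m1, n1)
    weights = [math.comb(n1, k) * math.comb(n2, m1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    den = math.comb(n, m1)
    return num / den


def odds_ratio(
    table: CarrierTable, zero_cell_policy: str = "haldane"
) -> tuple[float, float, float]:
    """Sample odds ratio with a 95% Woolf CI.

    Returns (OR, ci_low, ci_high). OR is +inf exactly when c == 0 and a > 0
    (no control carriers), 0.0 when a == 0 and c > 0, and nan when both
    carrier cells are zero (undefined). The CI uses
    exp(log OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)); under the default
    ``haldane`` policy 0.5 is added to all cells for the CI (and for the
    log-OR centring it) only when some cell is zero, so an infinite point
    estimate still carries a finite lower bound, as in (x - inf) intervals.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0 and c == 0:
        return math.nan, math.nan, math.nan
    if b == 0 and d == 0:
        return math.nan, math.nan, math.nan
    if c == 0 or b == 0:
        point = math.inf if a > 0 and d > 0 else math.nan
    elif a == 0 or d == 0:
        point = 0.0
    else:
        point = (a * d) / (b * c)
    if zero_cell_policy not in ("haldane", "none"):
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    if 0 in (a, b, c, d):
        if zero_cell_policy == "none":
            return point, 0.0 if point == 0.0 else math.nan, math.inf
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    z = norm.ppf(0.975)
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    if point == math.inf:
        ci_high = math.inf
    if point == 0.0:
        ci_low = 0.0
    return point, ci_low, ci_high


def pool_tables(tables: Sequence[CarrierTable], panel_id: str = "combined") -> CarrierTable:
    """Element-wise sum of per-panel tables (disjoint samples assumed)."""
    if not tables:
        raise ValueError("cannot pool an empty collection of tables")
    return CarrierTable(
        a=sum(t.a for t in tables),
        b=sum(t.b for t in tables),
        c=sum(t.c for t in tables),
        d=sum(t.d for t in tables),
        panel_id=panel_id,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def combine_stratified(
    tables: Sequence[CarrierTable],
    method: str = "stratified_permutation",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> dict:
    """Panel-stratified combined p-value.

    Two clearly labelled stand-in methods are offered for combining evidence
    across panels (neither reproduces the published mega-analysis
    combination, whose formula is external):

    * ``pooled_fisher`` — two-sided Fisher exact test on the element-wise
      pooled table; ignores stratification.
    * ``stratified_permutation`` — phenotype labels are permuted within each
      panel (margins fixed), the statistic is the total case-carrier count
      across panels, and p = (1 + #{permuted >= observed}) / (1 +
      n_permutations). One-sided in the enrichment direction. Within a
      panel, a label permutation makes the permuted case-carrier count
      hypergeometric, which is how it is sampled.

    Returns a dict with keys method, p, statistic_observed, n_permutations.
    """
    if method == "pooled_fisher":
        pooled = pool_tables(tables)
        return {
            "method": "pooled_fisher",
            "p": fisher_two_sided(pooled),
            "statistic_observed": pooled.a,
            "n_permutations": None,
        }
    if method != "stratified_permutation":
        raise ValueError(f"unknown combination method {method!r}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for a meaningful p-value")
    rng = np.random.default_rng(seed)
    observed = sum(t.a for t in tables)
    perm_total = np.zeros(n_permutations, dtype=np.int64)
    for t in tables:
        m1 = t.a + t.c
        if m1 == 0 or t.total == 0:
            continue
        perm_total += rng.hypergeometric(t.n_cases, t.n_controls, m1, size=n_permutations)
    p = (1 + int(np.sum(perm_total >= observed))) / (1 + n_permutations)
    return {
        "method": "stratified_permutation",
        "p": p,
        "statistic_observed": observed,
        "n_permutations": n_permutations,
    }


def associate(
    table: CarrierTable,
    bonferroni_m: Optional[int] = None,
) -> AssociationResult:
    """Fisher p, OR and CI for one table, with optional Bonferroni row."""
    p = fisher_two_sided(table)
    or_, lo, hi = odds_ratio(table)
    res = AssociationResult(
        table=table, p_two_sided=p, odds_ratio=or_, ci_low=lo, ci_high=hi
    )
    if bonferroni_m is not None:
        res.bonferroni_m = bonferroni_m
        res.p_bonferroni = bonferroni(p, bonferroni_m)
    return res
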