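"""Exact statistics for conversion counts and titration comparisons.

Fisher's exact test is implemented by full hypergeometric enumeration
with big-integer binomial coefficients (exact rational point
probabilities; the two-sided p sums every table, at fixed margins, whose
point probability does not exceed the observed one).  The Mann-Whitney
U test uses midranks, exact enumeration of rank assignments for small
samples and the tie-corrected normal approximation otherwise.  The
reference conversion-count tables from the dynamic-clamp and
pharmacology experiments on identified rat DRG afferents ship as named
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact",
    "mann_whitney_u",
    "conversion_tables",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns converted/not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_counts(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Build from 'k1 of n1 vs k2 of n2' conversion counts."""
        return cls(k1, n1 - k1, k2, n2 - k2)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)


def _hypergeom_point(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(top-left cell = a) at fixed margins, as an exact rational."""
    return Fraction(comb(r1, a) * comb(r2, c1 - a), comb(r1 + r2, c1))


def fisher_exact(
    table: ContingencyTable2x2, sidedness: str = "two"
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``sidedness="two"`` uses the point-probability rule: sum the exact
    hypergeometric probabilities of all tables (same margins) whose
    probability does not exceed the observed table's.  ``"greater"`` /
    ``"less"`` are one-sided tails on the top-left cell.  The statistic
    is the sample odds ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = _hypergeom_point(a, r1, r2, c1)
    if sidedness == "two":
        # tiny rational slack absorbs nothing: comparison is exact
        p = sum(
            _hypergeom_point(k, r1, r2, c1)
            for k in range(lo, hi + 1)
            if _hypergeom_point(k, r1, r2, c1) <= p_obs
        )
    elif sidedness == "greater":
        p = sum(_hypergeom_point(k, r1, r2, c1) for k in range(a, hi + 1))
    elif sidedness == "less":
        p = sum(_hypergeom_point(k, r1, r2, c1) for k in range(lo, a + 1))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult(
        statistic=odds,
        p_value=float(p),
        method="fisher-exact",
        sidedness=sidedness,
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(
    x, y, sidedness: str = "two", exact_max_n: int = 12
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    The statistic is U of the first sample.  For pooled sample sizes up
    to ``exact_max_n`` the null distribution is enumerated exactly over
    all rank assignments (ties included); otherwise the tie-corrected
    normal approximation with continuity correction is used.  Two-sided
    p doubles the smaller tail (capped at 1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    U = float(np.sum(ranks[:nx])) - nx * (nx + 1) / 2.0

    if nx + ny <= exact_max_n:
        us = []
        idx = range(nx + ny)
        for sub in combinations(idx, nx):
            us.append(float(np.sum(ranks[list(sub)])) - nx * (nx + 1) / 2.0)
        us = np.asarray(us)
        eps = 1e-9
        p_le = np.mean(us <= U + eps)
        p_ge = np.mean(us >= U - eps)
        if sidedness == "two":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif sidedness == "greater":
            p = p_ge
        elif sidedness == "less":
            p = p_le
        else:
            raise ValueError(f"unknown sidedness {sidedness!r}")
        return TestResult(
            statistic=U, p_value=float(p), method="mann-whitney-u", sidedness=sidedness
        )

    N = nx + ny
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = nx * ny / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        p = 1.0
    else:
        z = (abs(U - mu) - 0.5) / sqrt(var)
        z = max(z, 0.0)
        tail = 0.5 * (1.0 - erf(z / sqrt(2.0)))
        if sidedness == "two":
            p = min(1.0, 2.0 * tail)
        elif sidedness == "greater":
            p = tail if U >= mu else 1.0 - tail
        elif sidedness == "less":
            p = tail if U <= mu else 1.0 - tail
        else:
            raise ValueError(f"unknown sidedness {sidedness!r}")
    return TestResult(
        statistic=U, p_value=float(p), method="mann-whitney-u", sidedness=sidedness
    )


def conversion_tables() -> dict[str, ContingencyTable2x2]:
    """Reference conversion-count comparisons (converted k of n).

    Each entry compares two recorded groups of identified DRG afferents:
    how many exhibited (or were driven into) repetitive spiking versus
    not, under potassium-channel blockade (4-AP/dendrotoxin), virtual
    sodium conductance insertion, or nerve injury.
    """
    T = ContingencyTable2x2.from_counts
    return {
        # K-channel blockade converted 8 of 15 naive cutaneous afferents;
        # spontaneous conversion 0 of 23
        "4AP-cutaneous": T(8, 15, 0, 23),
        # virtual Na conductance converted 9 of 19 naive cutaneous afferents
        "virtual-Na-cutaneous": T(9, 19, 0, 23),
        # nerve injury: 1 of 9 injured cutaneous vs 0 of 23 naive
        "injured-cutaneous-vs-naive": T(1, 9, 0, 23),
        # 6 of 9 injured unlabeled vs 1 of 9 injured cutaneous
        "injured-unlabeled-vs-injured-cutaneous": T(6, 9, 1, 9),
        # 11 of 20 injured muscle vs 1 of 9 injured cutaneous
        "injured-muscle-vs-injured-cutaneous": T(11, 20, 1, 9),
        # 11 of 20 injured muscle vs 0 of 27 naive muscle
        "injured-muscle-vs-naive": T(11, 20, 0, 27),
        # virtual Na: 16 of 20 naive muscle vs 9 of 19 naive cutaneous
        "virtual-Na-muscle-vs-cutaneous": T(16, 20, 9, 19),
        # K blockade: 1 of 12 naive muscle vs 8 of 15 naive cutaneous
        "4AP-muscle-vs-cutaneous": T(1, 12, 8, 15),
    }
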