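"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the scanner oracle
walks every (position, unit) pair by string comparison, the Fisher oracle
enumerates margin-preserving tables with exact rational arithmetic, and
the Mann-Whitney oracle enumerates rank assignments.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

_ACGT = set("ACGT")


def _primitive(unit: str) -> bool:
    k = len(unit)
    return not any(k % d == 0 and unit == unit[:d] * (k // d) for d in range(1, k))


def brute_force_scan(seq: str, min_unit=1, max_unit=5, min_tract=10,
                     max_tract=100) -> set[tuple[int, int, str]]:
    """Every maximal, leftmost-anchored, primitive-unit repeat tract."""
    seq = seq.upper()
    n = len(seq)
    found: set[tuple[int, int, str]] = set()
    for k in range(min_unit, max_unit + 1):
        for i in range(n - 2 * k + 1):
            unit = seq[i : i + k]
            if set(unit) - _ACGT or not _primitive(unit):
                continue
            m = 1
            while seq[i + m * k : i + (m + 1) * k] == unit:
                m += 1
            if m < 2:
                continue
            tract_len = m * k
            if not (min_tract <= tract_len <= max_tract):
                continue
            # leftmost anchoring: the period-k agreement breaks just before i
            if i > 0 and seq[i - 1] in _ACGT and seq[i - 1] == seq[i - 1 + k]:
                continue
            found.add((i, i + tract_len, unit))
    return found


def fisher_exact_fraction(table) -> float:
    """Two-sided Fisher p by exact rational enumeration (totals <= ~40)."""
    rows = [list(map(int, r)) for r in table]
    r, c = len(rows), len(rows[0])
    row_sums = [sum(row) for row in rows]
    col_sums = [sum(rows[i][j] for i in range(r)) for j in range(c)]
    total = sum(row_sums)

    def prob(cells) -> Fraction:
        num = Fraction(1)
        for s in row_sums:
            num *= math.factorial(s)
        for s in col_sums:
            num *= math.factorial(s)
        den = Fraction(math.factorial(total))
        for row in cells:
            for v in row:
                den *= math.factorial(v)
        return num / den

    p_obs = prob(rows)

    def row_fills(row_sum, caps):
        if len(caps) == 1:
            if row_sum <= caps[0]:
                yield (row_sum,)
            return
        for v in range(min(row_sum, caps[0]) + 1):
            for rest in row_fills(row_sum - v, caps[1:]):
                yield (v,) + rest

    total_p = Fraction(0)

    def rec(i, remaining, acc):
        nonlocal total_p
        if i == r - 1:
            if all(v >= 0 for v in remaining):
                p = prob(acc + [list(remaining)])
                if p <= p_obs:
                    total_p += p
            return
        for fill in row_fills(row_sums[i], remaining):
            rec(i + 1, tuple(a - b for a, b in zip(remaining, fill)),
                acc + [list(fill)])

    rec(0, tuple(col_sums), [])
    return float(total_p)


def mann_whitney_exact(x, y) -> float:
    """Exact two-sided Mann-Whitney p for tie-free samples by enumeration.

    Under the symmetric tie-free null, the two-sided p-value is the
    probability that min(U, nx*ny - U) is at most its observed value,
    taken over all C(nx+ny, nx) equally likely rank assignments.
    """
    nx, ny = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == nx + ny, "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    u_obs = min(u, nx * ny - u)
    hits = 0
    for combo in itertools.combinations(range(1, nx + ny + 1), nx):
        s = sum(combo) - nx * (nx + 1) / 2
        if min(s, nx * ny - s) <= u_obs:
            hits += 1
    return min(1.0, hits / math.comb(nx + ny, nx))
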