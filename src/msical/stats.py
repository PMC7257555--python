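"""Cohort statistics: exact Fisher tests, Mann-Whitney U, MSI-PCR calls.

The Fisher test is the two-sided Freeman-Halton extension to r x c tables:
with margins fixed, the p-value is the total hypergeometric probability of
all tables whose point probability does not exceed that of the observed
table (with a small relative tolerance for floating-point ties).  This is
the convention of mainstream statistical software (R's ``fisher.test``).
Tables must be small enough for exact enumeration; the clinical tables this
package targets have totals well under 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import mannwhitneyu as _scipy_mwu

from .scoring import MSI_H, MSS

_TIE_RTOL = 1e-7
MAX_FISHER_TOTAL = 500


class ZeroMarginError(ValueError):
    """Raised when a contingency table has an all-zero row or column."""


@dataclass
class ContingencyTable:
    """An r x c table of non-negative counts with labeled rows/columns."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any() or (self.counts.sum(axis=0) == 0).any():
            raise ZeroMarginError("every row and column margin must be positive")


def _log_table_prob(cells: np.ndarray, row_sums: np.ndarray,
                    col_sums: np.ndarray, total: int) -> float:
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(cells + 1).sum()
    )


def _enumerate_logprobs(row_sums: np.ndarray, col_sums: np.ndarray) -> list[float]:
    """Log point-probabilities of every table with the given margins."""
    r, c = len(row_sums), len(col_sums)
    total = int(row_sums.sum())
    const = (
        float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum())
        - float(gammaln(total + 1))
    )
    out: list[float] = []
    cells = np.zeros((r, c), dtype=np.int64)

    def rec(i: int, remaining_cols: np.ndarray, acc: float) -> None:
        if i == r - 1:
            # last row is forced by the column margins
            if (remaining_cols >= 0).all():
                out.append(
                    const + acc - float(gammaln(remaining_cols + 1).sum())
                )
            return
        rs = int(row_sums[i])

        def fill(j: int, left: int, acc_row: float) -> None:
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    cells[i, j] = left
                    new_rem = remaining_cols - cells[i]
                    rec(i + 1, new_rem, acc_row - math.lgamma(left + 1))
                return
            hi = min(left, int(remaining_cols[j]))
            for v in range(hi + 1):
                cells[i, j] = v
                fill(j + 1, left - v, acc_row - math.lgamma(v + 1))

        fill(0, rs, acc)

    rec(0, col_sums.copy(), 0.0)
    return out


def fisher_exact(
    table: ContingencyTable | Sequence[Sequence[int]] | np.ndarray,
) -> float:
    """Two-sided Fisher exact p-value for an r x c contingency table.

    Sums the probabilities of all margin-preserving tables no more
    probable than the observed one; ties in probability are resolved with
    a 1e-7 relative tolerance so floating-point noise cannot split
    symmetric tables.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    total = int(counts.sum())
    if total > MAX_FISHER_TOTAL:
        raise ValueError(
            f"table total {total} too large for exact enumeration "
            f"(max {MAX_FISHER_TOTAL})"
        )
    log_obs = _log_table_prob(counts, row_sums, col_sums, total)
    threshold = log_obs + math.log1p(_TIE_RTOL)
    logps = _enumerate_logprobs(row_sums, col_sums)
    p = float(sum(math.exp(lp) for lp in logps if lp <= threshold))
    return min(p, 1.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _scipy_mwu(x, y, alternative="two-sided", method=method,
                     use_continuity=True)
    return float(min(res.pvalue, 1.0))


def msi_pcr_call(unstable_count: int) -> str:
    """MSI-PCR kit rule over six mononucleotide loci: MSI-H iff >= 2 unstable."""
    if not (0 <= unstable_count <= 6):
        raise ValueError(f"unstable locus count must be in 0..6, got {unstable_count}")
    return MSI_H if unstable_count >= 2 else MSS


def contingency_from_samples(
    categories: Sequence[str | None],
    statuses: Sequence[str],
    category_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Build a categories x (MSI-H, MSS) table, dropping missing categories.

    *categories* may contain None/NaN/"Missing" entries; those samples are
    removed before tabulation, never imputed.
    """
    rows: dict[str, list[int]] = {}
    clean = []
    for cat, st in zip(categories, statuses):
        if cat is None or (isinstance(cat, float) and math.isnan(cat)):
            continue
        if isinstance(cat, str) and cat.strip().lower() in ("", "missing", "na", "nan"):
            continue
        clean.append((str(cat), st))
    order = list(category_order) if category_order else sorted({c for c, _ in clean})
    for cat in order:
        rows[cat] = [
            sum(1 for c, s in clean if c == cat and s == MSI_H),
            sum(1 for c, s in clean if c == cat and s == MSS),
        ]
    counts = np.array([rows[c] for c in order], dtype=np.int64)
    return ContingencyTable(counts, row_labels=order, col_labels=[MSI_H, MSS])


def stats_report(
    sheet,
    category_columns: Sequence[str],
    status_column: str = "status",
):
    """Fisher-test every categorical column of a sample sheet against MSI status.

    *sheet* is a pandas DataFrame with one row per sample.  Returns a
    DataFrame with one row per category column: the p-value and the number
    of samples used after removing missing entries.
    """
    import pandas as pd

    rows = []
    for col in category_columns:
        table = contingency_from_samples(
            [None if pd.isna(v) else v for v in sheet[col]],
            list(sheet[status_column]),
        )
        rows.append(
            {
                "variable": col,
                "p_value": fisher_exact(table),
                "n_used": int(table.counts.sum()),
            }
        )
    return pd.DataFrame(rows)
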