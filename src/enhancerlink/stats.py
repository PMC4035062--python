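"""Shared statistical primitives: the 2x2 Pearson chi-square and BH adjustment.

Every between-group comparison in the pipeline (motif enrichment, gene-category
enrichment, window-scan contrasts) reduces to a 2x2 contingency table tested
with Pearson's chi-square on one degree of freedom, *without* Yates' continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "DegenerateTableError",
    "chi_square_2x2",
    "bh_adjust",
]


class DegenerateTableError(ValueError):
    """Raised when a 2x2 table has a zero marginal and the chi-square is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 contingency table.

    Row 1 is group A with/without the feature, row 2 is group B
    with/without the feature.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for field in ("a", "b", "c", "d"):
            v = getattr(self, field)
            if v < 0:
                raise ValueError(f"count {field}={v} is negative")
        if self.n == 0:
            raise ValueError("empty table: all counts are zero")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def marginals(self) -> dict[str, int]:
        return {
            "row1": self.a + self.b,
            "row2": self.c + self.d,
            "col1": self.a + self.c,
            "col2": self.b + self.d,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the p-value is the
    upper tail of the chi-square distribution with one degree of freedom.

    Raises :class:`DegenerateTableError` if any marginal is zero.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    for name, total in table.marginals().items():
        if total == 0:
            raise DegenerateTableError(f"marginal {name!r} is zero; chi-square undefined")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    statistic = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p_value = float(_sps.chi2.sf(statistic, df=1))
    return TestResult(statistic=float(statistic), df=1, p_value=p_value)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return _sps.false_discovery_control(p, method="bh")
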