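"""TNBC/basal-like sample selection, IHC scoring, and 2x2 chi-squared association.

Basal-like (triple-negative) status is read off the receptor annotations:
a sample qualifies iff ER, PR and HER2 are all negative. IHC percent
positivity is binned into the three standard categories (<25% negative,
25-49% low, >=50% high). The association between two binary groupings is
tested with the Pearson chi-squared statistic on the 2x2 table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from scipy import stats

from .io import DegenerateInputError, SampleAnnotation

logger = logging.getLogger(__name__)


class IHCCategory(str, Enum):
    NEGATIVE = "negative"
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b (row 1) and c, d (row 2) of a 2x2 cross-tabulation."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            count = getattr(self, name)
            if not isinstance(count, (int,)) or isinstance(count, bool):
                raise TypeError(f"count {name} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"count {name} must be non-negative, got {count}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float


def classify_tnbc(annotations: list[SampleAnnotation]) -> list[str]:
    """Return the ids of triple-negative (ER-/PR-/HER2-) samples.

    Samples with any ``unknown`` receptor status are excluded (not imputed);
    the number excluded is logged. Output order follows input order.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    selected: list[str] = []
    n_unknown = 0
    for ann in annotations:
        statuses = (ann.er_status, ann.pr_status, ann.her2_status)
        if "unknown" in statuses:
            n_unknown += 1
            continue
        if statuses == ("negative", "negative", "negative"):
            selected.append(ann.sample_id)
    logger.info(
        "classify_tnbc: %d/%d triple-negative, %d excluded for unknown receptor status",
        len(selected), len(annotations), n_unknown,
    )
    return selected


def ihc_categorize(percent_positive: float) -> IHCCategory:
    """Bin an IHC percent-positivity score into negative/low/high.

    <25 -> negative; 25-49 -> low; >=50 -> high. Boundaries are inclusive
    on the left of each upper bin (25 is low, 50 is high).
    """
    if not (0.0 <= percent_positive <= 100.0):
        raise ValueError(f"percent_positive must be in [0, 100], got {percent_positive}")
    if percent_positive < 25.0:
        return IHCCategory.NEGATIVE
    if percent_positive < 50.0:
        return IHCCategory.LOW
    return IHCCategory.HIGH


def chi_squared_2x2(table: ContingencyTable2x2, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2x2 table.

    Without continuity correction the statistic is the closed form
    ``n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``; with Yates correction
    ``|ad - bc|`` is shrunk by ``n/2`` (floored at zero) before squaring.
    The p-value is the upper tail of the chi-squared distribution with one
    degree of freedom. A zero marginal leaves the test undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    marginals = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in marginals):
        raise DegenerateInputError(
            f"chi-squared test undefined: zero marginal in table ({a}, {b}, {c}, {d})"
        )
    det = a * d - b * c
    if correction:
        det = max(abs(det) - n / 2.0, 0.0)
    statistic = n * float(det) ** 2 / float(math.prod(marginals))
    pvalue = float(stats.chi2.sf(statistic, df=1))
    # sf returns 0.0 only for astronomically large statistics; clamp into (0, 1]
    pvalue = max(pvalue, 5e-324)
    return ChiSquareResult(statistic=statistic, df=1, pvalue=min(pvalue, 1.0))
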