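"""Hypergeometric disease prioritization — the core ranking statistic.

For a query Q and a disease D, with

* ``m`` — publications in the link table,
* ``j`` — of those, publications involving D,
* ``n`` — query-retrieved publications present in the table,
* ``k`` — of those, publications involving D,

the tail probability of observing ``k`` or more D-publications when
``n`` publications are drawn without replacement from ``m`` is

    f(m, n, j, k) = Σ_{i=k}^{min(n,j)}  C(j, i) · C(m−j, n−i) / C(m, n)

and the disease's score is ``S_D = −log10 f(m, n, j, k)``.  Diseases
are ranked by score descending; ties break by ``j`` descending (better
documented diseases first), then by name ascending for determinism.

The tail is evaluated entirely in log space — log-gamma binomial
coefficients combined by sequential log-add accumulation — because
real contingencies reach f ≈ 10^−1800 and beyond, far below what
double-precision linear arithmetic can represent.  No multiple-testing
correction is applied: the raw −log10 tail probability *is* the
ranking score.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.special import gammaln

from .linktable import LinkTable
from .medline import QueryResult

__all__ = [
    "QueryContingency",
    "DiseaseScore",
    "ContingencyError",
    "log_hypergeom_tail",
    "hypergeom_tail",
    "score_disease",
    "prioritize",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


class ContingencyError(ValueError):
    """Raised when (m, n, j, k) violate the contingency inequalities."""


@dataclass(frozen=True)
class QueryContingency:
    """The 2×2 draw parameters (m, n, j, k) for one disease.

    Invariants ``0 ≤ k ≤ min(n, j)``, ``n ≤ m``, ``j ≤ m`` are enforced
    at construction; violations name the offending inequality.
    """

    m: int
    n: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ContingencyError(f"m ≥ 0 violated: m={self.m}")
        if not 0 <= self.n <= self.m:
            raise ContingencyError(f"0 ≤ n ≤ m violated: n={self.n}, m={self.m}")
        if not 0 <= self.j <= self.m:
            raise ContingencyError(f"0 ≤ j ≤ m violated: j={self.j}, m={self.m}")
        if not 0 <= self.k <= min(self.n, self.j):
            raise ContingencyError(
                f"0 ≤ k ≤ min(n, j) violated: k={self.k}, n={self.n}, j={self.j}"
            )


def _log_comb(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    """Natural-log binomial coefficient via log-gamma; requires 0 ≤ b ≤ a."""
    return gammaln(np.asarray(a) + 1) - gammaln(np.asarray(b) + 1) - gammaln(
        np.asarray(a) - np.asarray(b) + 1
    )


def log_hypergeom_tail(
    m: int, n: int, j: int, k: int, order: str = "forward"
) -> float:
    """Natural log of the upper tail f(m, n, j, k); always finite, ≤ 0.

    Terms with an impossible deficit (``n − i > m − j``) contribute
    nothing.  ``order`` selects the direction of the sequential log-add
    accumulation ("forward" from i=k, "reverse" from i=min(n,j)); the
    two orders agree to near machine precision and exist to let callers
    verify numerical stability of extreme contingencies.
    """
    QueryContingency(m, n, j, k)  # validate
    # At or below the support floor max(0, n+j−m) the event "≥ k" is
    # certain; return log 1 exactly rather than a rounded sum.
    if k <= max(0, n + j - m):
        return 0.0
    hi = min(n, j)
    i = np.arange(k, hi + 1, dtype=np.float64)
    terms = _log_comb(float(j), i) + _log_comb(float(m - j), n - i) - _log_comb(
        float(m), float(n)
    )
    # i below the support floor max(0, n+j−m) would need more non-D
    # publications than exist; mask them out.
    terms = np.where(n - i <= m - j, terms, -np.inf)
    if order == "reverse":
        terms = terms[::-1]
    elif order != "forward":
        raise ValueError(f"order must be 'forward' or 'reverse', got {order!r}")
    total = float(np.logaddexp.reduce(terms))
    return min(total, 0.0)


def hypergeom_tail(c: QueryContingency) -> float:
    """Linear-space tail probability in [0, 1] (may underflow to 0.0)."""
    return math.exp(log_hypergeom_tail(c.m, c.n, c.j, c.k))


def score_disease(c: QueryContingency, order: str = "forward") -> float:
    """``S_D = −log10 f(m, n, j, k)``; 0 when f = 1, finite always."""
    return max(0.0, -log_hypergeom_tail(c.m, c.n, c.j, c.k, order=order) / _LN10)


@dataclass(frozen=True)
class DiseaseScore:
    """One ranked result row."""

    disease: str
    score: float
    contingency: QueryContingency
    supporting_pmids: tuple[int, ...]
    rank: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "supporting_pmids", tuple(self.supporting_pmids))


def prioritize(
    table: LinkTable,
    query: Union[QueryResult, Iterable[int]],
    max_diseases: int | None = None,
    newest_first: bool = True,
) -> list[DiseaseScore]:
    """Score and rank every disease co-annotated with the query's PMIDs.

    Only query PMIDs present in the table participate (``n`` counts
    those; the rest are dropped with a logged count).  Every disease
    with ``k ≥ 1`` receives a score; ordering is score descending, ties
    by ``j`` descending, residual ties by name ascending; ranks are
    1-based and consecutive.  Supporting publications are ordered by
    date, most recent first by default.
    """
    if table.m == 0:
        raise ValueError("link table is empty")
    pmids = query.pmids if isinstance(query, QueryResult) else tuple(query)
    in_table = sorted({p for p in pmids if p in table.publications})
    dropped = len(set(pmids)) - len(in_table)
    if dropped:
        logger.info("dropped %d query PMIDs absent from the link table", dropped)
    n = len(in_table)
    if n == 0:
        logger.info("no query publications present in the link table")
        return []

    support: dict[str, list[int]] = {}
    for p in in_table:
        for d in table.publications[p][1]:
            support.setdefault(d, []).append(p)

    m = table.m
    rows = []
    for disease, sup in support.items():
        j = table.j(disease)
        k = len(sup)
        c = QueryContingency(m=m, n=n, j=j, k=k)
        sup_sorted = sorted(
            sup, key=lambda p: (table.publications[p][0], p), reverse=newest_first
        )
        rows.append((score_disease(c), j, disease, c, tuple(sup_sorted)))

    rows.sort(key=lambda r: (-r[0], -r[1], r[2]))
    if max_diseases is not None:
        rows = rows[:max_diseases]
    return [
        DiseaseScore(
            disease=disease,
            score=score,
            contingency=c,
            supporting_pmids=sup,
            rank=rank,
        )
        for rank, (score, j, disease, c, sup) in enumerate(rows, start=1)
    ]
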