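"""Gold-standard construction and ranked-retrieval metrics.

Curated term–disease association tables (a neutral TSV schema standing
in for gene–disease and chemical–disease curation databases) are turned
into per-term *relevant* disease sets under four stringency criteria:

1. union of the two sources' (term, disease) pairs;
2. union, restricted to pairs with ≥ ``min_pubs`` supporting
   publications in each database in which they appear;
3. intersection of the two sources;
4. intersection with ≥ ``min_pubs`` supporting publications in both.

For chemical queries a separate gold standard keeps only associations
whose evidence code is exactly ``"therapeutic"``.

Ranked disease lists are evaluated with the standard IR toolkit:
set precision/recall/F (F = 2pr/(p+r)), average precision (unretrieved
relevant items contribute 0), mean average precision, precision at a
fixed cutoff k (denominator stays k even for shorter lists), full
precision–recall curves, and the rank of the first relevant disease.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CuratedAssociation",
    "GoldStandard",
    "EvalMetrics",
    "build_gold_standard",
    "therapeutic_gold_standard",
    "precision_recall_f",
    "average_precision",
    "map_score",
    "precision_at_k",
    "pr_curve",
    "rank_of_gold",
    "gold_rank_counts",
    "read_associations_tsv",
    "write_associations_tsv",
]

ASSOCIATION_COLUMNS = ["term", "disease", "source", "publication_count", "evidence"]


@dataclass(frozen=True)
class CuratedAssociation:
    """One curated term–disease row.

    ``source`` labels the curation database (e.g. ``"GAD"``,
    ``"CTD_curated"`` or ``"synthetic"``); ``publication_count`` is the
    number of publications the database cites for the pair; ``evidence``
    is a free-text code such as ``"therapeutic"``.
    """

    term: str
    disease: str
    source: str
    publication_count: int = 0
    evidence: str = ""


@dataclass
class GoldStandard:
    """Per-term relevant disease sets under a named criterion."""

    relevant: dict[str, set[str]]
    criterion: str

    def __post_init__(self) -> None:
        empty = [t for t, s in self.relevant.items() if not s]
        if empty:
            raise ValueError(f"terms with empty relevant sets: {empty}")


@dataclass
class EvalMetrics:
    """Precision/recall/F plus optional ranking metrics for one query."""

    precision: float
    recall: float
    f_measure: float
    average_precision: Optional[float] = None
    precision_at_k: dict[int, float] = field(default_factory=dict)


def _pair_index(
    assocs: Iterable[CuratedAssociation],
) -> dict[tuple[str, str], dict[str, int]]:
    """(term, disease) → {source: max publication_count}."""
    index: dict[tuple[str, str], dict[str, int]] = {}
    for a in assocs:
        by_source = index.setdefault((a.term, a.disease), {})
        by_source[a.source] = max(by_source.get(a.source, 0), a.publication_count)
    return index


def build_gold_standard(
    assocs: Iterable[CuratedAssociation],
    criterion: int,
    min_pubs: int = 2,
    sources: tuple[str, str] = ("GAD", "CTD_curated"),
) -> GoldStandard:
    """Assemble a gold standard under one of the four criteria.

    "More than 1 supporting publication" is implemented as
    ``publication_count ≥ min_pubs`` with ``min_pubs=2``.  Terms whose
    relevant set comes out empty are dropped.
    """
    if criterion not in (1, 2, 3, 4):
        raise ValueError(f"unknown criterion {criterion!r}; expected 1, 2, 3 or 4")
    a_src, b_src = sources
    relevant: dict[str, set[str]] = {}
    for (term, disease), by_source in _pair_index(assocs).items():
        counts = {s: c for s, c in by_source.items() if s in sources}
        if not counts:
            continue
        in_both = a_src in counts and b_src in counts
        if criterion == 1:
            keep = True
        elif criterion == 2:
            keep = all(c >= min_pubs for c in counts.values())
        elif criterion == 3:
            keep = in_both
        else:
            keep = in_both and all(c >= min_pubs for c in counts.values())
        if keep:
            relevant.setdefault(term, set()).add(disease)
    return GoldStandard(relevant=relevant, criterion=str(criterion))


def therapeutic_gold_standard(
    assocs: Iterable[CuratedAssociation],
    source: str = "CTD_curated",
    evidence: str = "therapeutic",
) -> GoldStandard:
    """Keep only rows from *source* whose evidence code matches exactly.

    Matching is case-sensitive: ``"Therapeutic"`` does not match.
    """
    relevant: dict[str, set[str]] = {}
    for a in assocs:
        if a.source == source and a.evidence == evidence:
            relevant.setdefault(a.term, set()).add(a.disease)
    return GoldStandard(relevant=relevant, criterion="therapeutic")


def precision_recall_f(
    retrieved: Sequence[str], relevant: set[str]
) -> EvalMetrics:
    """Set-based precision, recall and F-measure.

    p = |relevant ∩ retrieved| / |retrieved|, r = |relevant ∩
    retrieved| / |relevant|, F = 2pr/(p+r) (0 when p+r = 0).  An empty
    retrieved list yields p = r = F = 0 by convention.
    """
    if not relevant:
        raise ValueError("relevant set must be non-empty")
    retrieved_set = set(retrieved)
    hits = len(retrieved_set & relevant)
    p = hits / len(retrieved_set) if retrieved_set else 0.0
    r = hits / len(relevant)
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return EvalMetrics(precision=p, recall=r, f_measure=f)


def average_precision(ranked: Sequence[str], relevant: set[str]) -> float:
    """Average precision of a ranked list.

    Mean over all relevant items of the precision at each relevant
    item's rank; relevant items never retrieved contribute 0.  Equals 1
    iff the relevant items fill the top |relevant| ranks.
    """
    if not relevant:
        raise ValueError("relevant set must be non-empty")
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicate entries")
    hits = 0
    total = 0.0
    for position, item in enumerate(ranked, start=1):
        if item in relevant:
            hits += 1
            total += hits / position
    return total / len(relevant)


def map_score(per_query_ap: Iterable[float]) -> float:
    """Mean average precision over a set of queries."""
    aps = list(per_query_ap)
    if not aps:
        raise ValueError("map_score needs at least one query")
    return sum(aps) / len(aps)


def precision_at_k(ranked: Sequence[str], relevant: set[str], k: int) -> float:
    """|top-k ∩ relevant| / k; the denominator stays k for short lists."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    return len(set(ranked[:k]) & relevant) / k


def pr_curve(
    ranked: Sequence[str], relevant: set[str]
) -> list[tuple[float, float]]:
    """(recall, precision) at every cutoff 1..len(ranked).

    Recall is non-decreasing along the curve.
    """
    points = []
    hits = 0
    denom = max(len(relevant), 1)
    for position, item in enumerate(ranked, start=1):
        if item in relevant:
            hits += 1
        points.append((hits / denom, hits / position))
    return points


def rank_of_gold(ranked: Sequence[str], relevant: set[str]) -> Optional[int]:
    """1-based rank of the first relevant disease; None when absent."""
    for position, item in enumerate(ranked, start=1):
        if item in relevant:
            return position
    return None


def gold_rank_counts(
    ranked_by_term: Mapping[str, Sequence[str]],
    gold: GoldStandard,
    tops: Sequence[int] = (1, 2, 5),
) -> dict[int, int]:
    """How many terms place a relevant disease within each top cutoff."""
    counts = {t: 0 for t in tops}
    for term, ranked in ranked_by_term.items():
        relevant = gold.relevant.get(term)
        if not relevant:
            continue
        rank = rank_of_gold(ranked, relevant)
        if rank is None:
            continue
        for t in tops:
            if rank <= t:
                counts[t] += 1
    return counts


def read_associations_tsv(path: str | os.PathLike) -> list[CuratedAssociation]:
    """Load the neutral association schema (5 tab-separated columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    return [
        CuratedAssociation(
            term=row.term,
            disease=row.disease,
            source=row.source,
            publication_count=int(row.publication_count),
            evidence=row.evidence,
        )
        for row in df.itertuples(index=False)
    ]


def write_associations_tsv(
    assocs: Iterable[CuratedAssociation], path: str | os.PathLike
) -> None:
    df = pd.DataFrame(
        [
            (a.term, a.disease, a.source, a.publication_count, a.evidence)
            for a in assocs
        ],
        columns=ASSOCIATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
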