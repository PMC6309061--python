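"""Result persistence and run summaries.

Ranked disease lists export to a TSV (columns: rank, disease, score,
k, j, n, m, semicolon-joined supporting PMIDs) and to a mirroring JSON
schema; both re-parse to equal in-memory structures.  Every query run
also produces a :class:`RunSummary` capturing the retrieval accounting
(retrieved = in-table + dropped) and the table census.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Optional

from .linktable import TableStats
from .prioritize import DiseaseScore, QueryContingency

__all__ = [
    "RunSummary",
    "write_results_tsv",
    "read_results_tsv",
    "write_results_json",
    "read_results_json",
]

RESULT_COLUMNS = ("rank", "disease", "score", "k", "j", "n", "m", "supporting_pmids")


@dataclass
class RunSummary:
    """Accounting for one query run."""

    query: str
    backend: str
    n_retrieved: int
    n_in_table: int
    n_dropped: int
    table_diseases: int
    table_publications: int
    table_relationships: int
    top_score: Optional[float] = None
    elapsed_seconds: float = 0.0
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.n_retrieved != self.n_in_table + self.n_dropped:
            raise ValueError(
                "inconsistent counts: retrieved must equal in-table + dropped "
                f"({self.n_retrieved} != {self.n_in_table} + {self.n_dropped})"
            )

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunSummary":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _score_row(s: DiseaseScore) -> dict:
    return {
        "rank": s.rank,
        "disease": s.disease,
        "score": repr(s.score),
        "k": s.contingency.k,
        "j": s.contingency.j,
        "n": s.contingency.n,
        "m": s.contingency.m,
        "supporting_pmids": ";".join(str(p) for p in s.supporting_pmids),
    }


def _row_to_score(row: dict) -> DiseaseScore:
    pmids = tuple(
        int(p) for p in str(row["supporting_pmids"]).split(";") if p
    )
    return DiseaseScore(
        disease=row["disease"],
        score=float(row["score"]),
        contingency=QueryContingency(
            m=int(row["m"]), n=int(row["n"]), j=int(row["j"]), k=int(row["k"])
        ),
        supporting_pmids=pmids,
        rank=int(row["rank"]),
    )


def write_results_tsv(scores: list[DiseaseScore], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for s in scores:
            row = _score_row(s)
            fh.write("\t".join(str(row[c]) for c in RESULT_COLUMNS) + "\n")


def read_results_tsv(path: str | os.PathLike) -> list[DiseaseScore]:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ValueError(f"unexpected results header: {header}")
        out = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(RESULT_COLUMNS):
                raise ValueError(f"line {lineno}: expected {len(RESULT_COLUMNS)} columns")
            out.append(_row_to_score(dict(zip(RESULT_COLUMNS, parts))))
    return out


def write_results_json(
    scores: list[DiseaseScore],
    path: str | os.PathLike,
    summary: Optional[RunSummary] = None,
) -> None:
    payload: dict = {"results": [_score_row(s) for s in scores]}
    if summary is not None:
        payload["summary"] = asdict(summary)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_results_json(
    path: str | os.PathLike,
) -> tuple[list[DiseaseScore], Optional[RunSummary]]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    scores = [_row_to_score(row) for row in payload["results"]]
    summary = (
        RunSummary(**payload["summary"]) if "summary" in payload else None
    )
    return scores, summary
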