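"""The publication-to-disease link table.

The link table is the bipartite structure at the heart of the method:
for every publication it stores the set of disease descriptors it is
indexed with, and for every disease the set of publications mentioning
it.  Its two census quantities parameterize the ranking statistic:

* ``m`` — the number of publications in the table (only publications
  carrying at least one disease heading enter, so ``m`` counts
  disease-bearing publications);
* ``j(D)`` — the number of publications annotated with disease ``D``.

Publications enter the table when dated on or after the minimum date
(default 1960-01-01) and carrying at least one MeSH heading that
resolves to a vocabulary descriptor passing the disease branch filter.
Repeated headings within one publication are deduplicated, so a PMID
contributes at most 1 to any ``j``.

Persistence is a commented TSV: ``pmid<TAB>ISO-date<TAB>name;name``.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .medline import PublicationRecord
from .vocabulary import DiseaseBranchFilter, MeshDescriptor, is_disease_descriptor

__all__ = [
    "LinkTable",
    "TableStats",
    "LinkTableFormatError",
    "ConfigurationError",
    "DEFAULT_MIN_DATE",
    "build_link_table",
    "table_stats",
    "write_link_table",
    "read_link_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_DATE = _dt.date(1960, 1, 1)


class LinkTableFormatError(ValueError):
    """Raised when a persisted link table does not match the schema."""


class ConfigurationError(ValueError):
    """Raised for unusable build inputs (e.g. an empty vocabulary)."""


class TableStats(NamedTuple):
    n_diseases: int
    n_publications: int
    n_relationships: int


@dataclass
class LinkTable:
    """Bipartite publication↔disease structure.

    ``publications`` maps pmid → (date, frozen set of disease names);
    ``diseases`` maps disease name → set of pmids.  The two views are
    kept mutually consistent, every disease row is non-empty, and
    ``m == len(publications)``.

    Equality compares the bipartite content and the filter description,
    not ``built_at``, so rebuilding from identical inputs yields an
    equal table.
    """

    publications: dict[int, tuple[_dt.date, frozenset[str]]] = field(default_factory=dict)
    diseases: dict[str, set[int]] = field(default_factory=dict)
    built_at: str = ""
    filter_used: str = ""

    @property
    def m(self) -> int:
        return len(self.publications)

    def j(self, disease: str) -> int:
        return len(self.diseases.get(disease, ()))

    @property
    def relationship_count(self) -> int:
        return sum(len(ds) for _, ds in self.publications.values())

    def stats(self) -> TableStats:
        return TableStats(len(self.diseases), self.m, self.relationship_count)

    def check_invariants(self) -> None:
        """Assert bipartite consistency; raises AssertionError on breakage."""
        assert all(pmids for pmids in self.diseases.values()), "empty disease row"
        forward = sum(len(ds) for _, ds in self.publications.values())
        backward = sum(len(ps) for ps in self.diseases.values())
        assert forward == backward, "bipartite views disagree"
        for disease, pmids in self.diseases.items():
            for p in pmids:
                assert disease in self.publications[p][1], "dangling disease→pmid edge"

    def drop_publication(self, pmid: int) -> "LinkTable":
        """Return a copy without *pmid* (empty disease rows removed)."""
        if pmid not in self.publications:
            raise KeyError(pmid)
        pubs = {p: v for p, v in self.publications.items() if p != pmid}
        diseases: dict[str, set[int]] = {}
        for d, ps in self.diseases.items():
            remaining = ps - {pmid}
            if remaining:
                diseases[d] = remaining
        return LinkTable(pubs, diseases, self.built_at, self.filter_used)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkTable):
            return NotImplemented
        return (
            self.publications == other.publications
            and self.diseases == other.diseases
            and self.filter_used == other.filter_used
        )


def build_link_table(
    records: Iterable[PublicationRecord],
    vocabulary: Iterable[MeshDescriptor],
    branch_filter: DiseaseBranchFilter | None = None,
    min_date: _dt.date = DEFAULT_MIN_DATE,
) -> LinkTable:
    """Construct a link table from parsed citations and a vocabulary.

    A record enters iff its date ≥ *min_date* and at least one heading
    resolves to a vocabulary descriptor passing the branch filter.
    Headings absent from the vocabulary are ignored (their count is
    logged).  Headings are matched by exact descriptor-name string.
    """
    if branch_filter is None:
        branch_filter = DiseaseBranchFilter()
    vocabulary = list(vocabulary)
    all_names = {d.name for d in vocabulary}
    disease_names = {
        d.name for d in vocabulary if is_disease_descriptor(d, branch_filter)
    }
    if not disease_names:
        # Distinguish "no vocabulary at all" from "no disease descriptors".
        raise ConfigurationError(
            "vocabulary contains no descriptors passing the disease filter"
        )

    table = LinkTable(
        built_at=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        filter_used=branch_filter.describe(),
    )
    unknown = 0
    for rec in records:
        if rec.date < min_date:
            continue
        hits = {h for h in rec.mesh_headings if h in disease_names}
        # Only headings absent from the vocabulary count as unknown;
        # vocabulary headings that are simply not diseases are expected.
        unknown += sum(1 for h in rec.mesh_headings if h not in all_names)
        if not hits:
            continue
        table.publications[rec.pmid] = (rec.date, frozenset(hits))
        for d in hits:
            table.diseases.setdefault(d, set()).add(rec.pmid)
    if unknown:
        logger.info("ignored %d headings outside the disease vocabulary", unknown)
    return table


def table_stats(table: LinkTable) -> TableStats:
    """(disease count, m, relationship count) with Σ j(D) == relationships."""
    return table.stats()


def write_link_table(table: LinkTable, path: str | os.PathLike) -> None:
    """Persist as commented TSV; rows sorted by PMID for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# built_at: {table.built_at}\n")
        fh.write(f"# filter: {table.filter_used}\n")
        for pmid in sorted(table.publications):
            date, names = table.publications[pmid]
            fh.write(f"{pmid}\t{date.isoformat()}\t{';'.join(sorted(names))}\n")


def read_link_table(source: str | os.PathLike) -> LinkTable:
    """Load a persisted table; ``read(write(t)) == t``.

    Raises
    ------
    LinkTableFormatError
        Naming the offending line number on any schema mismatch.
    """
    table = LinkTable()
    with open(source, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("built_at:"):
                    table.built_at = body.split(":", 1)[1].strip()
                elif body.startswith("filter:"):
                    table.filter_used = body.split(":", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LinkTableFormatError(
                    f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            try:
                pmid = int(parts[0])
                date = _dt.date.fromisoformat(parts[1])
            except ValueError as exc:
                raise LinkTableFormatError(f"line {lineno}: {exc}") from exc
            names = frozenset(n for n in parts[2].split(";") if n)
            if not names:
                raise LinkTableFormatError(f"line {lineno}: row has no disease names")
            if pmid in table.publications:
                raise LinkTableFormatError(f"line {lineno}: duplicate pmid {pmid}")
            table.publications[pmid] = (date, names)
            for d in names:
                table.diseases.setdefault(d, set()).add(pmid)
    return table
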