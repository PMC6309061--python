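"""MEDLINE/PubMed citation parsing and query→PMID retrieval.

Reads and writes the ``PubmedArticleSet`` XML dialect that NCBI's
eFetch returns, keeping only what the ranking method needs: the PMID,
the publication date, the MeSH descriptor headings, and the
title/abstract text (used by the offline fixture retrieval backend).

Two retrieval backends implement the query → PMID-list step:

``FixtureBackend``
    Pure, offline: case-insensitive whole-token match of the query over
    each record's title+abstract.  Same (query, corpus) always yields
    the same PMIDs.  This matching rule is an artifact of making the
    pipeline testable without a network; it does not emulate PubMed's
    query translation.

``EntrezBackend``
    Live NCBI eSearch over HTTP (stdlib urllib), with retstart/retmax
    paging, bounded retries and a politeness delay.  The query string is
    forwarded verbatim.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
import time
import urllib.parse
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

from lxml import etree

__all__ = [
    "PublicationRecord",
    "QueryResult",
    "MedlineParseError",
    "RetrievalError",
    "RetrievalBackend",
    "FixtureBackend",
    "EntrezBackend",
    "parse_medline_xml",
    "write_medline_xml",
    "retrieve_pmids",
    "get_backend",
]

logger = logging.getLogger(__name__)

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


class MedlineParseError(ValueError):
    """Raised for malformed citation XML."""


class RetrievalError(RuntimeError):
    """Raised when a retrieval backend fails after bounded retries."""


@dataclass(frozen=True)
class PublicationRecord:
    """One MEDLINE article reduced to ranking-relevant fields.

    Month and day default to January 1 when the source gives only a
    year, so every record carries a sortable date.
    """

    pmid: int
    date: _dt.date
    mesh_headings: tuple[str, ...] = ()
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")
        if self.date.year < 1900:
            raise ValueError(f"publication year {self.date.year} < 1900")
        object.__setattr__(self, "mesh_headings", tuple(self.mesh_headings))


@dataclass(frozen=True)
class QueryResult:
    """Deduplicated PMIDs returned for a query by some backend."""

    query: str
    pmids: tuple[int, ...]
    backend: str
    retrieved_at: str = ""

    def __post_init__(self) -> None:
        if len(set(self.pmids)) != len(self.pmids):
            raise ValueError("QueryResult.pmids must contain no duplicates")
        object.__setattr__(self, "pmids", tuple(self.pmids))


# ---------------------------------------------------------------------------
# XML parsing / serialization


def _parse_pubdate(citation: etree._Element) -> _dt.date:
    pubdate = citation.find(".//Journal/JournalIssue/PubDate")
    if pubdate is None:
        pubdate = citation.find(".//PubDate")
    year = month = day = None
    if pubdate is not None:
        ytext = pubdate.findtext("Year")
        if ytext and ytext.strip().isdigit():
            year = int(ytext)
            mtext = (pubdate.findtext("Month") or "").strip()
            if mtext:
                if mtext.isdigit():
                    month = int(mtext)
                else:
                    month = _MONTHS.get(mtext[:3].lower())
            dtext = (pubdate.findtext("Day") or "").strip()
            if dtext.isdigit():
                day = int(dtext)
        else:
            # MedlineDate holds ranges like "1998 Dec-1999 Jan"; take the
            # leading year.
            mdate = pubdate.findtext("MedlineDate") or ""
            match = re.search(r"(1[89]\d{2}|2\d{3})", mdate)
            if match:
                year = int(match.group(1))
    if year is None:
        raise MedlineParseError("article has no parseable publication year")
    return _dt.date(year, month or 1, day or 1)


def parse_medline_xml(source: Union[str, bytes, IO]) -> list[PublicationRecord]:
    """Parse a ``PubmedArticleSet`` document into publication records.

    One record per ``PubmedArticle``; MeSH headings carry the
    ``DescriptorName`` strings in document order; articles lacking a
    ``MeshHeadingList`` yield an empty heading tuple.

    Raises
    ------
    MedlineParseError
        On malformed XML (with the parser's line/column position), on an
        article lacking a PMID (naming the article index), or on
        duplicate PMIDs within the document.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        data = source
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise MedlineParseError(
            f"malformed MEDLINE XML at line {exc.lineno}, column {exc.position[1]}: {exc.msg}"
        ) from exc
    records: list[PublicationRecord] = []
    seen: set[int] = set()
    for idx, article in enumerate(root.iter("PubmedArticle")):
        citation = article.find("MedlineCitation")
        if citation is None:
            citation = article
        pmid_text = citation.findtext("PMID")
        if pmid_text is None or not pmid_text.strip().isdigit():
            raise MedlineParseError(f"article #{idx + 1} has no valid PMID")
        pmid = int(pmid_text)
        if pmid in seen:
            raise MedlineParseError(f"duplicate PMID {pmid} at article #{idx + 1}")
        seen.add(pmid)
        headings = tuple(
            dn.text.strip()
            for dn in citation.findall("MeshHeadingList/MeshHeading/DescriptorName")
            if dn.text and dn.text.strip()
        )
        title = (citation.findtext(".//Article/ArticleTitle") or "").strip()
        abstract = (citation.findtext(".//Article/Abstract/AbstractText") or "").strip()
        records.append(
            PublicationRecord(
                pmid=pmid,
                date=_parse_pubdate(citation),
                mesh_headings=headings,
                title=title,
                abstract=abstract,
            )
        )
    return records


def write_medline_xml(records: Iterable[PublicationRecord]) -> str:
    """Serialize records back to the ``PubmedArticleSet`` dialect.

    ``parse_medline_xml(write_medline_xml(records)) == records``.
    """
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        article = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = str(rec.pmid)
        art = etree.SubElement(citation, "Article")
        journal = etree.SubElement(art, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        etree.SubElement(pubdate, "Year").text = str(rec.date.year)
        etree.SubElement(pubdate, "Month").text = str(rec.date.month)
        etree.SubElement(pubdate, "Day").text = str(rec.date.day)
        etree.SubElement(art, "ArticleTitle").text = rec.title
        if rec.abstract:
            abstract = etree.SubElement(art, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        if rec.mesh_headings:
            mhl = etree.SubElement(citation, "MeshHeadingList")
            for heading in rec.mesh_headings:
                mh = etree.SubElement(mhl, "MeshHeading")
                etree.SubElement(mh, "DescriptorName").text = heading
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Retrieval backends


class RetrievalBackend(ABC):
    """Strategy turning a free-text query into a PMID list."""

    label: str = "abstract"

    @abstractmethod
    def search(
        self,
        query: str,
        max_results: int | None = None,
        min_date: _dt.date | None = None,
    ) -> list[int]:
        """Return PMIDs for *query*, possibly with duplicates."""


_TOKEN_RE = re.compile(r"[A-Za-z0-9_\-]+")


class FixtureBackend(RetrievalBackend):
    """Offline retrieval over an in-memory corpus.

    A record matches when every whitespace-separated query token occurs
    (case-insensitively) as a whole token in its title or abstract.
    Results come back in ascending PMID order, making retrieval a pure
    function of (query, corpus).
    """

    label = "fixture"

    def __init__(self, records: Iterable[PublicationRecord]):
        self._tokens: dict[int, frozenset[str]] = {}
        self._dates: dict[int, _dt.date] = {}
        for rec in records:
            text = f"{rec.title} {rec.abstract}"
            self._tokens[rec.pmid] = frozenset(
                t.lower() for t in _TOKEN_RE.findall(text)
            )
            self._dates[rec.pmid] = rec.date

    def search(
        self,
        query: str,
        max_results: int | None = None,
        min_date: _dt.date | None = None,
    ) -> list[int]:
        wanted = [t.lower() for t in _TOKEN_RE.findall(query)]
        hits = [
            pmid
            for pmid in sorted(self._tokens)
            if all(t in self._tokens[pmid] for t in wanted)
            and (min_date is None or self._dates[pmid] >= min_date)
        ]
        if not wanted:
            hits = []
        return hits[:max_results] if max_results is not None else hits


class EntrezBackend(RetrievalBackend):
    """Live NCBI eSearch backend (network required).

    Pages through results with retstart/retmax until the reported Count
    is exhausted or ``max_results`` is hit, retries transient HTTP
    failures up to ``retries`` times, and sleeps ``delay`` seconds
    between requests (NCBI etiquette: ≤ 3 requests/s without an API
    key).  The query is forwarded verbatim.
    """

    label = "live-eutils"
    BASE_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

    def __init__(
        self,
        api_key: str | None = None,
        page_size: int = 10_000,
        retries: int = 3,
        delay: float = 0.34,
        timeout: float = 30.0,
    ):
        self.api_key = api_key
        self.page_size = page_size
        self.retries = retries
        self.delay = delay
        self.timeout = timeout

    def _build_url(
        self,
        query: str,
        retstart: int,
        retmax: int,
        min_date: _dt.date | None,
    ) -> str:
        params = {
            "db": "pubmed",
            "term": query,
            "retmode": "xml",
            "retstart": str(retstart),
            "retmax": str(retmax),
        }
        if min_date is not None:
            params["datetype"] = "pdat"
            params["mindate"] = min_date.strftime("%Y/%m/%d")
            params["maxdate"] = "3000"
        if self.api_key:
            params["api_key"] = self.api_key
        return f"{self.BASE_URL}?{urllib.parse.urlencode(params)}"

    def _fetch(self, url: str) -> bytes:
        last: Exception | None = None
        for attempt in range(self.retries):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read()
            except Exception as exc:  # URLError, HTTPError, timeout
                last = exc
                logger.warning("eSearch attempt %d failed: %s", attempt + 1, exc)
                time.sleep(self.delay * (attempt + 1))
        raise RetrievalError(f"eSearch failed after {self.retries} attempts: {last}")

    def search(
        self,
        query: str,
        max_results: int | None = None,
        min_date: _dt.date | None = None,
    ) -> list[int]:
        pmids: list[int] = []
        retstart = 0
        count = None
        while True:
            retmax = self.page_size
            if max_results is not None:
                retmax = min(retmax, max_results - len(pmids))
                if retmax <= 0:
                    break
            data = self._fetch(self._build_url(query, retstart, retmax, min_date))
            root = etree.fromstring(data)
            if count is None:
                count = int(root.findtext("Count") or "0")
            page = [int(e.text) for e in root.findall("IdList/Id") if e.text]
            pmids.extend(page)
            retstart += len(page)
            if not page or retstart >= count:
                break
            time.sleep(self.delay)
        return pmids


_BACKENDS = {"fixture": FixtureBackend, "live": EntrezBackend, "live-eutils": EntrezBackend}


def get_backend(label: str, **kwargs) -> RetrievalBackend:
    """Instantiate a backend by label (``fixture`` needs ``records=``)."""
    try:
        cls = _BACKENDS[label]
    except KeyError:
        raise ValueError(
            f"unknown backend {label!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)


def retrieve_pmids(
    query: str,
    backend: RetrievalBackend,
    max_results: int | None = None,
    min_date: _dt.date | None = None,
) -> QueryResult:
    """Run *query* through *backend* and wrap deduplicated PMIDs.

    Duplicates are removed keeping first occurrence; the result records
    which backend produced it and when.
    """
    if not query:
        raise ValueError("query must be non-empty")
    raw = backend.search(query, max_results=max_results, min_date=min_date)
    seen: set[int] = set()
    pmids = []
    for p in raw:
        if p not in seen:
            seen.add(p)
            pmids.append(p)
    return QueryResult(
        query=query,
        pmids=tuple(pmids),
        backend=backend.label,
        retrieved_at=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    )
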