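"""Synthetic corpora with planted query–disease enrichment.

Stands in for a MeSH-annotated bibliographic corpus so the whole
pipeline is testable offline.  Each synthetic publication receives

* a uniform-random date in the configured range,
* a disease-heading set drawn without replacement from a multinomial
  background (Zipf-profiled by default — literature disease frequencies
  are heavy-tailed),
* and, when assigned to a planted query, that query's token in its
  title with the target diseases' weights multiplied by the enrichment
  factor and renormalized.

Everything is deterministic given the spec's seed: the same spec
serializes to byte-identical XML.  A companion generator emits noisy
curated-association tables (two sources, sampled publication counts)
from the planted ground truth so the gold-standard criteria can be
exercised end to end.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .evaluation import CuratedAssociation
from .medline import PublicationRecord
from .vocabulary import MeshDescriptor

__all__ = [
    "PlantedQuery",
    "CorpusSpec",
    "SyntheticCorpus",
    "zipf_weights",
    "generate_records",
    "generate_corpus",
    "synthetic_vocabulary",
    "generate_gold_standard",
]

_FILLER_WORDS = (
    "observational", "cohort", "registry", "longitudinal", "clinical",
    "retrospective", "prospective", "multicenter", "surveillance", "case",
)

_BRANCHES = tuple(f"C{i:02d}" for i in range(1, 27))


@dataclass(frozen=True)
class PlantedQuery:
    """One planted query: a title token enriched for target diseases."""

    token: str
    target_diseases: tuple[str, ...]
    multiplier: float = 8.0
    n_query_pubs: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_diseases", tuple(self.target_diseases))
        if self.multiplier < 1:
            raise ValueError("enrichment multiplier must be ≥ 1")
        if self.n_query_pubs < 1:
            raise ValueError("n_query_pubs must be ≥ 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus."""

    n_diseases: int = 50
    n_publications: int = 2000
    background_weights: Optional[tuple[float, ...]] = None
    diseases_per_pub: tuple[int, int] = (1, 3)
    planted_queries: tuple[PlantedQuery, ...] = ()
    seed: int = 0
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(1980, 1, 1), _dt.date(2016, 12, 31))

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_queries", tuple(self.planted_queries))
        if self.n_diseases < 1 or self.n_publications < 1:
            raise ValueError("n_diseases and n_publications must be ≥ 1")
        lo, hi = self.diseases_per_pub
        if not 1 <= lo <= hi <= self.n_diseases:
            raise ValueError("diseases_per_pub range must satisfy 1 ≤ lo ≤ hi ≤ n_diseases")
        if self.background_weights is not None:
            w = np.asarray(self.background_weights, dtype=float)
            if len(w) != self.n_diseases:
                raise ValueError("background_weights length must equal n_diseases")
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("background_weights must be non-negative, not all zero")
            object.__setattr__(self, "background_weights", tuple(w))
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start must precede end")
        total_planted = sum(q.n_query_pubs for q in self.planted_queries)
        if total_planted > self.n_publications:
            raise ValueError("planted query publications exceed corpus size")


def zipf_weights(n: int) -> np.ndarray:
    """Normalized 1/rank profile — the default heavy-tailed background."""
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def disease_name(i: int) -> str:
    """Name of the i-th (0-based) synthetic disease, most frequent first."""
    return f"Synthetic Condition {i + 1:03d}"


def synthetic_vocabulary(spec: CorpusSpec) -> list[MeshDescriptor]:
    """A matching descriptor vocabulary; every disease passes the
    default branch filter (tree numbers cycle through C01–C26)."""
    out = []
    for i in range(spec.n_diseases):
        branch = _BRANCHES[i % len(_BRANCHES)]
        out.append(
            MeshDescriptor(
                name=disease_name(i),
                ui=f"DSYN{i + 1:06d}",
                tree_numbers=(f"{branch}.{100 + i}",),
            )
        )
    return out


@dataclass
class SyntheticCorpus:
    """Generated corpus bundle: records, vocabulary, XML, ground truth."""

    spec: CorpusSpec
    records: list[PublicationRecord]
    vocabulary: list[MeshDescriptor]
    truth: tuple[PlantedQuery, ...]

    @property
    def xml(self) -> str:
        from .medline import write_medline_xml

        return write_medline_xml(self.records)


def _boosted_weights(
    base: np.ndarray, target_idx: np.ndarray, multiplier: float
) -> np.ndarray:
    boosted = base.copy()
    boosted[target_idx] *= multiplier
    total = boosted.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("enrichment multiplier degenerates the weight renormalization")
    boosted /= total
    # All-mass-on-targets degeneracy: drawing without replacement needs
    # enough strictly positive weight outside the targets.
    if boosted[target_idx].sum() > 1 - 1e-12 and len(target_idx) < len(base):
        raise ValueError("enrichment multiplier degenerates the weight renormalization")
    return boosted


def generate_records(spec: CorpusSpec) -> tuple[list[PublicationRecord], tuple[PlantedQuery, ...]]:
    """Draw the corpus as in-memory publication records.

    Deterministic given ``spec.seed``.  Returns the records and the
    ground truth (the planted queries themselves: token → target
    diseases and multiplier).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_diseases
    base = (
        np.asarray(spec.background_weights, dtype=float)
        if spec.background_weights is not None
        else zipf_weights(n)
    )
    base = base / base.sum()
    names = [disease_name(i) for i in range(n)]
    name_to_idx = {nm: i for i, nm in enumerate(names)}

    # Precompute per-query boosted weight vectors (validates degeneracy).
    boosted: list[np.ndarray] = []
    for q in spec.planted_queries:
        idx = np.array([name_to_idx[d] for d in q.target_diseases], dtype=int)
        boosted.append(_boosted_weights(base, idx, q.multiplier))

    # Assign planted publications to disjoint random subsets.
    assignment = np.full(spec.n_publications, -1, dtype=int)
    perm = rng.permutation(spec.n_publications)
    offset = 0
    for qi, q in enumerate(spec.planted_queries):
        assignment[perm[offset : offset + q.n_query_pubs]] = qi
        offset += q.n_query_pubs

    start, end = spec.date_range
    n_days = (end - start).days
    lo, hi = spec.diseases_per_pub
    records: list[PublicationRecord] = []
    for pub in range(spec.n_publications):
        pmid = pub + 1
        date = start + _dt.timedelta(days=int(rng.integers(0, n_days + 1)))
        size = int(rng.integers(lo, hi + 1))
        qi = assignment[pub]
        weights = boosted[qi] if qi >= 0 else base
        chosen = rng.choice(n, size=size, replace=False, p=weights)
        headings = tuple(names[i] for i in sorted(chosen))
        w1, w2 = rng.choice(len(_FILLER_WORDS), size=2, replace=False)
        title = f"{_FILLER_WORDS[w1]} {_FILLER_WORDS[w2]} record {pmid}"
        if qi >= 0:
            title = f"{spec.planted_queries[qi].token} {title}"
        records.append(
            PublicationRecord(
                pmid=pmid, date=date, mesh_headings=headings, title=title
            )
        )
    return records, spec.planted_queries


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate the full bundle (records, vocabulary, ground truth)."""
    records, truth = generate_records(spec)
    return SyntheticCorpus(
        spec=spec,
        records=records,
        vocabulary=synthetic_vocabulary(spec),
        truth=truth,
    )


def generate_gold_standard(
    truth: Sequence[PlantedQuery],
    noise: float = 0.0,
    seed: int = 0,
    unsupported_noise: Optional[float] = None,
) -> list[CuratedAssociation]:
    """Emit noisy two-source curated associations from the ground truth.

    Each planted (token, disease) pair starts present in both sources
    ("GAD" and "CTD_curated") with sampled publication counts ≥ 2.
    Independently per (pair, source), with probability *noise* the row
    is perturbed: half the time dropped, half the time its count set
    to 1 — exercising the distinctions among gold criteria 2–4.

    Pairs planted without real enrichment (multiplier 1) are perturbed
    with probability ``unsupported_noise`` (default 2.5 × noise, capped
    at 0.95): weakly evidenced claims get thinner curation support, the
    structure that drives the recall-up / precision-down trade-off
    across stricter criteria.

    Deterministic given *seed*; ``noise=0`` leaves every pair intact in
    both sources, making all four criteria coincide.
    """
    if not 0 <= noise < 1:
        raise ValueError("noise must lie in [0, 1)")
    if unsupported_noise is None:
        unsupported_noise = min(0.95, 2.5 * noise)
    if not 0 <= unsupported_noise < 1:
        raise ValueError("unsupported_noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[CuratedAssociation] = []
    for q in truth:
        p_noise = noise if q.multiplier > 1 else unsupported_noise
        for disease in q.target_diseases:
            for source in ("GAD", "CTD_curated"):
                count = int(2 + rng.poisson(3.0))
                if rng.random() < p_noise:
                    if rng.random() < 0.5:
                        continue  # drop this source's row
                    count = 1
                out.append(
                    CuratedAssociation(
                        term=q.token,
                        disease=disease,
                        source=source,
                        publication_count=count,
                        evidence="curated",
                    )
                )
    return out
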