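# Methods

## Model

`meshrank` treats disease discovery as an enrichment problem over a bipartite
publication–disease structure. The **link table** maps each publication (PMID)
to the set of disease MeSH descriptors it is indexed with, and each disease to
its publications. A publication enters the table when it is dated on or after
the minimum date (default 1960-01-01) and carries at least one heading that
resolves, by exact descriptor-name match, to a vocabulary descriptor passing
the **disease branch filter**: at least one tree number equal to or below
C01–C26, F02 or F03 (dot-boundary-aware prefix matching, so C260 never matches
C26), and a heading not among the four catch-all exclusions ("Disease",
"Disease Progression", "Disease Attributes", "Disease Models, Animal").
Repeated headings within a publication are deduplicated, so a PMID contributes
at most 1 to any disease's publication count `j`. `m` counts only
disease-bearing publications, because the statistic below conditions on
membership in the table.

For a query retrieving `n` in-table publications of which `k` involve disease
*D* (background `j` of `m`), the score is the negative decimal log of the
hypergeometric upper tail:

S_D = −log10 Σ_{i=k}^{min(n,j)} C(j,i)·C(m−j,n−i)/C(m,n).

Modelling assumptions worth stating explicitly:

* **Indexing is the evidence.** A publication "involves" a disease iff MeSH
  indexing says so; recall is bounded by the indexer's coverage, and
  un-indexed or very recent articles are invisible.
* **Random-draw null.** The null model treats the query's publications as an
  exchangeable random subset of the table. Query terms correlated with
  publication age or venue violate this mildly; the score is a ranking
  statistic, not a calibrated p-value (no multiple-testing correction is
  applied, deliberately).
* **One query, marginal scores.** Diseases are scored independently;
  co-annotation structure between diseases is ignored.

## Numerical evaluation of the tail

Scores of real queries reach the thousands (tail probabilities ~10^−1800), so
the tail is never formed in linear space. Each term's log is computed from
log-gamma binomial coefficients and the terms are combined by sequential
log-add-exp accumulation; terms below the support floor max(0, n+j−m) are
excluded analytically, and `k` at or below that floor returns log 1 = 0
exactly. The accumulated log-tail is clamped at 0 to absorb rounding above 1.
A `order="reverse"` switch re-runs the accumulation from the opposite end of
the index range; the two orders agree to better than 10⁻⁶ relative on the
extreme contingency (m = 10⁷, n = 10³, j = 10⁵, k = 800) and exist purely as a
stability check. Correctness is validated two independent ways: exhaustive
draw-enumeration in exact rational arithmetic over the full lattice m ≤ 12
(relative tolerance 10⁻⁹), and `scipy.stats.hypergeom.logsf` on moderate
contingencies — the SciPy routine is never the implementation.

Tie-breaking: the score orders primarily; equal scores order by `j` descending
(better-documented diseases first — the direction is a design choice, made
once), then by name ascending so every ranking is deterministic. Supporting
publications are listed most recent first (configurable).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_date` | 1960-01-01 | oldest publication admitted to the link table |
| branch prefixes | C01–C26, F02, F03 | MeSH tree branches counted as diseases |
| excluded names | the four catch-alls | headings dropped for lack of specificity |
| `min_pubs` | 2 | "more than 1 supporting publication" threshold in gold criteria 2 and 4 |
| `max_diseases` | unlimited | result-list cap in `prioritize` |
| `newest_first` | True | ordering of supporting publications |

## Synthetic corpora

The generator emulates the bipartite structure the method consumes, not the
text of real abstracts. Each publication gets a uniform-random date, between 1
and 3 disease headings drawn without replacement from a Zipf (1/rank)
background — literature disease frequencies are heavy-tailed — and, when
assigned to a planted query, that query's token in its title with the target
diseases' weights multiplied by the enrichment factor and renormalized.
Retrieval for fixtures is whole-token, case-insensitive matching over
title+abstract; this stands in for a search engine and makes retrieval a pure
function of (query, corpus). Everything is deterministic given the spec seed.

What the generator does **not** emulate: MeSH co-annotation correlations,
secular trends in publication volume, indexing depth differences across
journals, and query ambiguity (a real gene symbol can match journal names or
abbreviations). Passing synthetic benchmarks therefore demonstrates the
statistical machinery — not robustness to the messiness of live literature.

The companion gold-standard generator emits each planted (term, disease) pair
under two curation sources with sampled publication counts ≥ 2; per
(pair, source), with a configurable noise probability the row is dropped or its
count set to 1. Pairs planted without enrichment (multiplier 1 — "claimed but
unsupported" associations) are perturbed at 2.5× the noise rate (capped at
0.95): weakly evidenced claims get thinner curation support. That asymmetry is
what gives the four stringency criteria their realistic behaviour — stricter
criteria preferentially discard unsupported claims, so recall (against the
shrinking relevant set) rises while precision falls.

## Benchmarks

* **Rank recovery** (100 replicates): 2000 publications, 50 diseases, one
  planted query of 50 publications with 8× enrichment of a single target. The
  target is drawn from the top third of the frequency profile: curated
  benchmarks are built from well-studied associations, and a power analysis
  shows an 8× boost of a Zipf-tail disease (background weight ~0.004) yields
  an expected k ≈ 3 — statistically undetectable at this corpus size, so
  planting there would measure sampling noise, not the ranker. Expected
  behaviour: the target ranks first in ≥ 95% of replicates.
* **Null calibration** (100 replicates): identical setup with multiplier 1.
  The planted query is then a random publication subset, so the target's
  normalized rank is compared two-sample against matched pseudo-queries drawn
  from the same corpora (4 per replicate); the planted mean must sit inside
  the central 90% band of the null mean.
* **Criterion trade-off** (one corpus, 20 queries): 4000 publications, 100
  diseases; each query enriches 6 well-studied diseases (top-20 pool, 8×) and
  claims 4 more without enrichment; gold tables sampled at noise 0.3; metrics
  on the top-10 retrieved diseases, MAP on full lists against criterion 1.
  Twenty queries keep the criterion-1 → criterion-4 direction (precision down,
  recall up) clear of Monte Carlo noise. These sizes run the whole benchmark
  suite in well under a minute on one CPU.

## Degenerate inputs and edge conventions

* Empty retrieval or no query PMIDs in the table → empty ranking (logged, not
  an error); an empty link table is an error.
* Empty retrieved list in set metrics → p = r = F = 0; precision@k keeps the
  fixed denominator k for short lists; relevant-but-unretrieved items
  contribute 0 to average precision.
* Gold evidence codes ("therapeutic") and excluded MeSH headings match
  case-sensitively — MeSH headings and CTD-style codes are canonical strings.
* Enrichment multipliers that push essentially all renormalized weight onto
  the targets are rejected as degenerate configuration.
* Reported F per criterion is the mean of per-query F values, not the F of
  mean precision and recall.

## Known limitations

* Name-based heading↔descriptor matching assumes one MeSH release for corpus
  and vocabulary; cross-release name changes would silently drop headings
  (the count of unmatched headings is logged).
* The live E-utilities backend forwards queries verbatim and is intentionally
  minimal (paging, bounded retries, politeness delay); it is not exercised by
  the offline test suite.
* The link-table builder is in-memory and suited to fixture- and
  evaluation-scale corpora, not to rebuilding a production table of tens of
  millions of records.
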