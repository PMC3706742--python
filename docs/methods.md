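# Methods

## Task and data model

The task is paper-centric GO term assignment: given a free text, rank the
GO terms a curator would attach to that publication. Gene-product columns
of annotation files are deliberately discarded; the unit of curation is the
triple *(GO id; PMID; annotation year)*. Annotation dates are treated as
creation dates (updates are ignored); when the same (GO id, PMID) pair
appears with several dates, the earliest year is kept so that temporal
filtering errs on the side of a smaller historical knowledge base.

Temporal semantics: "the knowledge base as of 1 January of year Y" keeps
exactly the triples with year < Y. A benchmark for year Y samples documents
*published* in Y; their PMIDs are removed from the retrieval index, so a
query can never retrieve itself even if some of its annotations predate Y.

## Text pipeline

Both classifiers share one pipeline: lowercase, split on non-alphanumeric
characters, drop tokens shorter than 2 characters, remove stopwords, apply
the original (1980) Porter suffix-stripping algorithm. The stemmer is
implemented in-package from the published rule tables and verified against
the algorithm's classic example pairs. The stopword list is a frozen
~130-word general-English function-word list shipped with the package and
versioned (`STOPWORDS_VERSION`), because any change to it changes every
ranking the package produces.

## Retrieval

Okapi BM25 with k1 = 1.2 and b = 0.75 (the canonical defaults; both
configurable per index). The idf uses the +1-inside-the-log variant,
idf(t) = ln((N − df + 0.5)/(df + 0.5) + 1), which cannot go negative on
the few-document corpora the test fixtures use; at realistic corpus sizes
it is indistinguishable from the classic form. Repeated query tokens
contribute once per occurrence. Ranking ties are broken by ascending
document id so every ranking is exactly reproducible; search results are
invariant under document insertion order.

## k-NN classifier

The k = 200 default follows the observation that performance is stable for
k between roughly 100 and 250 on MEDLINE-scale knowledge bases. Votes are
similarity-weighted by default; `vote="uniform"` switches to plain counts
(the weighted variant degrades to counting when similarities are flat).
Scores are normalized by the total similarity mass of the retrieved
neighbours, which makes them comparable across queries and directly usable
by the combiner. With multi-annotated neighbours the distinct-term scores
can sum to more than 1 (each neighbour votes once per term it carries);
in the single-annotation regime they partition the mass and sum to exactly
1. If fewer than k documents have positive similarity, all positive ones
are used without padding. Votes are not propagated to ontology ancestors:
the classifier predicts curated terms as curators assigned them.

## Thesaurus classifier

The vector-space module indexes each non-obsolete term's name and synonyms
(all scopes) as one small document; the query is the input text. The
regular-expression module compiles each name and EXACT synonym into a
pattern tolerant of (i) interchangeable runs of whitespace/hyphen/comma
between words, (ii) a plural "s" on the final word, (iii) absent
parenthesized qualifier words; patterns are anchored at word boundaries so
"host cell" never fires inside "ghost cells". Matched terms receive
1 + vs_score + 0.001·(longest matching pattern length) before a final
rescale to [0, 1]. The constants make the boost rank-dominant: since
vs scores live in [0, 1] and the length bonus is ≪ 1 for any realistic
term name, every matched term strictly outranks every unmatched term,
matched terms order by (vs score, pattern length), and unmatched terms
keep their vector-space order. Edit-distance matching was rejected: with
tens of thousands of patterns it is expensive and its false-positive
behaviour is untestable without a distance threshold, which no published
description provides.

## Score normalization and fusion

Runs are normalized by their maximum score with the lower anchor fixed at
0, not at the observed minimum: classifier scores have a natural zero (no
evidence), a run's weakest candidate still carries evidence, and this
choice makes normalization idempotent and lets a term absent from a run
contribute exactly 0. A single-item or all-equal run normalizes to 1.0
everywhere — presence in a run is evidence. The combiner computes
w·ml + (1−w)·tb on the union of the two term sets, w = 0.7 by default,
the mixing level at which the combined run improves on either input.

## Evaluation

MRR and macro-averaged Recall@k (k = 5, 20 by default), standard TREC
semantics: rank k is inclusive, recall is per-query and then averaged,
queries with an empty ranking score 0 rather than being dropped (the
benchmark size is fixed). The test suite cross-checks the module against
an independent file-based re-implementation of the reference evaluator's
recip_rank/recall_k measures on randomized TREC run/qrels files; generated
runs use distinct scores so the two evaluators' tie policies cannot
diverge. Run files are truncated at depth 100 (configurable).

## Synthetic data generator

The generator emulates a curated literature at desk scale. Defaults: 50
terms, 40 documents per term, 2.8 terms per document on average (the mean
curated-terms-per-abstract rate in GO annotation practice), 12-word
signature vocabularies, 500 background words, 120-token documents with 60%
of tokens drawn from the document's terms' signatures, annotation and
publication years uniform on 2006–2012, PMIDs above 900 000 000 to avoid
collision with real PubMed ids, GO accessions in the GO:09xxxxx range.
Pseudo-words are consonant-vowel syllable strings screened to be unique
*after* stemming and never stopwords, so signature disjointness survives
the token pipeline. One held-out document per term (single gold term, same
token model) forms the benchmark; an `inject_names` flag prepends the
term's name verbatim for testing the fuzzy matcher.

What the generator does not emulate: real syntax and discourse, synonymy
between surface forms and term names (signature words are shared between a
term's name and its documents, which is *more* favourable to the
vector-space route than real text, where term names rarely occur
literally), class imbalance, ontology growth across years, and obsolete
terms in the annotation stream. Passing recovery tests therefore
demonstrates correctness of the machinery, not expected performance on
MEDLINE; published-scale recall figures require the real GOA/MEDLINE
resources.

At the default conditions every classifier saturates (R20 = 1.0), so the
trend and degradation properties are exercised on deliberately sparser
worlds (signature fraction 0.15, 6 documents per term), where the smallest
historical knowledge base sits visibly below ceiling and growth is
measurable.

## Numerical and degenerate-input choices

- Obsolete terms stay in the ontology map (for alt_id resolution and
  audit) but are excluded from every classifier vocabulary and may not be
  rendered as indexable text.
- Synonyms are deduplicated against the primary name on
  whitespace-normalized lowercase text; a synonym line without a scope tag
  is RELATED (only EXACT is privileged anywhere).
- Only `is_a` edges are parsed; nothing traverses the graph.
- GAF rows without a PMID reference, with unparseable dates, or with
  malformed GO accessions are skipped (counted and logged, never fatal).
- An empty knowledge base yields an empty prediction with a warning, not
  an error; an empty gold set makes a query invalid (error).
- `ontology stats` counts non-obsolete terms only; "all synonyms" counts
  every scope.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the largest world is 2 000 documents × 120 tokens; brute-force BM25
cross-checks use corpora of at most 50 documents; the metric oracle uses
20 randomized run sets of up to 50 queries. The full suite completes in
well under a minute on one CPU.
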