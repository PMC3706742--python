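"""k-nearest-neighbour GO categorizer over the curated knowledge base.

A new text is assigned the GO terms most prevalent among its k most similar
already-curated abstracts.  Retrieval is BM25 over title+abstract; votes are
similarity-weighted by default (an unweighted variant is available), and
scores are normalized by the total similarity mass of the k neighbours so
they are comparable across queries and can feed the score combiner.

The classifier is closed-world: a GO term with no annotation in the
(temporally filtered) knowledge base can never be predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .kb import KnowledgeBase
from .predictions import Prediction, rank_terms
from .retrieval import InvertedIndex, search

logger = logging.getLogger(__name__)

DEFAULT_K = 200


@dataclass
class KnnConfig:
    k: int = DEFAULT_K
    exclude_pmids: frozenset[str] = field(default_factory=frozenset)
    vote: str = "weighted"  # "weighted" | "uniform"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.vote not in ("weighted", "uniform"):
            raise ValueError(f"unknown vote mode {self.vote!r}")
        self.exclude_pmids = frozenset(self.exclude_pmids)


def classify_knn(
    text: str,
    kb: KnowledgeBase,
    index: InvertedIndex,
    config: KnnConfig | None = None,
) -> list[Prediction]:
    """Rank GO terms for ``text`` by aggregating its neighbours' annotations.

    For each GO term t,  raw(t) = sum of vote weights of the neighbours
    annotated with t, and score(t) = raw(t) / total vote weight of all
    retrieved neighbours — so scores lie in (0, 1] and sum to at most 1
    (exactly 1 when every neighbour carries at least one annotation).
    If fewer than k documents score > 0, all positive-scoring neighbours
    are used.
    """
    if config is None:
        config = KnnConfig()
    if not kb.documents:
        logger.warning("k-NN classification against an empty knowledge base")
        return []
    neighbours = search(text, index, config.k, exclude=config.exclude_pmids)
    if not neighbours:
        return []
    gold_by_pmid: dict[str, set[str]] = {}
    for t in kb.triples:
        gold_by_pmid.setdefault(t.pmid, set()).add(t.go_id)
    total = 0.0
    raw: dict[str, float] = {}
    for pmid, sim in neighbours:
        weight = sim if config.vote == "weighted" else 1.0
        total += weight
        for go_id in gold_by_pmid.get(pmid, ()):
            raw[go_id] = raw.get(go_id, 0.0) + weight
    if total <= 0.0:
        return []
    return rank_terms({go_id: w / total for go_id, w in raw.items()})


@dataclass
class CoverageReport:
    """Per-term annotation counts, stratified by trainability.

    Terms with >= 10 knowledge-base instances are reliably learnable by the
    k-NN; those with 1-9 are hard; those with 0 are invisible to it (only
    the thesaurus route can reach them).
    """

    counts: dict[str, int]
    well_covered: frozenset[str]  # >= 10 instances
    sparse: frozenset[str]  # 1..9 instances
    uncovered: frozenset[str]  # 0 instances (needs an ontology)

    @property
    def strata_sizes(self) -> tuple[int, int, int]:
        return len(self.well_covered), len(self.sparse), len(self.uncovered)


def coverage_report(kb: KnowledgeBase, vocabulary=()) -> CoverageReport:
    """Count annotations per GO term and stratify at the 10-instance line.

    ``vocabulary`` (e.g. the ontology's non-obsolete term ids) supplies the
    terms that may have zero instances; without it the zero stratum is empty.
    """
    counts = kb.annotation_counts()
    vocab_ids = {t if isinstance(t, str) else t.id for t in vocabulary}
    for go_id in vocab_ids:
        counts.setdefault(go_id, 0)
    well = frozenset(g for g, c in counts.items() if c >= 10)
    sparse = frozenset(g for g, c in counts.items() if 1 <= c <= 9)
    uncovered = frozenset(g for g, c in counts.items() if c == 0)
    return CoverageReport(
        counts=counts, well_covered=well, sparse=sparse, uncovered=uncovered
    )
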