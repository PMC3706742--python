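"""MRR and macro-averaged Recall@k over runs vs. qrels; temporal simulation.

Metrics follow standard TREC semantics (as computed by trec_eval's
recip_rank and recall_k measures): the reciprocal rank of the first gold
term, and the per-query fraction of gold terms found in the top k, averaged
over queries (macro).  A query for which a classifier returns nothing
contributes 0 to every metric rather than being dropped — the benchmark
size is fixed.

``simulate_years`` drives the year-by-year replay: for each year Y the
knowledge base is restored to its 1-January-Y state, the index is rebuilt,
a benchmark of abstracts published in Y is sampled (and barred from
retrieval), and every classifier is scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

from .combiner import CombinerConfig, combine
from .kb import BenchmarkQuery, KnowledgeBase, build_benchmark, temporal_filter
from .knn import KnnConfig, classify_knn
from .ontology import Ontology
from .predictions import Prediction
from .retrieval import build_index
from .thesaurus import build_term_index, classify_tb

logger = logging.getLogger(__name__)

DEFAULT_KS = (5, 20)


@dataclass
class EvalResult:
    mrr: float
    recall_at: dict[int, float]
    n_queries: int


def reciprocal_rank(ranked: Sequence[str], gold: frozenset[str] | set[str]) -> float:
    """1/rank of the first gold term in the ranking; 0 if none appears."""
    for i, go_id in enumerate(ranked, start=1):
        if go_id in gold:
            return 1.0 / i
    return 0.0


def recall_at_k(
    ranked: Sequence[str], gold: frozenset[str] | set[str], k: int
) -> float:
    """|gold ∩ top-k| / |gold|; rank k itself counts as retrieved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not gold:
        raise ValueError("empty gold set: query is invalid")
    return len(set(ranked[:k]) & set(gold)) / len(gold)


def evaluate(
    runs: Mapping[str, Sequence[str] | Sequence[Prediction]],
    qrels: Mapping[str, frozenset[str] | set[str]],
    ks: Sequence[int] = DEFAULT_KS,
) -> EvalResult:
    """Macro-average MRR and Recall@k of per-query rankings against gold sets.

    ``runs`` values may be GO-id sequences or Prediction lists.  Every run
    query must have qrels; qrels queries missing from the run count as empty
    runs (scoring 0), keeping the denominator at the benchmark size.
    """
    for qid in runs:
        if qid not in qrels:
            raise KeyError(f"run query {qid!r} has no qrels entry")
    query_ids = sorted(qrels)
    n = len(query_ids)
    if n == 0:
        return EvalResult(mrr=0.0, recall_at={k: 0.0 for k in ks}, n_queries=0)
    mrr_sum = 0.0
    recall_sums = {k: 0.0 for k in ks}
    for qid in query_ids:
        ranking = runs.get(qid, ())
        ranked_ids = [
            p.go_id if isinstance(p, Prediction) else p for p in ranking
        ]
        gold = qrels[qid]
        mrr_sum += reciprocal_rank(ranked_ids, gold)
        for k in ks:
            recall_sums[k] += recall_at_k(ranked_ids, gold, k)
    return EvalResult(
        mrr=mrr_sum / n,
        recall_at={k: recall_sums[k] / n for k in ks},
        n_queries=n,
    )


@dataclass
class SimulationConfig:
    n_queries: int = 50
    seed: int = 0
    k: int = 200
    ks: tuple[int, ...] = DEFAULT_KS
    weight_ml: float = 0.7
    classifiers: tuple[str, ...] = ("ml", "tb", "combo")
    top: int = 100


@dataclass
class YearResult:
    year: int
    classifier: str
    result: EvalResult


def _run_classifiers(
    queries: Sequence[BenchmarkQuery],
    kb: KnowledgeBase,
    ontology: Ontology,
    config: SimulationConfig,
) -> dict[str, dict[str, list[Prediction]]]:
    """Run the requested classifiers over a benchmark against one KB state."""
    bench_pmids = frozenset(q.query_id for q in queries)
    doc_index = build_index(
        (pmid, kb.documents[pmid].text)
        for pmid in sorted(kb.documents)
        if pmid not in bench_pmids
    )
    term_index = build_term_index(ontology)
    knn_config = KnnConfig(k=config.k, exclude_pmids=bench_pmids)
    combo_config = CombinerConfig(weight_ml=config.weight_ml)
    need_ml = "ml" in config.classifiers or "combo" in config.classifiers
    need_tb = "tb" in config.classifiers or "combo" in config.classifiers
    runs: dict[str, dict[str, list[Prediction]]] = {
        name: {} for name in config.classifiers
    }
    for q in queries:
        ml = classify_knn(q.text, kb, doc_index, knn_config) if need_ml else []
        tb = classify_tb(q.text, ontology, term_index) if need_tb else []
        if "ml" in runs:
            runs["ml"][q.query_id] = ml[: config.top]
        if "tb" in runs:
            runs["tb"][q.query_id] = tb[: config.top]
        if "combo" in runs:
            runs["combo"][q.query_id] = combine(ml, tb, combo_config)[: config.top]
    return runs


def simulate_years(
    kb: KnowledgeBase,
    ontology_by_year: Mapping[int, Ontology],
    years: Sequence[int],
    config: SimulationConfig | None = None,
) -> list[YearResult]:
    """Replay the classifiers' historical states year by year.

    For each year Y: the knowledge base is cut to annotations created before
    Y, a benchmark of documents published in Y is sampled, the sampled PMIDs
    are excluded from retrieval, and each classifier is evaluated with the
    ontology release for Y.  Years lacking an ontology or enough benchmark
    documents are skipped with a warning.
    """
    if config is None:
        config = SimulationConfig()
    results: list[YearResult] = []
    for year in years:
        ontology = ontology_by_year.get(year)
        if ontology is None:
            logger.warning("year %d skipped: no ontology release", year)
            continue
        try:
            queries = build_benchmark(kb, year, config.n_queries, config.seed)
        except ValueError as exc:
            logger.warning("year %d skipped: %s", year, exc)
            continue
        past_kb = temporal_filter(kb, year)
        if not past_kb.documents:
            logger.warning("year %d skipped: empty knowledge base", year)
            continue
        runs = _run_classifiers(queries, past_kb, ontology, config)
        qrels = {q.query_id: q.gold_terms for q in queries}
        for name in config.classifiers:
            result = evaluate(runs[name], qrels, config.ks)
            results.append(YearResult(year=year, classifier=name, result=result))
    return results


def write_results_table(results: Sequence[YearResult], stream: IO[str]) -> None:
    """TSV: year, classifier, n, MRR, then one R column per cutoff."""
    ks = sorted({k for r in results for k in r.result.recall_at})
    header = ["year", "classifier", "n", "MRR"] + [f"R{k}" for k in ks]
    stream.write("\t".join(header) + "\n")
    for r in results:
        row = [str(r.year), r.classifier, str(r.result.n_queries),
               f"{r.result.mrr:.4f}"]
        row += [f"{r.result.recall_at.get(k, 0.0):.4f}" for k in ks]
        stream.write("\t".join(row) + "\n")
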