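"""Curated-abstract knowledge base built from GAF annotations.

The knowledge-base atom is the three-tuple (GO id; PMID; annotation year):
the task is paper-centric, so gene-product columns of the GAF are discarded
and only manual curation linked to a PMID is kept.  Annotation dates are
treated as creation dates; on duplicate (GO id, PMID) pairs the earliest year
wins, which makes temporal filtering conservative.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

from .ontology import GO_ID_RE, Ontology

logger = logging.getLogger(__name__)

_PMID_REF_RE = re.compile(r"\bPMID:(\d+)\b")
_DATE_RE = re.compile(r"^(\d{4})[/-]?(\d{2})[/-]?(\d{2})$")


@dataclass(frozen=True)
class AnnotationTriple:
    go_id: str
    pmid: str
    year: int
    evidence_code: str = ""

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.go_id):
            raise ValueError(f"not a GO accession: {self.go_id!r}")
        if not 1000 <= self.year <= 9999:
            raise ValueError(f"annotation year must be 4-digit, got {self.year}")


@dataclass
class CuratedDocument:
    pmid: str
    pub_year: int
    title: str
    abstract: str
    gold_terms: frozenset[str] = frozenset()

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()

    @property
    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())


@dataclass(frozen=True)
class BenchmarkQuery:
    """One evaluation unit: a document's text and its gold GO-term set."""

    query_id: str
    text: str
    gold_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gold_terms:
            raise ValueError(f"benchmark query {self.query_id} has no gold terms")


@dataclass
class KnowledgeBase:
    documents: dict[str, CuratedDocument] = field(default_factory=dict)
    triples: set[AnnotationTriple] = field(default_factory=set)
    cutoff_year: int | None = None

    def validate(self) -> None:
        for t in self.triples:
            if t.pmid not in self.documents:
                raise ValueError(f"triple references unknown pmid {t.pmid}")
        if self.cutoff_year is not None:
            bad = [t for t in self.triples if t.year >= self.cutoff_year]
            if bad:
                raise ValueError(
                    f"{len(bad)} triples at/after cutoff {self.cutoff_year}"
                )
        pairs = {(t.go_id, t.pmid) for t in self.triples}
        if len(pairs) != len(self.triples):
            raise ValueError("duplicate (go_id, pmid) pairs in knowledge base")

    def terms_for(self, pmid: str) -> frozenset[str]:
        return frozenset(t.go_id for t in self.triples if t.pmid == pmid)

    def annotation_counts(self) -> dict[str, int]:
        """GO id -> number of PMIDs annotated with it."""
        counts: dict[str, int] = {}
        for t in self.triples:
            counts[t.go_id] = counts.get(t.go_id, 0) + 1
        return counts

    def triples_per_pmid(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.triples:
            counts[t.pmid] = counts.get(t.pmid, 0) + 1
        return counts


def parse_gaf(
    stream: IO[str] | str,
    ontology: Ontology | None = None,
) -> tuple[list[AnnotationTriple], int]:
    """Parse GAF 2.x rows into annotation triples.

    Keeps only rows whose reference column (column 6) carries a PMID; GO ids
    are normalized through the ontology's alt_id map when an ontology is
    given.  Dates (column 14) may be YYYYMMDD or with / or - separators.
    Duplicate (go_id, pmid) pairs collapse to the earliest year.

    Returns (triples, number of rows skipped for unparseable dates).
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    best: dict[tuple[str, str], AnnotationTriple] = {}
    skipped = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 14:
            logger.warning("GAF line %d: only %d columns, skipped", lineno, len(cols))
            skipped += 1
            continue
        go_id, reference, evidence, date = cols[4], cols[5], cols[6], cols[13]
        m = _PMID_REF_RE.search(reference)
        if not m:
            continue  # not PMID-linked curation (e.g. GO_REF:...)
        pmid = m.group(1)
        dm = _DATE_RE.match(date.strip())
        if not dm:
            logger.warning("GAF line %d: unparseable date %r, skipped", lineno, date)
            skipped += 1
            continue
        year = int(dm.group(1))
        if ontology is not None:
            go_id = ontology.resolve(go_id)
        try:
            triple = AnnotationTriple(go_id, pmid, year, evidence_code=evidence)
        except ValueError as exc:
            logger.warning("GAF line %d: %s, skipped", lineno, exc)
            skipped += 1
            continue
        key = (triple.go_id, pmid)
        if key not in best or triple.year < best[key].year:
            best[key] = triple
    return list(best.values()), skipped


def read_abstract_store(stream: IO[str] | str) -> dict[str, CuratedDocument]:
    """Read the abstract-store TSV: pmid, pub_year, title, abstract.

    One record per line, no header; embedded newlines escaped as ``\\n``.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    documents: dict[str, CuratedDocument] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ValueError(
                f"abstract store line {lineno}: expected 4 columns, got {len(cols)}"
            )
        pmid, year_s, title, abstract = cols
        try:
            pub_year = int(year_s)
        except ValueError:
            raise ValueError(
                f"abstract store line {lineno}: bad publication year {year_s!r}"
            ) from None
        documents[pmid] = CuratedDocument(
            pmid=pmid,
            pub_year=pub_year,
            title=title.replace("\\n", "\n"),
            abstract=abstract.replace("\\n", "\n"),
        )
    return documents


def write_abstract_store(documents: Iterable[CuratedDocument], stream: IO[str]) -> None:
    for doc in documents:
        for text in (doc.title, doc.abstract):
            if "\t" in text:
                raise ValueError(f"embedded tab in record {doc.pmid}")
        title = doc.title.replace("\n", "\\n")
        abstract = doc.abstract.replace("\n", "\\n")
        stream.write(f"{doc.pmid}\t{doc.pub_year}\t{title}\t{abstract}\n")


def assemble(
    documents: Mapping[str, CuratedDocument],
    triples: Iterable[AnnotationTriple],
) -> KnowledgeBase:
    """Join triples with the abstract store; attach gold terms to documents.

    Triples whose PMID has no stored document are dropped with a warning
    (the store stands in for the MEDLINE download and may lag the GAF).
    """
    kept: set[AnnotationTriple] = set()
    missing = 0
    by_pmid: dict[str, set[str]] = {}
    for t in triples:
        if t.pmid not in documents:
            missing += 1
            continue
        kept.add(t)
        by_pmid.setdefault(t.pmid, set()).add(t.go_id)
    if missing:
        logger.warning("%d triples dropped: PMID not in abstract store", missing)
    docs = {
        pmid: replace(doc, gold_terms=frozenset(by_pmid.get(pmid, ())))
        for pmid, doc in documents.items()
        if pmid in by_pmid
    }
    kb = KnowledgeBase(documents=docs, triples=kept)
    kb.validate()
    return kb


def temporal_filter(kb: KnowledgeBase, cutoff_year: int) -> KnowledgeBase:
    """Restore the knowledge base to its state on 1 January of ``cutoff_year``.

    Keeps exactly the triples with annotation year < cutoff_year; documents
    with no surviving triple are removed.  Idempotent and monotone in the
    cutoff.
    """
    if not 1000 <= cutoff_year <= 9999:
        raise ValueError(f"cutoff_year must be a 4-digit year, got {cutoff_year}")
    kept = {t for t in kb.triples if t.year < cutoff_year}
    by_pmid: dict[str, set[str]] = {}
    for t in kept:
        by_pmid.setdefault(t.pmid, set()).add(t.go_id)
    docs = {
        pmid: replace(doc, gold_terms=frozenset(by_pmid[pmid]))
        for pmid, doc in kb.documents.items()
        if pmid in by_pmid
    }
    return KnowledgeBase(documents=docs, triples=kept, cutoff_year=cutoff_year)


def build_benchmark(
    kb: KnowledgeBase,
    pub_year: int,
    n: int,
    seed: int,
    require_abstract: bool = True,
) -> list[BenchmarkQuery]:
    """Sample n documents published in ``pub_year`` as evaluation queries.

    Sampling is uniform without replacement under ``seed``.  Documents with
    an empty abstract are excluded by default (title-only records make
    degenerate queries).  The caller must exclude the sampled PMIDs from the
    retrieval index — they are the held-out "just published" abstracts.
    """
    eligible = [
        doc
        for doc in kb.documents.values()
        if doc.pub_year == pub_year
        and doc.gold_terms
        and (doc.has_abstract or not require_abstract)
    ]
    if len(eligible) < n:
        raise ValueError(
            f"requested {n} benchmark documents for {pub_year}, "
            f"only {len(eligible)} eligible"
        )
    eligible.sort(key=lambda d: d.pmid)
    rng = random.Random(seed)
    sample = rng.sample(eligible, n)
    return [
        BenchmarkQuery(query_id=d.pmid, text=d.text, gold_terms=d.gold_terms)
        for d in sample
    ]


def write_qrels(queries: Iterable[BenchmarkQuery], stream: IO[str]) -> None:
    """TREC qrels format: <query id> 0 <GO id> 1."""
    for q in queries:
        for go_id in sorted(q.gold_terms):
            stream.write(f"{q.query_id} 0 {go_id} 1\n")


def read_qrels(stream: IO[str] | str) -> dict[str, frozenset[str]]:
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    gold: dict[str, set[str]] = {}
    for line in lines:
        if not line.strip():
            continue
        qid, _zero, docid, rel = line.split()
        if int(rel) > 0:
            gold.setdefault(qid, set()).add(docid)
    return {qid: frozenset(terms) for qid, terms in gold.items()}
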