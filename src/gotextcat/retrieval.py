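"""Tokenization, inverted indexing and Okapi BM25 ranked retrieval.

This is the "related article search engine" both classifiers sit on: curated
abstracts (title + abstract) for the k-NN route, GO term texts for the
thesaurus route.  The pipeline is lowercase -> split on non-alphanumeric ->
drop length-1 tokens -> stopword removal -> Porter stemming, applied
identically to documents and queries.

BM25 uses the +1-inside-log idf variant,

    idf(t) = ln((N - df + 0.5) / (df + 0.5) + 1),

which stays positive on tiny corpora, with the canonical defaults k1 = 1.2
and b = 0.75 for term-frequency saturation and length normalization.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .porter import stem
from .stopwords import STOPWORDS, STOPWORDS_VERSION

_SPLIT_RE = re.compile(r"[^0-9a-z]+")

INDEX_FORMAT_VERSION = 1

DEFAULT_K1 = 1.2
DEFAULT_B = 0.75


def tokenize(text: str) -> list[str]:
    """Normalize free text to a stemmed, stopped token sequence."""
    tokens = []
    for raw in _SPLIT_RE.split(text.lower()):
        if len(raw) < 2:
            continue
        if raw in STOPWORDS:
            continue
        tokens.append(stem(raw))
    return tokens


@dataclass
class InvertedIndex:
    """Token -> postings map over a fixed document collection.

    postings[token] is a list of (doc_id, term frequency); doc order within
    a postings list follows insertion order of build_index, which together
    with the deterministic tie-break in :func:`search` makes rankings
    reproducible.
    """

    postings: dict[str, list[tuple[str, int]]]
    doc_lengths: dict[str, int]
    k1: float = DEFAULT_K1
    b: float = DEFAULT_B

    @property
    def doc_count(self) -> int:
        return len(self.doc_lengths)

    @property
    def avg_doc_length(self) -> float:
        if not self.doc_lengths:
            return 0.0
        return sum(self.doc_lengths.values()) / len(self.doc_lengths)

    def idf(self, token: str) -> float:
        df = len(self.postings.get(token, ()))
        n = self.doc_count
        return math.log((n - df + 0.5) / (df + 0.5) + 1.0)

    def save(self, stream: IO[str]) -> None:
        header = {
            "format": "gotextcat-index",
            "version": INDEX_FORMAT_VERSION,
            "stopwords_version": STOPWORDS_VERSION,
            "k1": self.k1,
            "b": self.b,
        }
        stream.write(json.dumps(header) + "\n")
        for doc_id, length in self.doc_lengths.items():
            stream.write(json.dumps({"doc": doc_id, "len": length}) + "\n")
        for token, plist in self.postings.items():
            stream.write(json.dumps({"tok": token, "post": plist}) + "\n")

    @classmethod
    def load(cls, stream: IO[str]) -> "InvertedIndex":
        header = json.loads(stream.readline())
        if header.get("format") != "gotextcat-index":
            raise ValueError("not a gotextcat index file")
        if header.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index version {header.get('version')}")
        index = cls(postings={}, doc_lengths={},
                    k1=header.get("k1", DEFAULT_K1), b=header.get("b", DEFAULT_B))
        for line in stream:
            if not line.strip():
                continue
            rec = json.loads(line)
            if "doc" in rec:
                index.doc_lengths[rec["doc"]] = rec["len"]
            else:
                index.postings[rec["tok"]] = [tuple(p) for p in rec["post"]]
        return index


def build_index(
    documents: Iterable[tuple[str, str]],
    k1: float = DEFAULT_K1,
    b: float = DEFAULT_B,
) -> InvertedIndex:
    """Index (doc_id, text) pairs.  Doc ids must be unique."""
    postings: dict[str, list[tuple[str, int]]] = {}
    doc_lengths: dict[str, int] = {}
    for doc_id, text in documents:
        if doc_id in doc_lengths:
            raise ValueError(f"duplicate doc id {doc_id!r}")
        tokens = tokenize(text)
        doc_lengths[doc_id] = len(tokens)
        tf: dict[str, int] = {}
        for token in tokens:
            tf[token] = tf.get(token, 0) + 1
        for token, count in tf.items():
            postings.setdefault(token, []).append((doc_id, count))
    return InvertedIndex(postings=postings, doc_lengths=doc_lengths, k1=k1, b=b)


def bm25_score(
    query_tokens: Sequence[str],
    doc_id: str,
    index: InvertedIndex,
) -> float:
    """Okapi BM25 score of one document against a tokenized query."""
    if doc_id not in index.doc_lengths:
        raise KeyError(f"unknown doc id {doc_id!r}")
    avgdl = index.avg_doc_length
    dl = index.doc_lengths[doc_id]
    score = 0.0
    for token in query_tokens:
        tf = 0
        for did, count in index.postings.get(token, ()):
            if did == doc_id:
                tf = count
                break
        if tf == 0:
            continue
        norm = index.k1 * (1.0 - index.b + index.b * dl / avgdl) if avgdl else index.k1
        score += index.idf(token) * tf * (index.k1 + 1.0) / (tf + norm)
    return score


def search(
    query_text: str,
    index: InvertedIndex,
    top_n: int,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Rank documents by BM25 against the query text.

    Returns up to ``top_n`` documents with positive score, sorted by score
    descending with ties broken by ascending doc id.  ``exclude`` bars
    documents from the result (the benchmark leakage guard).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    query = tokenize(query_text)
    if not query or not index.doc_count:
        return []
    avgdl = index.avg_doc_length
    k1, b = index.k1, index.b
    # term-at-a-time accumulation over postings; repeated query tokens
    # contribute multiplicatively, as in the per-document formula
    qtf: dict[str, int] = {}
    for token in query:
        qtf[token] = qtf.get(token, 0) + 1
    scores: dict[str, float] = {}
    for token, count in qtf.items():
        plist = index.postings.get(token)
        if not plist:
            continue
        idf = index.idf(token)
        for doc_id, tf in plist:
            if doc_id in exclude:
                continue
            dl = index.doc_lengths[doc_id]
            norm = k1 * (1.0 - b + b * dl / avgdl) if avgdl else k1
            contrib = idf * tf * (k1 + 1.0) / (tf + norm)
            scores[doc_id] = scores.get(doc_id, 0.0) + count * contrib
    ranked = sorted(
        ((doc_id, s) for doc_id, s in scores.items() if s > 0.0),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:top_n]
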