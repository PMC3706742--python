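"""Thesaurus-based GO categorizer: term-text retrieval plus fuzzy matching.

Two cooperating components:

* a vector-space module — each non-obsolete GO term's text (name and
  synonyms by default) is indexed as a tiny document and ranked by BM25
  against the input text as the query;
* a regular-expression module — term names and EXACT synonyms are compiled
  into patterns tolerant of whitespace/hyphen/comma variation, a plural "s"
  on the final word, and parenthesized qualifiers; a firing pattern boosts
  its term above every unmatched term.

The boost is rank-dominant and deterministic: matched terms get
1 + vs_score + 0.001 * longest_match_pattern_length before a final rescale
to [0, 1], so matched terms strictly outrank unmatched ones, order among
themselves by (vector-space score, match length), and unmatched terms keep
their vector-space order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .ontology import Ontology, OntologyTerm, term_document
from .predictions import Prediction, as_predictions, rank_terms
from .retrieval import InvertedIndex, build_index, search

MATCH_LENGTH_WEIGHT = 0.001

DEFAULT_VS_FIELDS = ("name", "synonyms")


@dataclass(frozen=True)
class TermMatch:
    go_id: str
    matched_text: str
    matched_source: str
    match_length: int


def build_term_index(
    ontology: Ontology,
    fields: Iterable[str] = DEFAULT_VS_FIELDS,
) -> InvertedIndex:
    """Index every non-obsolete term's text for the vector-space module."""
    fields = tuple(fields)
    docs = [
        (term.id, term_document(term, fields))
        for term in sorted(ontology.active_terms(), key=lambda t: t.id)
    ]
    return build_index(docs)


def classify_vs(
    text: str,
    ontology: Ontology,
    term_index: InvertedIndex,
) -> list[Prediction]:
    """Rank GO terms by BM25 similarity of their text to the input.

    Scores are normalized to [0, 1] by the top score (zero is the natural
    floor); a single candidate scores 1.0.  Only terms with positive
    retrieval score appear.
    """
    ranked = search(text, term_index, top_n=max(term_index.doc_count, 1))
    if not ranked:
        return []
    hi = ranked[0][1]
    normalized = [(go_id, s / hi) for go_id, s in ranked]
    # re-sort: equal normalized scores must still tie-break by GO id
    normalized.sort(key=lambda item: (-item[1], item[0]))
    return as_predictions(normalized)


def _split_words(source: str) -> list[tuple[str, bool]]:
    """(word, inside-parentheses) pairs in surface order."""
    words: list[tuple[str, bool]] = []
    depth = 0
    for chunk in re.split(r"([()])", source):
        if chunk == "(":
            depth += 1
        elif chunk == ")":
            depth = max(depth - 1, 0)
        else:
            for w in re.split(r"[\s\-,]+", chunk):
                if w:
                    words.append((w, depth > 0))
    return words


def _compile_pattern(source: str) -> re.Pattern | None:
    """Compile one term name/synonym into its fuzzy-match pattern.

    Word separators (whitespace, hyphens, commas) are interchangeable and
    may repeat; parenthesized qualifier words are optional; the final word
    may take a plural "s".  Case-insensitive, anchored at word boundaries.
    """
    words = _split_words(source)
    if not words:
        return None
    if all(optional for _w, optional in words):
        # a fully parenthesized name has no mandatory skeleton; match it all
        words = [(w, False) for w, _ in words]
    sep = r"[\s\-,]+"
    pieces: list[str] = []
    started = False
    for i, (word, optional) in enumerate(words):
        escaped = re.escape(word)
        if i == len(words) - 1:
            escaped += "s?"
        if not started:
            if optional:
                pieces.append(f"(?:{escaped}{sep})?")
            else:
                pieces.append(escaped)
                started = True
        elif optional:
            pieces.append(f"(?:{sep}{escaped})?")
        else:
            pieces.append(sep + escaped)
    pattern = r"(?<![0-9a-zA-Z])" + "".join(pieces) + r"(?![0-9a-zA-Z])"
    try:
        return re.compile(pattern, re.IGNORECASE)
    except re.error:
        return None


def match_terms(text: str, ontology: Ontology) -> list[TermMatch]:
    """Recognize GO terms in free text via fuzzy surface matching.

    Patterns are generated from each non-obsolete term's name and EXACT
    synonyms; every firing yields one TermMatch, overlapping matches
    included.  ``match_length`` is the character count of the source
    name/synonym, used by the boost tie-break (longer patterns are more
    specific).
    """
    matches: list[TermMatch] = []
    for term in sorted(ontology.active_terms(), key=lambda t: t.id):
        sources = [term.name] + [
            syn for syn, scope in term.synonyms if scope == "EXACT"
        ]
        for source in sources:
            if not source:
                continue
            pattern = _compile_pattern(source)
            if pattern is None:
                continue
            for m in pattern.finditer(text):
                if not m.group(0):
                    continue
                matches.append(
                    TermMatch(
                        go_id=term.id,
                        matched_text=m.group(0),
                        matched_source=source,
                        match_length=len(source),
                    )
                )
    return matches


def classify_tb(
    text: str,
    ontology: Ontology,
    term_index: InvertedIndex,
) -> list[Prediction]:
    """Full thesaurus classifier: vector-space ranking with match boosting."""
    vs = classify_vs(text, ontology, term_index)
    matches = match_terms(text, ontology)
    if not matches:
        return vs
    best_match_len: dict[str, int] = {}
    for m in matches:
        if m.match_length > best_match_len.get(m.go_id, 0):
            best_match_len[m.go_id] = m.match_length
    scores = {p.go_id: p.score for p in vs}
    boosted: dict[str, float] = dict(scores)
    for go_id, length in best_match_len.items():
        base = scores.get(go_id, 0.0)
        boosted[go_id] = 1.0 + base + MATCH_LENGTH_WEIGHT * length
    if not boosted:
        return []
    hi = max(boosted.values())
    if hi <= 0.0:
        return []
    rescaled = {go_id: s / hi for go_id, s in boosted.items()}
    return rank_terms(rescaled)
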