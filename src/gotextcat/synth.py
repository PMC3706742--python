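"""Synthetic mini-ontologies and knowledge bases with known structure.

Every pipeline stage is testable offline: each synthetic GO term owns a
private "signature" vocabulary of pseudo-words, disjoint from every other
term's signature and from a shared background vocabulary.  A curated
document mixes tokens from its assigned terms' signatures (a configurable
fraction of the document) with background tokens, so the term-to-text
mapping is known exactly and parameter recovery can be measured: with fully
disjoint signatures and signature_fraction 1.0 the assignment is perfectly
recoverable; lowering the fraction degrades it smoothly.

Pseudo-words are consonant-vowel syllable strings screened so that no two
survive tokenization as the same stem and none is a stopword — the
generated vocabulary stays disjoint all the way through the retrieval
pipeline, not just on the page.

Defaults mirror the curation data the pipeline targets at desk scale:
2.8 GO terms per document on average, annotation years spread uniformly so
temporal cutoffs bite, synthetic PMIDs above 900000000 so fixtures can
never collide with real PubMed identifiers.
"""

from __future__ import annotations

import itertools
import os
import random
from dataclasses import dataclass, field

from .kb import (
    AnnotationTriple,
    BenchmarkQuery,
    CuratedDocument,
    KnowledgeBase,
    write_abstract_store,
    write_qrels,
)
from .ontology import Ontology, OntologyTerm, write_obo
from .porter import stem
from .stopwords import STOPWORDS

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aeiou"

PMID_BASE = 900000000
GO_ID_BASE = 900000  # synthetic accessions GO:0900001 ... stay clear of real ids


@dataclass
class SynthConfig:
    n_terms: int = 50
    n_synonyms_per_term: int = 2
    signature_vocab_size: int = 12
    background_vocab_size: int = 500
    docs_per_term: int = 40
    terms_per_doc: float = 2.8  # mean assigned terms per document (min 1)
    signature_fraction: float = 0.6
    doc_length: int = 120
    year_range: tuple[int, int] = (2006, 2012)
    seed: int = 0
    inject_names: bool = False  # held-out abstracts start with the term's name

    def __post_init__(self) -> None:
        if self.n_terms < 1 or self.docs_per_term < 1:
            raise ValueError("n_terms and docs_per_term must be >= 1")
        if self.signature_vocab_size < 3:
            raise ValueError("signature_vocab_size must be >= 3 (3-word names)")
        if not 0.0 < self.signature_fraction <= 1.0:
            raise ValueError("signature_fraction must be in (0, 1]")
        if self.terms_per_doc < 1.0:
            raise ValueError("terms_per_doc must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")
        n_phrases = self.n_synonyms_per_term + 1
        if _max_phrases(self.signature_vocab_size) < n_phrases:
            raise ValueError(
                f"signature vocabulary of {self.signature_vocab_size} words "
                f"cannot yield {n_phrases} distinct 3-word phrases"
            )


def _max_phrases(vocab: int) -> int:
    n = vocab * (vocab - 1) * (vocab - 2)
    return n


def _make_word(rng: random.Random, n_syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
        for _ in range(n_syllables)
    ) + rng.choice(_CONSONANTS)


def _word_pool(rng: random.Random, size: int) -> list[str]:
    """Distinct pseudo-words, unique under stemming, never stopwords."""
    words: list[str] = []
    seen_stems: set[str] = set()
    while len(words) < size:
        word = _make_word(rng, rng.choice((2, 3)))
        if word in STOPWORDS:
            continue
        s = stem(word)
        if s in seen_stems:
            continue
        seen_stems.add(s)
        words.append(word)
    return words


def _distinct_phrases(rng: random.Random, vocab: list[str], count: int) -> list[str]:
    """``count`` distinct 3-word phrases over a signature vocabulary."""
    phrases: set[tuple[str, ...]] = set()
    while len(phrases) < count:
        phrases.add(tuple(rng.sample(vocab, 3)))
    return [" ".join(p) for p in sorted(phrases)]


def generate(
    config: SynthConfig,
) -> tuple[Ontology, KnowledgeBase, list[BenchmarkQuery]]:
    """Build (ontology, knowledge base, held-out benchmark) from the config.

    * each term gets a disjoint signature vocabulary, a 3-word name and
      ``n_synonyms_per_term`` EXACT synonyms drawn from it;
    * each of ``n_terms * docs_per_term`` documents is assigned a primary
      term (each term primary in exactly ``docs_per_term`` documents) plus
      a Poisson(terms_per_doc - 1) count of extra terms; its tokens are
      drawn from its terms' signatures with probability
      ``signature_fraction`` and from the background otherwise;
    * one held-out document per term (single gold term, same token model)
      is generated and excluded from the knowledge base;
    * every (document, term) assignment becomes an annotation triple with a
      year uniform over ``year_range``.

    Fully reproducible: the same config (seed included) gives identical
    output.
    """
    rng = random.Random(config.seed)
    total_words = config.n_terms * config.signature_vocab_size + config.background_vocab_size
    pool = _word_pool(rng, total_words)
    signatures = [
        pool[i * config.signature_vocab_size:(i + 1) * config.signature_vocab_size]
        for i in range(config.n_terms)
    ]
    background = pool[config.n_terms * config.signature_vocab_size:]

    terms: list[OntologyTerm] = []
    for i, signature in enumerate(signatures):
        phrases = _distinct_phrases(rng, signature, config.n_synonyms_per_term + 1)
        rng.shuffle(phrases)
        terms.append(
            OntologyTerm(
                id=f"GO:{GO_ID_BASE + i + 1:07d}",
                name=phrases[0],
                namespace="biological_process",
                definition=f"Synthetic process number {i + 1}.",
                synonyms=[(p, "EXACT") for p in phrases[1:]],
            )
        )
    ontology = Ontology(terms, release_label=f"synthetic-seed{config.seed}")

    def sample_tokens(term_indices: list[int]) -> list[str]:
        sig_union = list(
            itertools.chain.from_iterable(signatures[t] for t in term_indices)
        )
        tokens = []
        for _ in range(config.doc_length):
            if rng.random() < config.signature_fraction:
                tokens.append(rng.choice(sig_union))
            else:
                tokens.append(rng.choice(background))
        return tokens

    def poisson(mean: float) -> int:
        # inverse-CDF sampling; means here are tiny
        if mean <= 0:
            return 0
        u = rng.random()
        p = pr = 2.718281828459045 ** (-mean)
        k = 0
        while u > p and k < 100:
            k += 1
            pr *= mean / k
            p += pr
        return k

    first_year, last_year = config.year_range
    documents: dict[str, CuratedDocument] = {}
    triples: set[AnnotationTriple] = set()
    pmid_counter = itertools.count(PMID_BASE + 1)
    for term_idx in range(config.n_terms):
        for _ in range(config.docs_per_term):
            pmid = str(next(pmid_counter))
            extras = poisson(config.terms_per_doc - 1.0)
            others = [t for t in range(config.n_terms) if t != term_idx]
            assigned = [term_idx] + rng.sample(others, min(extras, len(others)))
            tokens = sample_tokens(assigned)
            gold = frozenset(terms[t].id for t in assigned)
            documents[pmid] = CuratedDocument(
                pmid=pmid,
                pub_year=rng.randint(first_year, last_year),
                title=" ".join(tokens[:8]),
                abstract=" ".join(tokens[8:]),
                gold_terms=gold,
            )
            for t in assigned:
                triples.add(
                    AnnotationTriple(
                        go_id=terms[t].id,
                        pmid=pmid,
                        year=rng.randint(first_year, last_year),
                        evidence_code="IMP",
                    )
                )
    kb = KnowledgeBase(documents=documents, triples=triples)
    kb.validate()

    heldout: list[BenchmarkQuery] = []
    for term_idx in range(config.n_terms):
        pmid = str(next(pmid_counter))
        tokens = sample_tokens([term_idx])
        text = " ".join(tokens)
        if config.inject_names:
            text = terms[term_idx].name + " " + text
        heldout.append(
            BenchmarkQuery(
                query_id=pmid,
                text=text,
                gold_terms=frozenset({terms[term_idx].id}),
            )
        )
    return ontology, kb, heldout


@dataclass
class FixtureFiles:
    obo: str
    gaf: str
    abstracts: str
    qrels: str


def write_fixture_files(
    ontology: Ontology,
    kb: KnowledgeBase,
    heldout: list[BenchmarkQuery],
    directory: str,
) -> FixtureFiles:
    """Emit go.obo, annotations.gaf, abstracts.tsv and qrels.txt.

    These are the exact formats the real pipeline reads, so fixtures and
    real data share one code path.  Held-out query texts are appended to
    the abstract store (they carry no GAF rows, so knowledge-base assembly
    keeps them out of the index); their gold terms go to qrels.txt.
    """
    os.makedirs(directory, exist_ok=True)
    paths = FixtureFiles(
        obo=os.path.join(directory, "go.obo"),
        gaf=os.path.join(directory, "annotations.gaf"),
        abstracts=os.path.join(directory, "abstracts.tsv"),
        qrels=os.path.join(directory, "qrels.txt"),
    )
    with open(paths.obo, "w", encoding="utf-8") as fh:
        write_obo(ontology, fh)
    with open(paths.gaf, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for t in sorted(kb.triples, key=lambda t: (t.pmid, t.go_id)):
            cols = [
                "SYNTH", f"OBJ:{t.pmid}", f"S{t.pmid}", "",
                t.go_id, f"PMID:{t.pmid}", t.evidence_code or "IMP", "",
                "P", "", "", "protein", "taxon:0000",
                f"{t.year}0101", "synth", "", "",
            ]
            fh.write("\t".join(cols) + "\n")
    with open(paths.abstracts, "w", encoding="utf-8") as fh:
        write_abstract_store(
            (kb.documents[p] for p in sorted(kb.documents)), fh
        )
        heldout_year = max((t.year for t in kb.triples), default=2012)
        for q in heldout:
            tokens = q.text.split(" ")
            title = " ".join(tokens[:8])
            abstract = " ".join(tokens[8:])
            fh.write(f"{q.query_id}\t{heldout_year}\t{title}\t{abstract}\n")
    with open(paths.qrels, "w", encoding="utf-8") as fh:
        write_qrels(heldout, fh)
    return paths
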