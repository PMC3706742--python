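"""Gene Ontology flat-file (OBO 1.2) parsing and term-text access.

Only the information the classifiers consume is modelled: identifiers, names,
namespaces, definitions, scoped synonyms, ``is_a`` parents, ``alt_id`` merge
records and the obsolescence flag.  ``relationship:`` lines (part_of etc.) are
deliberately ignored — nothing here traverses the graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable

GO_ID_RE = re.compile(r"^GO:\d{7}$")

SYNONYM_SCOPES = ("EXACT", "RELATED", "BROAD", "NARROW")

#: fields selectable for term_document
TERM_TEXT_FIELDS = ("name", "synonyms", "definition")


class OboParseError(ValueError):
    """Raised for a malformed [Term] stanza; carries the stanza byte offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (stanza at byte offset {offset})")
        self.offset = offset


@dataclass
class OntologyTerm:
    id: str
    name: str = ""
    namespace: str = ""
    definition: str = ""
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    parents: frozenset[str] = frozenset()
    is_obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.id):
            raise ValueError(f"not a GO accession: {self.id!r}")
        if self.is_obsolete:
            # obsolete terms expose no parents to consumers
            self.parents = frozenset()
        # dedupe synonyms against the primary name and each other,
        # on whitespace-normalized lowercase text
        seen = {_norm(self.name)}
        kept = []
        for text, scope in self.synonyms:
            key = _norm(text)
            if key in seen:
                continue
            seen.add(key)
            kept.append((text, scope))
        self.synonyms = kept


def _norm(text: str) -> str:
    return " ".join(text.lower().split())


class Ontology:
    """Map of GO id -> OntologyTerm with alt_id resolution."""

    def __init__(self, terms: Iterable[OntologyTerm] = (), release_label: str = ""):
        self.terms: dict[str, OntologyTerm] = {}
        self.release_label = release_label
        self._alt: dict[str, str] = {}
        for term in terms:
            self.add(term)

    def add(self, term: OntologyTerm) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id}")
        self.terms[term.id] = term
        for alt in term.alt_ids:
            if alt in self._alt and self._alt[alt] != term.id:
                raise ValueError(f"alt_id {alt} maps to two primary ids")
            self._alt[alt] = term.id

    def resolve(self, go_id: str) -> str:
        """Map a possibly-merged accession to its surviving primary id."""
        if go_id in self.terms:
            return go_id
        return self._alt.get(go_id, go_id)

    def get(self, go_id: str) -> OntologyTerm | None:
        return self.terms.get(self.resolve(go_id))

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, go_id: str) -> bool:
        return self.resolve(go_id) in self.terms

    def __iter__(self):
        return iter(self.terms.values())

    def active_terms(self) -> list[OntologyTerm]:
        """Non-obsolete terms — the classifier vocabulary."""
        return [t for t in self.terms.values() if not t.is_obsolete]

    def validate(self) -> None:
        """Check that parents of non-obsolete terms resolve in the ontology."""
        for term in self.active_terms():
            for parent in term.parents:
                if parent not in self:
                    raise ValueError(
                        f"term {term.id} references unknown parent {parent}"
                    )


_SYNONYM_RE = re.compile(
    r'"(?P<text>(?:[^"\\]|\\.)*)"\s*(?:\[(?P<bracketed>[A-Z]+)\]|(?P<bare>[A-Z]+))?'
)


def _parse_synonym(value: str) -> tuple[str, str]:
    """Parse a synonym line value; scope defaults to RELATED when absent."""
    m = _SYNONYM_RE.match(value.strip())
    if m:
        text = m.group("text").replace('\\"', '"')
        scope = m.group("bracketed") or m.group("bare") or "RELATED"
    else:
        # tolerate the paper's quote style: 'text' [SCOPE]
        stripped = value.strip()
        sm = re.match(r"^[‘']?(?P<text>.*?)[’']?\s*\[(?P<scope>[A-Z]+)\]\s*$",
                      stripped)
        if sm:
            text, scope = sm.group("text"), sm.group("scope")
        else:
            text, scope = stripped.strip("'‘’"), "RELATED"
    if scope not in SYNONYM_SCOPES:
        scope = "RELATED"
    return text, scope


def _strip_comment(value: str) -> str:
    """Drop an OBO trailing comment: ' ! regulation of ...'."""
    idx = value.find("!")
    return value[:idx].strip() if idx >= 0 else value.strip()


def _unquote_def(value: str) -> str:
    m = re.match(r'\s*"((?:[^"\\]|\\.)*)"', value)
    if m:
        return m.group(1).replace('\\"', '"')
    return value.strip().strip("'‘’")


def parse_obo(stream: IO[str] | str, release_label: str = "") -> Ontology:
    """Parse OBO 1.2 stanzas into an :class:`Ontology`.

    Accepts ``GO_id:`` as an alias for ``id:`` (the tag used in some printed
    renderings of GO stanzas).  Unknown tags are ignored.  A ``[Term]`` stanza
    with no id line raises :class:`OboParseError` naming its byte offset.
    """
    if isinstance(stream, str):
        lines = stream.splitlines(keepends=True)
    else:
        lines = stream.readlines()

    ontology = Ontology(release_label=release_label)
    offset = 0
    stanza_offset: int | None = None
    in_term = False
    fields: dict[str, list[str]] = {}

    def flush() -> None:
        nonlocal fields, in_term
        if not in_term:
            return
        ids = fields.get("id", [])
        if not ids:
            raise OboParseError("[Term] stanza has no id line", stanza_offset or 0)
        term_id = _strip_comment(ids[0])
        synonyms = [_parse_synonym(v) for v in fields.get("synonym", [])]
        parents = frozenset(_strip_comment(v) for v in fields.get("is_a", []))
        alt_ids = frozenset(_strip_comment(v) for v in fields.get("alt_id", []))
        obsolete = any(
            _strip_comment(v).lower() == "true" for v in fields.get("is_obsolete", [])
        )
        try:
            term = OntologyTerm(
                id=term_id,
                name=_strip_comment(fields.get("name", [""])[0]),
                namespace=_strip_comment(fields.get("namespace", [""])[0]),
                definition=_unquote_def(fields.get("def", [""])[0]),
                synonyms=synonyms,
                parents=parents,
                is_obsolete=obsolete,
                alt_ids=alt_ids,
            )
        except ValueError as exc:
            raise OboParseError(str(exc), stanza_offset or 0) from exc
        ontology.add(term)
        fields = {}
        in_term = False

    for line in lines:
        stripped = line.strip()
        if stripped.startswith("["):
            flush()
            if stripped == "[Term]":
                in_term = True
                stanza_offset = offset
                fields = {}
        elif in_term and stripped and not stripped.startswith("!"):
            tag, sep, value = stripped.partition(":")
            if sep:
                tag = tag.strip().lower()
                if tag == "go_id":
                    tag = "id"
                fields.setdefault(tag, []).append(value.strip())
        offset += len(line.encode("utf-8"))
    flush()
    return ontology


def write_obo(ontology: Ontology, stream: IO[str]) -> None:
    """Serialize to OBO 1.2; parse(write(parse(x))) is the identity."""
    stream.write("format-version: 1.2\n")
    if ontology.release_label:
        stream.write(f"data-version: {ontology.release_label}\n")
    for term in sorted(ontology.terms.values(), key=lambda t: t.id):
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        if term.name:
            stream.write(f"name: {term.name}\n")
        if term.namespace:
            stream.write(f"namespace: {term.namespace}\n")
        if term.definition:
            escaped = term.definition.replace('"', '\\"')
            stream.write(f'def: "{escaped}" []\n')
        for alt in sorted(term.alt_ids):
            stream.write(f"alt_id: {alt}\n")
        for text, scope in term.synonyms:
            escaped = text.replace('"', '\\"')
            stream.write(f'synonym: "{escaped}" {scope} []\n')
        for parent in sorted(term.parents):
            stream.write(f"is_a: {parent}\n")
        if term.is_obsolete:
            stream.write("is_obsolete: true\n")


def term_document(term: OntologyTerm, fields: Iterable[str] = ("name", "synonyms")) -> str:
    """Concatenated indexable text of a non-obsolete term.

    Field order is fixed name -> synonyms -> definition regardless of the
    order given, so the output is deterministic.
    """
    if term.is_obsolete:
        raise ValueError(f"term {term.id} is obsolete and cannot be indexed")
    selected = set(fields)
    unknown = selected - set(TERM_TEXT_FIELDS)
    if unknown:
        raise ValueError(f"unknown term text fields: {sorted(unknown)}")
    parts: list[str] = []
    if "name" in selected and term.name:
        parts.append(term.name)
    if "synonyms" in selected:
        parts.extend(text for text, _scope in term.synonyms)
    if "definition" in selected and term.definition:
        parts.append(term.definition)
    return " ".join(parts)


def ontology_stats(ontology: Ontology) -> tuple[int, int, int]:
    """(term count, EXACT synonym count, all-scope synonym count).

    Counts run over non-obsolete terms only, mirroring the usual
    per-release GO statistics (terms / exact synonyms / all synonyms).
    """
    terms = ontology.active_terms()
    exact = sum(1 for t in terms for _, scope in t.synonyms if scope == "EXACT")
    total = sum(len(t.synonyms) for t in terms)
    return len(terms), exact, total
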