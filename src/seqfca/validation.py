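"""Extrinsic validation against UMLS-like tables and a literature corpus.

Two evidence routes, tried in order:

1. **Terminology evidence.** A missing concept's normalized sequence is
   looked up in a term table (CUI, source vocabulary, term string). When
   found, the suggested position is checked too: evidence supports it when a
   directed IS-A chain leads from a mapped CUI of some suggested subtype to
   a mapped CUI of the missing concept — the chain may mix edges contributed
   by different source vocabularies.
2. **Literature evidence**, only for concepts the term table does not cover.
   A document supports a concept when its title or abstract contains the
   concept phrase (case-insensitive, token-boundary match) and contains none
   of the *blocker* phrases — longer existing-concept or suggested-subtype
   names of which the concept phrase is a substring. Blocking keeps a hit on
   "colorectal adenoma with severe dysplasia" from counting as evidence for
   "adenoma with severe dysplasia". Phrases absent from the blocker list
   (e.g. "oral lentiginous melanoma" when that concept exists nowhere in the
   audited terminology) still slip through; that failure mode is inherent to
   the rule and is reproduced, not patched.

The UMLS stand-in is three small TSVs mirroring the relevant columns of
MRCONSO / MRREL / MRSTY; the corpus is JSON-lines with ``doc_id``,
``title``, ``abstract``.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .positioning import PositionedMissingConcept
from .preprocess import (
    EmptySequenceError,
    NormalizationTable,
    Seq,
    normalize_sequence,
    tokenize,
)
from .terminology import Terminology

__all__ = [
    "UmlsTables",
    "load_umls_tables",
    "CorpusDoc",
    "load_corpus",
    "ValidationRecord",
    "map_to_cuis",
    "isa_path_exists",
    "semantic_type_overlap",
    "literature_hits",
    "collect_blockers",
    "validate_all",
]


@dataclass(frozen=True)
class UmlsTables:
    """Simplified Metathesaurus slices.

    ``terms``: (cui, source, term string); ``isa``: (child_cui, parent_cui,
    source); ``semtypes``: (cui, tui). The IS-A graph may span sources and is
    queried across all of them.
    """

    terms: tuple[tuple[str, str, str], ...] = ()
    isa: tuple[tuple[str, str, str], ...] = ()
    semtypes: tuple[tuple[str, str], ...] = ()

    def tuis(self, cui: str) -> set[str]:
        return {tui for c, tui in self.semtypes if c == cui}


def load_umls_tables(terms_path=None, isa_path=None, semtypes_path=None) -> UmlsTables:
    """Load ``umls_terms.tsv`` / ``umls_isa.tsv`` / ``umls_semtypes.tsv``;
    any table may be omitted (empty)."""

    def _read(path, cols):
        if path is None:
            return ()
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if list(df.columns) != cols:
            raise ValidationError(f"{path}: expected columns {cols}, got {list(df.columns)}")
        return tuple(df.itertuples(index=False, name=None))

    return UmlsTables(
        terms=_read(terms_path, ["cui", "source", "term"]),
        isa=_read(isa_path, ["child_cui", "parent_cui", "source"]),
        semtypes=_read(semtypes_path, ["cui", "tui"]),
    )


@dataclass(frozen=True)
class CorpusDoc:
    doc_id: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("corpus document with empty doc_id")
        if not (self.title or self.abstract):
            raise ValidationError(f"corpus document {self.doc_id!r} has no text")


def load_corpus(path) -> list[CorpusDoc]:
    """Read a JSON-lines corpus; one object per line with keys ``doc_id``,
    ``title``, ``abstract``."""
    docs = []
    seen = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            doc = CorpusDoc(
                doc_id=str(obj["doc_id"]),
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
            )
            if doc.doc_id in seen:
                raise ValidationError(f"{path}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


@dataclass(frozen=True)
class ValidationRecord:
    """Evidence gathered for one positioned missing concept."""

    concept: PositionedMissingConcept
    umls_found: bool
    supporting_sources: tuple[str, ...]
    position_supported: bool
    literature_doc_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "display_name": self.concept.display_name,
            "sequence": list(self.concept.sequence),
            "supertypes": list(self.concept.supertypes),
            "subtypes": list(self.concept.subtypes),
            "umls_found": self.umls_found,
            "supporting_sources": list(self.supporting_sources),
            "position_supported": self.position_supported,
            "literature_doc_ids": list(self.literature_doc_ids),
        }


def _term_index(u: UmlsTables, table: NormalizationTable) -> dict[Seq, set[tuple[str, str]]]:
    index: dict[Seq, set[tuple[str, str]]] = {}
    for cui, source, term in u.terms:
        try:
            seq = normalize_sequence(tokenize(term), table)
        except EmptySequenceError:
            continue
        index.setdefault(seq, set()).add((cui, source))
    return index


def map_to_cuis(
    seq: Seq, u: UmlsTables, table: NormalizationTable
) -> set[tuple[str, str]]:
    """Every (cui, source) whose normalized term sequence equals ``seq``.

    Term strings pass through the same tokenize/normalize pipeline as concept
    names, so "appears in an external terminology" is well-defined up to
    lexical variation.
    """
    return set(_term_index(u, table).get(seq, set()))


def isa_path_exists(from_cui: str, to_cui: str, u: UmlsTables, max_depth: int = 10) -> bool:
    """True iff a directed IS-A chain of length 1..``max_depth`` leads from
    ``from_cui`` to ``to_cui``; edges from different sources may be mixed.
    Zero-length paths do not count."""
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    up: dict[str, set[str]] = {}
    for child, parent, _source in u.isa:
        up.setdefault(child, set()).add(parent)
    queue: deque[tuple[str, int]] = deque([(from_cui, 0)])
    visited = {from_cui: 0}
    while queue:
        cui, depth = queue.popleft()
        if depth >= max_depth:
            continue
        for parent in up.get(cui, ()):
            if parent == to_cui:
                return True
            if parent not in visited or visited[parent] > depth + 1:
                visited[parent] = depth + 1
                queue.append((parent, depth + 1))
    return False


def semantic_type_overlap(cui_a: str, cui_b: str, u: UmlsTables) -> bool:
    """True iff the TUI sets of the two CUIs intersect; a CUI absent from the
    semantic-type table has an empty set."""
    return bool(u.tuis(cui_a) & u.tuis(cui_b))


def _phrase_pattern(phrase: str) -> re.Pattern:
    tokens = [t for t in re.split(r"\W+", phrase.lower()) if t]
    if not tokens:
        raise ValidationError(f"phrase {phrase!r} has no word tokens")
    body = r"\W+".join(re.escape(tok) for tok in tokens)
    return re.compile(rf"(?<![0-9A-Za-z]){body}(?![0-9A-Za-z])", re.IGNORECASE)


def phrase_in_text(phrase: str, text: str) -> bool:
    """Case-insensitive token-boundary containment: the phrase's tokens occur
    consecutively and no token continues into a longer word."""
    return bool(_phrase_pattern(phrase).search(text))


def literature_hits(
    record: PositionedMissingConcept,
    corpus: Iterable[CorpusDoc],
    blockers: Sequence[str],
) -> list[str]:
    """Documents whose title or abstract contains the concept phrase and none
    of the blocker phrases; returned in corpus order."""
    phrase_re = _phrase_pattern(record.display_name)
    blocker_res = [_phrase_pattern(b) for b in blockers]
    hits = []
    for doc in corpus:
        text = f"{doc.title}\n{doc.abstract}"
        if not phrase_re.search(text):
            continue
        if any(b.search(text) for b in blocker_res):
            continue
        hits.append(doc.doc_id)
    return hits


def collect_blockers(
    record: PositionedMissingConcept,
    t: Terminology,
    table: NormalizationTable,
) -> list[str]:
    """Blocker phrases for ``record``: every normalized preferred-name or
    synonym phrase in ``t`` of which the record's sequence is a proper
    substring, plus the names of the record's suggested subtypes."""
    from .fca import is_proper_substring
    from .positioning import _sequence_index

    blockers = set()
    for seq in _sequence_index(t, table):
        if is_proper_substring(record.sequence, seq):
            blockers.add(" ".join(seq))
    for cid in record.subtypes:
        blockers.add(" ".join(normalize_sequence(tokenize(t.concepts[cid].preferred_name), table)))
    return sorted(blockers)


def validate_all(
    records: Iterable[PositionedMissingConcept],
    u: UmlsTables,
    corpus: Iterable[CorpusDoc],
    t: Terminology,
    table: NormalizationTable,
    max_depth: int = 10,
) -> list[ValidationRecord]:
    """Run both evidence routes over every record.

    ``position_supported`` is true iff some mapped CUI of some suggested
    subtype reaches some mapped CUI of the record via an IS-A chain.
    Literature search runs only for records the term table does not cover.
    """
    corpus = list(corpus)
    index = _term_index(u, table)
    out = []
    for record in records:
        mapped = sorted(index.get(record.sequence, set()))
        umls_found = bool(mapped)
        sources = tuple(sorted({source for _cui, source in mapped}))
        position_supported = False
        if umls_found:
            concept_cuis = {cui for cui, _source in mapped}
            for cid in record.subtypes:
                sub_seq = normalize_sequence(tokenize(t.concepts[cid].preferred_name), table)
                sub_cuis = {cui for cui, _source in index.get(sub_seq, set())}
                if any(
                    isa_path_exists(sc, cc, u, max_depth=max_depth)
                    for sc in sorted(sub_cuis)
                    for cc in sorted(concept_cuis)
                ):
                    position_supported = True
                    break
        doc_ids: tuple[str, ...] = ()
        if not umls_found:
            blockers = collect_blockers(record, t, table)
            doc_ids = tuple(literature_hits(record, corpus, blockers))
        out.append(
            ValidationRecord(
                concept=record,
                umls_found=umls_found,
                supporting_sources=sources,
                position_supported=position_supported,
                literature_doc_ids=doc_ids,
            )
        )
    return out


def write_validation_report(records: Iterable[ValidationRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump([r.to_dict() for r in records], handle, indent=2, sort_keys=True)
        handle.write("\n")
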