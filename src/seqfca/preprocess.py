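"""Name pre-processing: tokenization, lexical normalization, formal context.

Concept names become ordered sequences of lowercase word tokens. Two
table-driven substitution passes then unify lexical variants, emulating the
observable effect of the UMLS norm tools on a user-supplied vocabulary:

1. *normalization* (inflectional variants, e.g. ``arteries -> artery``),
2. *single-word synonym substitution* (e.g. ``before -> prior``),

in that order, word for word, so sequence length never changes. Both maps
are closed to idempotence at load time (values that are themselves keys are
chased to a fixpoint), which makes ``normalize_sequence`` idempotent.

The formal context pairs every audited concept (FCA object) with exactly one
attribute: the normalized sequence of its preferred name. Normalized synonym
sequences are kept in a side table for the existing-concept check only; they
do not participate in the intersection.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptySequenceError, ValidationError
from .terminology import Terminology

__all__ = [
    "Seq",
    "tokenize",
    "NormalizationTable",
    "load_normalization_table",
    "normalize_sequence",
    "FormalContext",
    "build_context",
]

#: A name sequence: an ordered tuple of lowercase word tokens. Order is
#: significant and duplicate tokens are permitted.
Seq = tuple[str, ...]

_SPLIT_RE = re.compile(r"[\s/\-]+")


def tokenize(name: str) -> list[str]:
    """Split a concept name into lowercase word tokens.

    Splits on whitespace, hyphen and slash; strips leading/trailing
    punctuation from each token; drops empty tokens. Stopwords are retained —
    they carry positional information in the sequence.

    Raises :class:`EmptySequenceError` if nothing survives.
    """
    tokens = []
    for raw in _SPLIT_RE.split(name.lower()):
        tok = raw.strip(string.punctuation)
        if tok:
            tokens.append(tok)
    if not tokens:
        raise EmptySequenceError(f"name {name!r} tokenized to an empty sequence")
    return tokens


def _closed(mapping: dict[str, str], label: str) -> dict[str, str]:
    """Chase values through the map to a fixpoint (idempotent closure)."""
    out: dict[str, str] = {}
    for key, value in mapping.items():
        seen = {key}
        while value in mapping and mapping[value] != value:
            if value in seen:
                raise ValidationError(f"{label}: substitution cycle through {value!r}")
            seen.add(value)
            value = mapping[value]
        out[key] = value
    return out


@dataclass(frozen=True)
class NormalizationTable:
    """Word-for-word substitution tables applied to every token.

    ``mapping`` holds lexical-normalization rows (surface -> normalized);
    ``synonym_map`` holds single-word synonym rows (synonym -> preferred).
    Keys and values are single lowercase words; lookups are case-insensitive
    because everything is lowercased at construction. Missing entries fall
    back to identity.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)
    synonym_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, table in (("mapping", self.mapping), ("synonym_map", self.synonym_map)):
            lowered: dict[str, str] = {}
            for key, value in table.items():
                key, value = key.lower(), value.lower()
                if not key or not value or any(ch.isspace() for ch in key + value):
                    raise ValidationError(
                        f"{label}: keys and values must be single non-empty words "
                        f"(offending row: {key!r} -> {value!r})"
                    )
                if key in lowered and lowered[key] != value:
                    raise ValidationError(
                        f"{label}: conflicting rows for key {key!r}: "
                        f"{lowered[key]!r} vs {value!r}"
                    )
                lowered[key] = value
            object.__setattr__(self, label, _closed(lowered, label))

    def apply(self, token: str) -> str:
        """Normalize then synonym-substitute one token."""
        token = self.mapping.get(token, token)
        return self.synonym_map.get(token, token)

    @classmethod
    def identity(cls) -> "NormalizationTable":
        return cls()


def _load_two_column(path, key_col: str, value_col: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != [key_col, value_col]:
        raise ValidationError(
            f"{path}: expected columns ['{key_col}', '{value_col}'], got {list(df.columns)}"
        )
    rows: dict[str, str] = {}
    for row in df.itertuples(index=True):
        key = getattr(row, key_col).lower()
        value = getattr(row, value_col).lower()
        if key in rows and rows[key] != value:
            raise ValidationError(
                f"{path} row {row.Index + 2}: conflicting value for key {key!r}"
            )
        rows[key] = value
    return rows


def load_normalization_table(norm_path=None, synonyms_path=None) -> NormalizationTable:
    """Load ``norm_table.tsv`` (``surface\\tnormalized``) and ``synonyms.tsv``
    (``synonym\\tpreferred``); either may be omitted."""
    mapping = _load_two_column(norm_path, "surface", "normalized") if norm_path else {}
    synonym_map = (
        _load_two_column(synonyms_path, "synonym", "preferred") if synonyms_path else {}
    )
    return NormalizationTable(mapping=mapping, synonym_map=synonym_map)


def normalize_sequence(tokens: Iterable[str], table: NormalizationTable) -> Seq:
    """Apply both substitution passes to every token; length is preserved."""
    seq = tuple(table.apply(tok.lower()) for tok in tokens)
    if not seq:
        raise EmptySequenceError("cannot normalize an empty token list")
    return seq


@dataclass(frozen=True)
class FormalContext:
    """The formal context K = (O, A, R) of an audited sub-hierarchy.

    ``entries`` maps each concept id (object) to its single attribute, the
    normalized preferred-name sequence. ``reverse`` inverts it (several
    concepts may share one normalized name). ``synonym_sequences`` carries
    normalized synonym sequences per concept, consumed only by the
    existing-concept check.
    """

    entries: Mapping[str, Seq]
    reverse: Mapping[Seq, frozenset[str]]
    synonym_sequences: Mapping[str, tuple[Seq, ...]]

    def __len__(self) -> int:
        return len(self.entries)


def build_context(t: Terminology, table: NormalizationTable) -> FormalContext:
    """Build the formal context of ``t`` under ``table``.

    Raises :class:`ValidationError` naming any concept whose preferred name
    yields an empty sequence. Synonyms that tokenize to nothing are skipped.
    """
    entries: dict[str, Seq] = {}
    reverse: dict[Seq, set[str]] = {}
    synonym_sequences: dict[str, tuple[Seq, ...]] = {}
    for cid in sorted(t.concepts):
        concept = t.concepts[cid]
        try:
            seq = normalize_sequence(tokenize(concept.preferred_name), table)
        except EmptySequenceError as exc:
            raise ValidationError(f"concept {cid!r}: {exc}") from exc
        entries[cid] = seq
        reverse.setdefault(seq, set()).add(cid)
        syn_seqs = []
        for synonym in concept.synonyms:
            try:
                syn_seqs.append(normalize_sequence(tokenize(synonym), table))
            except EmptySequenceError:
                continue
        synonym_sequences[cid] = tuple(syn_seqs)
    return FormalContext(
        entries=entries,
        reverse={seq: frozenset(ids) for seq, ids in reverse.items()},
        synonym_sequences=synonym_sequences,
    )
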