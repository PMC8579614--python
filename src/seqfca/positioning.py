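"""Qualification, existing-concept filtering, and insertion-point search.

The sublist relation between name sequences is the lexical proxy for the
subconcept-superconcept relation: Y is a supertype of X when Y's sequence is
a *proper* contiguous substring of X's (equality is handled by the
existing-concept check instead).

A candidate with no supertype among the audited concepts is considered
"outside the given hierarchy" — it usually names knowledge from another
branch, such as ``dendrite cell`` (a cell, not a neoplasm) — and is dropped.
Qualified candidates that already exist anywhere in the full terminology
(as a synonym inside the audited sub-hierarchy, or as a concept of another
sub-hierarchy) are dropped as well. The survivors are reported with their
most specific supertypes and most general subtypes.

Subtype reduction uses BOTH dominance orders: a collected subtype is removed
when it is an IS-A descendant of another collected subtype, or when its
sequence properly contains another's. Sequence containment alone is not
enough — "Inflammatory Pseudotumor-Like Follicular/Fibroblastic Dendritic
Cell Sarcoma" must be removed below "Follicular Dendritic Cell Sarcoma"
although its token sequence does not contiguously contain the latter; only
the IS-A graph explains that removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .fca import CandidateConcept, is_proper_substring
from .preprocess import FormalContext, NormalizationTable, Seq, build_context
from .terminology import Terminology

__all__ = [
    "PositionedMissingConcept",
    "find_supertypes",
    "find_subtypes",
    "existing_concept_check",
    "pinpoint_locations",
    "write_missing_concepts",
]

#: existing_concept_check outcomes
NEW = "new"
SYNONYM_IN_HIERARCHY = "synonym_in_hierarchy"
OUTSIDE_HIERARCHY_EXISTING = "outside_hierarchy_existing"


@dataclass(frozen=True)
class PositionedMissingConcept:
    """A qualified, genuinely-new candidate with its suggested position.

    ``supertypes`` are the most specific original concepts whose sequences
    are proper substrings of ``sequence``; ``subtypes`` the most general
    original concepts whose sequences properly contain it (an antichain).
    """

    sequence: Seq
    display_name: str
    supertypes: tuple[str, ...]
    subtypes: tuple[str, ...]
    provenance: tuple[tuple[str, str], ...]
    stage: int


def find_supertypes(c: CandidateConcept, ctx: FormalContext) -> list[str]:
    """Most specific original supertypes of ``c`` (possibly empty).

    Collects concepts whose sequence is a proper substring of ``c.sequence``,
    then drops any whose sequence is a proper substring of another collected
    supertype's; ties (shared sequences) are all reported.
    """
    collected = [
        cid for cid, seq in ctx.entries.items() if is_proper_substring(seq, c.sequence)
    ]
    kept = [
        cid
        for cid in collected
        if not any(
            is_proper_substring(ctx.entries[cid], ctx.entries[other])
            for other in collected
        )
    ]
    return sorted(kept)


def find_subtypes(c: CandidateConcept, ctx: FormalContext, t: Terminology) -> list[str]:
    """Most general original subtypes of ``c``: concepts whose sequence
    properly contains ``c.sequence``, minus those dominated by another
    collected subtype through IS-A ancestry or sequence containment."""
    collected = [
        cid for cid, seq in ctx.entries.items() if is_proper_substring(c.sequence, seq)
    ]
    collected_set = set(collected)
    kept = []
    for cid in collected:
        dominated = bool(t.ancestors(cid) & collected_set) or any(
            is_proper_substring(ctx.entries[other], ctx.entries[cid])
            for other in collected
            if other != cid
        )
        if not dominated:
            kept.append(cid)
    return sorted(kept)


def _sequence_index(full_t: Terminology, table: NormalizationTable) -> dict[Seq, set[str]]:
    """Normalized preferred-name and synonym sequences of every concept."""
    ctx = build_context(full_t, table)
    index: dict[Seq, set[str]] = {}
    for cid, seq in ctx.entries.items():
        index.setdefault(seq, set()).add(cid)
        for syn_seq in ctx.synonym_sequences[cid]:
            index.setdefault(syn_seq, set()).add(cid)
    return index


def _classify_existing(
    sequence: Seq, index: Mapping[Seq, set[str]], audited: set[str]
) -> str:
    matches = index.get(sequence, set())
    if not matches:
        return NEW
    if matches & audited:
        return SYNONYM_IN_HIERARCHY
    return OUTSIDE_HIERARCHY_EXISTING


def existing_concept_check(
    c: CandidateConcept,
    full_t: Terminology,
    audited_root: str,
    table: NormalizationTable,
) -> str:
    """Classify a candidate against every normalized name and synonym of the
    full terminology.

    Returns ``"new"`` (no match), ``"synonym_in_hierarchy"`` (matched a
    concept under ``audited_root``) or ``"outside_hierarchy_existing"``
    (matched a concept of another sub-hierarchy only). When only the audited
    sub-hierarchy is available the check degrades to matching within it.
    """
    index = _sequence_index(full_t, table)
    audited = full_t.descendants(audited_root) | {audited_root}
    return _classify_existing(c.sequence, index, audited)


def pinpoint_locations(
    candidates: Iterable[CandidateConcept],
    ctx: FormalContext,
    full_t: Terminology,
    audited_root: str,
    table: NormalizationTable,
) -> list[PositionedMissingConcept]:
    """Assemble the potentially-missing-concept report.

    Drops unqualified candidates (no supertype) and candidates that already
    exist in the terminology; emits the rest in lexicographic sequence order.
    """
    index = _sequence_index(full_t, table)
    audited = full_t.descendants(audited_root) | {audited_root}
    records = []
    for c in sorted(candidates, key=lambda c: c.sequence):
        supertypes = find_supertypes(c, ctx)
        if not supertypes:
            continue
        if _classify_existing(c.sequence, index, audited) != NEW:
            continue
        subtypes = find_subtypes(c, ctx, full_t)
        records.append(
            PositionedMissingConcept(
                sequence=c.sequence,
                display_name=c.display_name,
                supertypes=tuple(supertypes),
                subtypes=tuple(subtypes),
                provenance=c.provenance,
                stage=c.stage,
            )
        )
    return records


def write_missing_concepts(records: Iterable[PositionedMissingConcept], path) -> None:
    """Write ``missing_concepts.tsv`` (lists semicolon-separated)."""
    df = pd.DataFrame(
        [
            {
                "display_name": r.display_name,
                "sequence": " ".join(r.sequence),
                "supertypes": ";".join(r.supertypes),
                "subtypes": ";".join(r.subtypes),
                "provenance": ";".join(f"{a}×{b}" for a, b in r.provenance),
                "stage": r.stage,
            }
            for r in records
        ],
        columns=["display_name", "sequence", "supertypes", "subtypes", "provenance", "stage"],
    )
    df.to_csv(path, sep="\t", index=False)
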