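"""Confusion accounting for the concept-positioning enhancement.

Every newly formalized concept is crossed on two axes: whether it has a
supertype (qualification — the positioning enhancement's accept signal) and
whether independent evidence places it *inside* the audited sub-hierarchy.
A qualified concept inside the hierarchy is a true positive; qualified but
outside, a false positive; unqualified and outside, a true negative;
unqualified but inside, a false negative.

Two evidence strata are computed independently and never pooled:

* **terminology stratum** — candidates whose sequence matches an existing
  concept of the full terminology; "inside" means the match lies under the
  audited root (a synonym in the same sub-hierarchy).
* **UMLS stratum** — remaining candidates whose sequence appears in the
  term table; "inside" means the candidate's CUI shares a semantic type
  with some suggested subtype's CUI.

Candidates found in neither source carry no evidence and are counted
separately, outside both strata.

Precision with the enhancement is TP/(TP+FP); without it, every candidate
counts as suggested, so precision is (total - outside)/total. Percentages
are reported to two decimals, round-half-up, matching the convention of the
published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .errors import UndefinedPrecisionError
from .fca import CandidateConcept
from .positioning import (
    NEW,
    _classify_existing,
    _sequence_index,
    find_subtypes,
    find_supertypes,
)
from .preprocess import FormalContext, NormalizationTable
from .terminology import Terminology
from .validation import UmlsTables, _term_index, semantic_type_overlap

__all__ = [
    "ConfusionCounts",
    "StratifiedCounts",
    "classify_candidates",
    "precision_with_enhancement",
    "precision_without_enhancement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def outside(self) -> int:
        return self.fp + self.tn

    def add(self, qualified: bool, inside: bool) -> "ConfusionCounts":
        if qualified:
            return ConfusionCounts(self.tp + inside, self.fp + (not inside), self.tn, self.fn)
        return ConfusionCounts(self.tp, self.fp, self.tn + (not inside), self.fn + inside)


@dataclass(frozen=True)
class StratifiedCounts:
    """Per-stratum confusion counts plus the evidence-free remainder."""

    terminology: ConfusionCounts
    umls: ConfusionCounts
    unclassified: int


def classify_candidates(
    candidates: Iterable[CandidateConcept],
    ctx: FormalContext,
    full_t: Terminology,
    audited_root: str,
    u: UmlsTables,
    table: NormalizationTable,
) -> StratifiedCounts:
    """Cross qualification with inside/outside evidence per stratum.

    The terminology stratum takes every candidate matching an existing name
    or synonym anywhere in ``full_t``; the UMLS stratum takes the remaining
    candidates covered by the term table. Candidates in neither are tallied
    as ``unclassified``.
    """
    name_index = _sequence_index(full_t, table)
    audited = full_t.descendants(audited_root) | {audited_root}
    term_index = _term_index(u, table)

    terminology = ConfusionCounts()
    umls = ConfusionCounts()
    unclassified = 0
    for c in sorted(candidates, key=lambda c: c.sequence):
        qualified = bool(find_supertypes(c, ctx))
        status = _classify_existing(c.sequence, name_index, audited)
        if status != NEW:
            inside = status == "synonym_in_hierarchy"
            terminology = terminology.add(qualified, inside)
            continue
        mapped = term_index.get(c.sequence, set())
        if mapped:
            cand_cuis = sorted({cui for cui, _source in mapped})
            inside = False
            for cid in find_subtypes(c, ctx, full_t):
                sub_seq = ctx.entries[cid]
                sub_cuis = sorted({cui for cui, _s in term_index.get(sub_seq, set())})
                if any(
                    semantic_type_overlap(a, b, u) for a in cand_cuis for b in sub_cuis
                ):
                    inside = True
                    break
            umls = umls.add(qualified, inside)
            continue
        unclassified += 1
    return StratifiedCounts(terminology=terminology, umls=umls, unclassified=unclassified)


def _pct(numerator: int, denominator: int) -> float:
    value = Decimal(numerator * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def precision_with_enhancement(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FP), two decimals, round-half-up."""
    if c.tp + c.fp == 0:
        raise UndefinedPrecisionError("no qualified candidates in stratum (tp + fp = 0)")
    return _pct(c.tp, c.tp + c.fp)


def precision_without_enhancement(total_positive: int, outside: int) -> float:
    """Precision when every formalized concept counts as suggested:
    100 * (total - outside) / total, two decimals, round-half-up."""
    if total_positive <= 0:
        raise UndefinedPrecisionError("empty stratum (total_positive = 0)")
    if outside > total_positive:
        raise ValueError("outside count exceeds total")
    return _pct(total_positive - outside, total_positive)
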