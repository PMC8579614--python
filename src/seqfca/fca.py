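"""Sequence-based concept formalization.

The classic FCA intersection ("shared attributes of two objects") is
reformulated on word sequences: intersecting two concepts means computing
the longest common substring(s) of their name sequences, i.e. the longest
contiguous token runs occurring in both. Because the result is itself a
word sequence, a newly derived formal concept arrives with a ready-to-use
name — the property the bag-of-words variant lacks.

Derivation runs as a multistage closure. Stage 1 intersects all unordered
pairs of original sequences; each later stage intersects sequences added in
the previous stage against the whole cumulated set; a sequence enters the
set only if not already present. Iteration stops when a stage adds nothing
(closure) or at ``max_stages``, in which case the result is flagged
non-closed and a warning is emitted. Restricting later stages to pairs that
touch the newest additions is output-equivalent to the naive all-pairs
fixpoint (asserted against that oracle in the test suite) but avoids
re-intersecting settled pairs.

All distinct maximal-length common substrings are kept when there are ties,
and single-word results are kept here — the positioning stage is what
discards unqualified candidates such as ``recurrent`` or ``brain``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import pandas as pd

from .errors import SeqFcaError
from .preprocess import FormalContext, Seq

__all__ = [
    "CandidateConcept",
    "FormalizationResult",
    "longest_common_substrings",
    "is_substring",
    "bag_of_words_intersection",
    "formalize_new_concepts",
    "write_candidates",
]


def longest_common_substrings(a: Seq, b: Seq) -> set[Seq]:
    """Every distinct maximal-length contiguous common substring of two
    sequences (token-wise); empty set if no token is shared.

    Standard suffix-alignment dynamic programme; all ties are returned, per
    the plural in "longest common substring(s)".
    """
    if not a or not b:
        raise SeqFcaError("longest_common_substrings requires non-empty sequences")
    best = 0
    ends: set[int] = set()  # end indices (exclusive) in a of best-length matches
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        curr = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                curr[j] = prev[j - 1] + 1
                if curr[j] > best:
                    best = curr[j]
                    ends = {i}
                elif curr[j] == best:
                    ends.add(i)
        prev = curr
    if best == 0:
        return set()
    return {a[end - best : end] for end in ends}


def is_substring(small: Seq, big: Seq) -> bool:
    """True iff ``small`` occurs as a contiguous run inside ``big``,
    including at either end and including equality (the sublist relation)."""
    n, m = len(small), len(big)
    if n == 0 or m == 0:
        return False
    return any(big[i : i + n] == small for i in range(m - n + 1))


def is_proper_substring(small: Seq, big: Seq) -> bool:
    """Contiguous containment with equality excluded."""
    return len(small) < len(big) and is_substring(small, big)


def bag_of_words_intersection(a: Seq, b: Seq) -> set[str]:
    """Unordered token-set intersection — the earlier bag-of-words
    formalization, kept as a comparison mode."""
    if not a or not b:
        raise SeqFcaError("bag_of_words_intersection requires non-empty sequences")
    return set(a) & set(b)


@dataclass(frozen=True)
class CandidateConcept:
    """A newly formalized sequence.

    ``stage`` is the intersection stage that first produced it (originals are
    stage 0 and never appear here). ``provenance`` holds the unordered pairs
    of sequence identifiers whose intersection yielded it: concept ids for
    original sequences (``|``-joined when several concepts share one
    normalized name), space-joined tokens for derived ones.
    """

    sequence: Seq
    stage: int
    provenance: tuple[tuple[str, str], ...]

    @property
    def display_name(self) -> str:
        return " ".join(self.sequence)


@dataclass(frozen=True)
class FormalizationResult:
    """Candidates from a multistage run plus a closure flag."""

    candidates: tuple[CandidateConcept, ...]
    closed: bool

    def __iter__(self) -> Iterator[CandidateConcept]:
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def sequences(self) -> set[Seq]:
        return {c.sequence for c in self.candidates}


def formalize_new_concepts(ctx: FormalContext, max_stages: int = 32) -> FormalizationResult:
    """Run the multistage sequence intersection to closure.

    Returns only derived candidates (stage >= 1), deduplicated by token tuple
    with provenance merged across every generating pair. Candidates are
    ordered lexicographically by token tuple so runs are reproducible.
    """
    if max_stages < 1:
        raise SeqFcaError("max_stages must be >= 1")
    originals: list[Seq] = sorted(set(ctx.entries.values()))
    label: dict[Seq, str] = {s: "|".join(sorted(ctx.reverse[s])) for s in originals}
    known: set[Seq] = set(originals)
    stages: dict[Seq, int] = {}
    provenance: dict[Seq, set[tuple[str, str]]] = {}
    frontier: list[Seq] = originals
    closed = False
    for stage in range(1, max_stages + 1):
        if stage == 1:
            pairs = combinations(originals, 2)
        else:
            # frontier x cumulated; avoid visiting a frontier-frontier pair twice
            cumulated = sorted(known)
            pairs = (
                (x, y)
                for x in frontier
                for y in cumulated
                if y != x and (y not in set(frontier) or y > x)
            )
        new: dict[Seq, set[tuple[str, str]]] = {}
        for x, y in pairs:
            for s in longest_common_substrings(x, y):
                if s == x or s == y:
                    continue  # not proper: one input contains the other
                pair = tuple(sorted((label[x], label[y])))
                if s in known:
                    if s in provenance:
                        provenance[s].add(pair)
                    continue
                new.setdefault(s, set()).add(pair)
        if not new:
            closed = True
            break
        for s in sorted(new):
            stages[s] = stage
            provenance[s] = new[s]
            label[s] = " ".join(s)
            known.add(s)
        frontier = sorted(new)
    if not closed:
        warnings.warn(
            f"formalize_new_concepts stopped at max_stages={max_stages} before closure",
            RuntimeWarning,
            stacklevel=2,
        )
    candidates = tuple(
        CandidateConcept(
            sequence=s,
            stage=stages[s],
            provenance=tuple(sorted(provenance[s])),
        )
        for s in sorted(stages)
    )
    return FormalizationResult(candidates=candidates, closed=closed)


def write_candidates(result: FormalizationResult, path) -> None:
    """Write ``candidates.tsv``: sequence (space-joined), stage, provenance
    (semicolon-separated ``idAxidB`` pairs)."""
    df = pd.DataFrame(
        [
            {
                "sequence": c.display_name,
                "stage": c.stage,
                "provenance": ";".join(f"{a}×{b}" for a, b in c.provenance),
            }
            for c in result.candidates
        ],
        columns=["sequence", "stage", "provenance"],
    )
    df.to_csv(path, sep="\t", index=False)
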