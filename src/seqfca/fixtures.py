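"""Synthetic terminologies with planted missing concepts, and the three
worked-example fixtures used throughout the tests.

The generator emulates the compositional naming that makes sequence
intersection meaningful: names are modifier chains over head nouns
("recurrent cutaneous melanoma"), grown by prepending one modifier at a
time, so every suffix of a name is itself a concept and IS-A coincides
exactly with sequence containment. In that regime the detector is exact:
hiding an internal concept and rewiring its children upward plants a
missing concept that the pipeline must recover, with the hidden concept's
surviving parent as supertype and its children as most-general subtypes.

What the generator deliberately does NOT emulate: names whose subsumption
is purely semantic ("Carcinoma" IS-A "Neoplasm" shares no token). The
``noise`` option plants such containment-violating concepts to exercise
that documented blind spot.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from math import perm

from .errors import ConfigurationError
from .preprocess import NormalizationTable
from .terminology import Concept, Terminology

__all__ = [
    "GeneratorConfig",
    "HiddenConcept",
    "generate_terminology",
    "paper_fixtures",
]

_HEADS = [
    "neoplasm", "sarcoma", "carcinoma", "lymphoma", "melanoma", "adenoma",
    "glioma", "fibroma", "lipoma", "myeloma",
]
_MODIFIERS = [
    "malignant", "benign", "recurrent", "cutaneous", "thyroid", "palate",
    "follicular", "gastric", "hepatic", "renal", "pediatric", "metastatic",
    "primary", "secondary", "anterior", "posterior", "nodular", "diffuse",
    "chronic", "acute",
]
_NOISE_HEADS = ["disorder", "syndrome", "lesion", "anomaly", "finding"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-terminology generator.

    ``n_concepts`` counts named concepts excluding the artificial root;
    ``max_modifier_chain`` bounds the number of modifiers before the head;
    ``hide_fraction`` of the hideable (internal, non-root-child-only)
    concepts are removed and returned as ground truth; ``noise`` adds
    single-token concepts whose placement violates sequence containment.
    """

    n_heads: int = 3
    n_modifiers: int = 6
    max_modifier_chain: int = 3
    n_concepts: int = 40
    hide_fraction: float = 0.2
    seed: int = 0
    noise: int = 0

    def __post_init__(self) -> None:
        if min(self.n_heads, self.n_modifiers, self.max_modifier_chain, self.n_concepts) <= 0:
            raise ConfigurationError("all generator counts must be positive")
        if not (0.0 <= self.hide_fraction < 1.0):
            raise ConfigurationError("hide_fraction must lie in [0, 1)")
        if self.noise < 0:
            raise ConfigurationError("noise must be non-negative")

    @property
    def capacity(self) -> int:
        """Distinct chain-over-head names expressible under this config."""
        return self.n_heads * sum(
            perm(self.n_modifiers, k) for k in range(self.max_modifier_chain + 1)
        )


@dataclass(frozen=True)
class HiddenConcept:
    """Ground truth for one planted missing concept: the concept removed
    from the terminology plus its original parents and children."""

    concept: Concept
    parents: tuple[str, ...]
    children: tuple[str, ...]


ROOT_ID = "T0000"


def _vocab(base: list[str], prefix: str, n: int) -> list[str]:
    words = list(base)
    while len(words) < n:
        words.append(f"{prefix}{len(words)}")
    return words[:n]


def generate_terminology(
    cfg: GeneratorConfig,
) -> tuple[Terminology, list[HiddenConcept]]:
    """Build a seeded synthetic terminology and its planted ground truth.

    Concepts are grown from head nouns by prepending unused modifiers, so
    the name DAG is suffix-closed. A non-adjacent subset of the internal
    concepts (``hide_fraction`` of them) is then removed, each hidden
    concept's children rewired to its parents. Fully reproducible from
    ``cfg.seed``; raises :class:`ConfigurationError` when more concepts are
    requested than distinct names exist.
    """
    if cfg.n_concepts > cfg.capacity:
        raise ConfigurationError(
            f"n_concepts={cfg.n_concepts} exceeds the {cfg.capacity} distinct "
            f"names expressible under this configuration"
        )
    rng = random.Random(cfg.seed)
    heads = _vocab(_HEADS, "head", cfg.n_heads)
    modifiers = _vocab(_MODIFIERS, "modifier", cfg.n_modifiers)

    names: list[tuple[str, ...]] = [(h,) for h in heads[: min(cfg.n_heads, cfg.n_concepts)]]
    name_set = set(names)
    while len(names) < cfg.n_concepts:
        growable = [n for n in names if len(n) - 1 < cfg.max_modifier_chain]
        base = rng.choice(growable)
        candidates = [m for m in modifiers if m not in base and ((m,) + base) not in name_set]
        if not candidates:
            continue
        new = (rng.choice(candidates),) + base
        names.append(new)
        name_set.add(new)

    ids = {name: f"T{i + 1:04d}" for i, name in enumerate(names)}
    concepts = {ROOT_ID: Concept(id=ROOT_ID, preferred_name="root entity")}
    edges: set[tuple[str, str]] = set()
    for name in names:
        cid = ids[name]
        concepts[cid] = Concept(id=cid, preferred_name=" ".join(name))
        parent = name[1:]
        edges.add((cid, ids[parent] if parent else ROOT_ID))

    for i in range(cfg.noise):
        noise_head = _vocab(_NOISE_HEADS, "noiseword", cfg.noise)[i]
        cid = f"N{i + 1:04d}"
        concepts[cid] = Concept(id=cid, preferred_name=noise_head)
        host = rng.choice([ids[n] for n in names])
        edges.add((cid, host))

    full = Terminology(concepts=dict(concepts), isa_edges=frozenset(edges))

    # hide a non-adjacent subset of internal concepts
    hideable = [
        cid
        for cid in sorted(concepts)
        if cid != ROOT_ID and full.children(cid) and full.parents(cid)
    ]
    n_hide = round(cfg.hide_fraction * len(hideable))
    rng.shuffle(hideable)
    hidden_ids: list[str] = []
    for cid in hideable:
        if len(hidden_ids) >= n_hide:
            break
        neighbours = full.children(cid) | full.parents(cid)
        if neighbours & set(hidden_ids):
            continue
        hidden_ids.append(cid)

    hidden = [
        HiddenConcept(
            concept=concepts[cid],
            parents=tuple(sorted(full.parents(cid))),
            children=tuple(sorted(full.children(cid))),
        )
        for cid in sorted(hidden_ids)
    ]
    hidden_set = set(hidden_ids)
    kept_concepts = {cid: c for cid, c in concepts.items() if cid not in hidden_set}
    kept_edges: set[tuple[str, str]] = set()
    for child, parent in edges:
        if child in hidden_set:
            continue
        if parent in hidden_set:
            # non-adjacency of the hidden set: grandparents always survive
            for grandparent in full.parents(parent):
                kept_edges.add((child, grandparent))
        else:
            kept_edges.add((child, parent))
    observed = Terminology(concepts=kept_concepts, isa_edges=frozenset(kept_edges))
    return observed, hidden


@dataclass(frozen=True)
class RecoveryReport:
    """End-to-end detector performance on one synthetic terminology.

    ``eligible`` hidden concepts are those the method can recover by
    construction: at least two surviving children whose name LCS equals the
    hidden name, plus a surviving concept whose name is a proper substring
    of it (the qualification witness). ``recovered`` counts eligible hidden
    concepts emitted with exactly their true parents as supertypes and true
    children as most-general subtypes. ``false_missing`` counts emitted
    records that correspond to no hidden concept.
    """

    n_hidden: int
    eligible: int
    recovered: int
    false_missing: int


def planted_recovery(cfg: GeneratorConfig) -> RecoveryReport:
    """Generate, run the full detection pipeline, score against the plant."""
    from .fca import formalize_new_concepts, is_proper_substring, longest_common_substrings
    from .positioning import pinpoint_locations
    from .preprocess import build_context, normalize_sequence, tokenize

    observed, hidden = generate_terminology(cfg)
    table = NormalizationTable.identity()
    ctx = build_context(observed.subhierarchy(ROOT_ID), table)
    result = formalize_new_concepts(ctx)
    records = {
        r.sequence: r
        for r in pinpoint_locations(result, ctx, observed, ROOT_ID, table)
    }

    eligible = recovered = 0
    hidden_seqs = set()
    for h in hidden:
        seq = normalize_sequence(tokenize(h.concept.preferred_name), table)
        hidden_seqs.add(seq)
        surviving_children = [c for c in h.children if c in observed.concepts]
        child_pairs_hit = any(
            seq in longest_common_substrings(ctx.entries[a], ctx.entries[b])
            for i, a in enumerate(surviving_children)
            for b in surviving_children[i + 1 :]
        )
        has_witness = any(
            is_proper_substring(s, seq) for s in ctx.entries.values()
        )
        if not (child_pairs_hit and has_witness):
            continue
        eligible += 1
        record = records.get(seq)
        if (
            record is not None
            and set(record.supertypes) == {p for p in h.parents if p != ROOT_ID}
            and set(record.subtypes) == set(surviving_children)
        ):
            recovered += 1
    false_missing = sum(1 for seq in records if seq not in hidden_seqs)
    return RecoveryReport(
        n_hidden=len(hidden),
        eligible=eligible,
        recovered=recovered,
        false_missing=false_missing,
    )


# -- worked-example fixtures ----------------------------------------------


def _terminology(rows, edges) -> Terminology:
    concepts = {
        cid: Concept(id=cid, preferred_name=name, synonyms=tuple(syns))
        for cid, name, syns in rows
    }
    return Terminology(concepts=concepts, isa_edges=frozenset(edges))


def paper_fixtures() -> dict[str, tuple[Terminology, NormalizationTable]]:
    """The dendritic-cell-sarcoma, tongue-carcinoma and palate-neoplasm
    worked examples, with the normalization rows their sequences need.

    Keys: ``fig1`` (7-concept Neoplasm slice), ``fig1_full`` (fig1 plus a
    Cell branch containing "Dendritic Cell", for the outside-hierarchy
    existing-concept check), ``fig2``, ``fig4``.
    """
    norm_fig1 = NormalizationTable(
        mapping={
            "follicular": "follicle",
            "dendritic": "dendrite",
            "interdigitating": "interdigitate",
        }
    )
    fig1_rows = [
        ("C3262", "Neoplasm", []),
        ("C9118", "Sarcoma", []),
        ("C35460", "Histiocytic and Dendritic Cell Neoplasm", []),
        ("C9281", "Follicular Dendritic Cell Sarcoma", []),
        ("C9282", "Interdigitating Dendritic Cell Sarcoma", []),
        (
            "C150704",
            "Inflammatory Pseudotumor-Like Follicular/Fibroblastic Dendritic Cell Sarcoma",
            [],
        ),
        ("C156408", "Thyroid Gland Follicular Dendritic Cell Sarcoma", []),
    ]
    fig1_edges = [
        ("C9118", "C3262"),
        ("C35460", "C3262"),
        ("C9281", "C9118"),
        ("C9282", "C9118"),
        ("C9281", "C35460"),
        ("C9282", "C35460"),
        ("C150704", "C9281"),
        ("C156408", "C9281"),
    ]
    fig1 = _terminology(fig1_rows, fig1_edges)

    fig1_full = _terminology(
        fig1_rows
        + [
            ("C7057", "Thing", []),
            ("C12508", "Cell", []),
            ("C12938", "Dendritic Cell", []),
        ],
        fig1_edges
        + [("C3262", "C7057"), ("C12508", "C7057"), ("C12938", "C12508")],
    )

    fig2 = _terminology(
        [
            ("C2916", "Carcinoma", []),
            ("C2970", "Adenoid Cystic Carcinoma", []),
            ("C160901", "Anterior Tongue Adenoid Cystic Carcinoma", []),
            ("C160902", "Posterior Tongue Adenoid Cystic Carcinoma", []),
        ],
        [
            ("C2970", "C2916"),
            ("C160901", "C2970"),
            ("C160902", "C2970"),
        ],
    )

    fig4 = _terminology(
        [
            ("C3262", "Neoplasm", []),
            ("C4402", "Palate Neoplasm", []),
            ("C4004", "Malignant Palate Neoplasm", []),
            ("C4405", "Benign Palate Neoplasm", []),
            ("C3528", "Malignant Hard Palate Neoplasm", []),
            ("C4403", "Benign Hard Palate Neoplasm", []),
        ],
        [
            ("C4402", "C3262"),
            ("C4004", "C4402"),
            ("C4405", "C4402"),
            ("C3528", "C4004"),
            ("C4403", "C4405"),
        ],
    )

    identity = NormalizationTable.identity()
    return {
        "fig1": (fig1, norm_fig1),
        "fig1_full": (fig1_full, norm_fig1),
        "fig2": (fig2, identity),
        "fig4": (fig4, identity),
    }
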