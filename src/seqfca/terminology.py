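"""Terminology containers and IS-A graph queries.

A terminology is a set of concepts (id, preferred name, synonyms) together
with a directed acyclic IS-A graph. Multiple parents are permitted — NCIt
concepts routinely belong to several sub-hierarchies — so all ancestor and
descendant queries run over the DAG, not a tree. Cycles are rejected at load
time: every downstream reduction assumes a partial order.

File schemas (UTF-8, tab-separated, with header):

* ``concepts.tsv``:  ``concept_id`` / ``preferred_name`` / ``synonyms``
  (synonyms pipe-separated, empty allowed);
* ``hierarchy.tsv``: ``child_id`` / ``parent_id``.

The writer emits the same schemas with rows sorted lexicographically by id,
so load -> write -> load is an identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import LookupError_, ValidationError

__all__ = [
    "Concept",
    "Terminology",
    "load_terminology",
    "write_terminology",
    "subhierarchy",
    "ancestors",
    "descendants",
]


@dataclass(frozen=True)
class Concept:
    """A single terminology concept.

    ``id`` is an opaque non-empty identifier, unique within a terminology;
    ``preferred_name`` is the free-text name the FCA attribute is built from;
    ``synonyms`` are alternative names, used only by the existing-concept check.
    """

    id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("concept id must be non-empty")
        if not self.preferred_name:
            raise ValidationError(f"concept {self.id!r}: preferred_name must be non-empty")


@dataclass
class Terminology:
    """A validated concept set plus its IS-A DAG.

    ``isa_edges`` holds (child_id, parent_id) pairs; duplicates are collapsed.
    """

    concepts: dict[str, Concept]
    isa_edges: frozenset[tuple[str, str]]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for child, parent in self.isa_edges:
            for endpoint in (child, parent):
                if endpoint not in self.concepts:
                    raise ValidationError(
                        f"IS-A edge ({child!r}, {parent!r}) references unknown concept id {endpoint!r}"
                    )
            g.add_edge(child, parent)  # edge direction: child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"IS-A graph contains a cycle: {cycle}")
        self._graph = g

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def _require(self, concept_id: str) -> None:
        if concept_id not in self.concepts:
            raise LookupError_(f"unknown concept id {concept_id!r}")

    def parents(self, concept_id: str) -> set[str]:
        self._require(concept_id)
        return set(self._graph.successors(concept_id))

    def children(self, concept_id: str) -> set[str]:
        self._require(concept_id)
        return set(self._graph.predecessors(concept_id))

    def ancestors(self, concept_id: str) -> set[str]:
        """All IS-A ancestors of ``concept_id``, excluding itself."""
        self._require(concept_id)
        return nx.descendants(self._graph, concept_id)

    def descendants(self, concept_id: str) -> set[str]:
        """All IS-A descendants of ``concept_id``, excluding itself."""
        self._require(concept_id)
        return nx.ancestors(self._graph, concept_id)

    def subhierarchy(self, root_id: str) -> "Terminology":
        """The induced sub-terminology on ``root_id`` and its descendants."""
        self._require(root_id)
        keep = self.descendants(root_id) | {root_id}
        concepts = {cid: self.concepts[cid] for cid in keep}
        edges = frozenset(
            (c, p) for c, p in self.isa_edges if c in keep and p in keep
        )
        return Terminology(concepts=concepts, isa_edges=edges)


# -- module-level operation surface ---------------------------------------


def subhierarchy(t: Terminology, root_id: str) -> Terminology:
    return t.subhierarchy(root_id)


def ancestors(t: Terminology, concept_id: str) -> set[str]:
    return t.ancestors(concept_id)


def descendants(t: Terminology, concept_id: str) -> set[str]:
    return t.descendants(concept_id)


# -- I/O -------------------------------------------------------------------

_CONCEPT_COLS = ["concept_id", "preferred_name", "synonyms"]
_EDGE_COLS = ["child_id", "parent_id"]


def load_terminology(concepts_path, edges_path) -> Terminology:
    """Load and validate a terminology from the two TSV tables.

    Raises :class:`ValidationError` naming the offending row on duplicate
    concept ids, dangling edge endpoints, or IS-A cycles.
    """
    cdf = pd.read_csv(concepts_path, sep="\t", dtype=str, keep_default_na=False)
    if list(cdf.columns) != _CONCEPT_COLS:
        raise ValidationError(
            f"{concepts_path}: expected columns {_CONCEPT_COLS}, got {list(cdf.columns)}"
        )
    edf = pd.read_csv(edges_path, sep="\t", dtype=str, keep_default_na=False)
    if list(edf.columns) != _EDGE_COLS:
        raise ValidationError(
            f"{edges_path}: expected columns {_EDGE_COLS}, got {list(edf.columns)}"
        )

    concepts: dict[str, Concept] = {}
    for row in cdf.itertuples(index=True):
        cid = row.concept_id
        if cid in concepts:
            raise ValidationError(
                f"{concepts_path} row {row.Index + 2}: duplicate concept id {cid!r}"
            )
        synonyms = tuple(s for s in row.synonyms.split("|") if s)
        concepts[cid] = Concept(id=cid, preferred_name=row.preferred_name, synonyms=synonyms)

    edges = frozenset((row.child_id, row.parent_id) for row in edf.itertuples(index=False))
    return Terminology(concepts=concepts, isa_edges=edges)


def write_terminology(t: Terminology, concepts_path, edges_path) -> None:
    """Write the two TSV tables with rows in lexicographic id order."""
    cdf = pd.DataFrame(
        [
            {
                "concept_id": c.id,
                "preferred_name": c.preferred_name,
                "synonyms": "|".join(c.synonyms),
            }
            for c in (t.concepts[cid] for cid in sorted(t.concepts))
        ],
        columns=_CONCEPT_COLS,
    )
    cdf.to_csv(concepts_path, sep="\t", index=False)
    edf = pd.DataFrame(sorted(t.isa_edges), columns=_EDGE_COLS)
    edf.to_csv(edges_path, sep="\t", index=False)
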