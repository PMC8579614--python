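"""UMLS-style and literature evidence gathering."""

import random

import pytest

from seqfca.positioning import PositionedMissingConcept
from seqfca.preprocess import NormalizationTable
from seqfca.terminology import Concept, Terminology
from seqfca.validation import (
    CorpusDoc,
    UmlsTables,
    collect_blockers,
    isa_path_exists,
    literature_hits,
    load_corpus,
    map_to_cuis,
    phrase_in_text,
    semantic_type_overlap,
    validate_all,
)


def record(*tokens, supertypes=("S1",), subtypes=()):
    return PositionedMissingConcept(
        sequence=tuple(tokens),
        display_name=" ".join(tokens),
        supertypes=tuple(supertypes),
        subtypes=tuple(subtypes),
        provenance=(("A", "B"),),
        stage=1,
    )


IDENTITY = NormalizationTable.identity()


class TestMapToCuis:
    def test_multi_source_term(self):
        u = UmlsTables(
            terms=(
                ("C0026850", "OMIM", "Congenital muscular dystrophy"),
                ("C0026850", "HPO", "Congenital muscular dystrophy"),
                ("C0026850", "CHV", "congenital muscular dystrophy"),
                ("C0001111", "MSH", "Motor neuropathy"),
            )
        )
        hits = map_to_cuis(("congenital", "muscular", "dystrophy"), u, IDENTITY)
        assert hits == {("C0026850", "OMIM"), ("C0026850", "HPO"), ("C0026850", "CHV")}

    def test_absent_sequence(self):
        assert map_to_cuis(("absent",), UmlsTables(), IDENTITY) == set()

    def test_terms_are_normalized_before_matching(self):
        u = UmlsTables(terms=(("C1", "SRC", "muscular dystrophies"),))
        table = NormalizationTable(mapping={"dystrophies": "dystrophy"})
        assert map_to_cuis(("muscular", "dystrophy"), u, table) == {("C1", "SRC")}


class TestIsaPathExists:
    def test_direct_edge(self):
        u = UmlsTables(isa=(("A", "B", "SRC"),))
        assert isa_path_exists("A", "B", u)
        assert not isa_path_exists("B", "A", u)

    def test_hemiplegic_migraine_example(self):
        u = UmlsTables(
            isa=(("C0338484", "C0270862", "SNOMEDCT_US"),)
        )
        assert isa_path_exists("C0338484", "C0270862", u)

    def test_mixed_source_chain_and_depth_bound(self):
        u = UmlsTables(isa=(("A", "B", "S1"), ("B", "C", "S2"), ("C", "D", "S1")))
        assert isa_path_exists("A", "D", u, max_depth=3)
        assert not isa_path_exists("A", "D", u, max_depth=2)

    def test_no_zero_length_paths_in_acyclic_data(self):
        u = UmlsTables(isa=(("A", "B", "S"),))
        assert not isa_path_exists("A", "A", u)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_dfs_on_random_dags(self, seed):
        rng = random.Random(seed)
        n = 30
        edges = tuple(
            (f"U{i}", f"U{rng.randrange(i)}", "S")
            for i in range(1, n)
            for _ in range(rng.randint(1, 2))
        )
        u = UmlsTables(isa=edges)

        def dfs(a, b, depth):
            if depth == 0:
                return False
            for child, parent, _s in edges:
                if child == a and (parent == b or dfs(parent, b, depth - 1)):
                    return True
            return False

        for _ in range(20):
            a, b = f"U{rng.randrange(n)}", f"U{rng.randrange(n)}"
            assert isa_path_exists(a, b, u, max_depth=6) == dfs(a, b, 6)


class TestSemanticTypeOverlap:
    def test_shared_disease_or_syndrome(self):
        u = UmlsTables(semtypes=(("A", "T047"), ("B", "T047"), ("B", "T191")))
        assert semantic_type_overlap("A", "B", u)

    def test_disjoint_or_missing_sets(self):
        u = UmlsTables(semtypes=(("A", "T047"), ("B", "T191")))
        assert not semantic_type_overlap("A", "B", u)
        assert not semantic_type_overlap("A", "C", u)


ADENOMA_DOC = CorpusDoc(
    doc_id="12626909",
    title="Colorectal adenomas",
    abstract=(
        "Of the adenomas, 29 were tubulous, 118 tubulovillous, and 20 villous; "
        "adenoma with severe dysplasia was found in 49 cases."
    ),
)
BLOCKED_DOC = CorpusDoc(
    doc_id="55555",
    title="",
    abstract="A colorectal adenoma with severe dysplasia was resected.",
)
ADENOMA_BLOCKERS = [
    "colorectal adenoma with severe dysplasia",
    "rectal adenoma with severe dysplasia",
    "colon adenoma with severe dysplasia",
]


class TestLiteratureHits:
    def test_adenoma_example_hit_and_blocker_exclusion(self):
        r = record("adenoma", "with", "severe", "dysplasia")
        hits = literature_hits(r, [ADENOMA_DOC, BLOCKED_DOC], ADENOMA_BLOCKERS)
        assert hits == ["12626909"]

    def test_unblocked_more_specific_phrase_slips_through(self):
        # the documented failure mode: "oral lentiginous melanoma" is not in
        # the terminology, so nothing blocks it
        doc = CorpusDoc(
            doc_id="99",
            title="",
            abstract="We report a case of oral lentiginous melanoma in a patient.",
        )
        r = record("lentiginous", "melanoma")
        assert literature_hits(r, [doc], []) == ["99"]
        assert literature_hits(r, [doc], ["oral lentiginous melanoma"]) == []

    def test_token_boundary_matching(self):
        r = record("melanoma")
        doc = CorpusDoc(doc_id="1", title="", abstract="Cutaneous melanomas were studied.")
        assert literature_hits(r, [doc], []) == []  # "melanomas" != "melanoma"
        assert phrase_in_text("melanoma", "a Melanoma, resected")  # case + punctuation

    def test_monotone_in_blockers(self):
        r = record("adenoma", "with", "severe", "dysplasia")
        docs = [ADENOMA_DOC, BLOCKED_DOC]
        hits = literature_hits(r, docs, [])
        for k in range(len(ADENOMA_BLOCKERS)):
            fewer = literature_hits(r, docs, ADENOMA_BLOCKERS[:k])
            more = literature_hits(r, docs, ADENOMA_BLOCKERS[: k + 1])
            assert set(more) <= set(fewer) <= set(hits)

    def test_every_hit_contains_the_phrase(self):
        r = record("adenoma", "with", "severe", "dysplasia")
        docs = [ADENOMA_DOC, BLOCKED_DOC, CorpusDoc(doc_id="7", title="no match", abstract="x")]
        for doc_id in literature_hits(r, docs, []):
            doc = next(d for d in docs if d.doc_id == doc_id)
            assert phrase_in_text(r.display_name, f"{doc.title}\n{doc.abstract}")


class TestCorpusIO:
    def test_jsonl_round_trip(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        path.write_text(
            '{"doc_id": "1", "title": "t", "abstract": "a"}\n'
            '{"doc_id": "2", "title": "", "abstract": "b"}\n'
        )
        docs = load_corpus(path)
        assert [d.doc_id for d in docs] == ["1", "2"]


def _blocker_terminology():
    concepts = {
        "C1": Concept(id="C1", preferred_name="Adenoma"),
        "C2": Concept(id="C2", preferred_name="Colorectal Adenoma with Severe Dysplasia"),
    }
    return Terminology(concepts=concepts, isa_edges=frozenset({("C2", "C1")}))


class TestValidateAll:
    def test_blockers_assembled_from_terminology_and_subtypes(self):
        t = _blocker_terminology()
        r = record("adenoma", "with", "severe", "dysplasia", subtypes=("C2",))
        blockers = collect_blockers(r, t, IDENTITY)
        assert blockers == ["colorectal adenoma with severe dysplasia"]

    def test_umls_found_skips_literature(self):
        t = _blocker_terminology()
        r = record("adenoma", "with", "severe", "dysplasia", subtypes=("C2",))
        u = UmlsTables(terms=(("C0111", "CHV", "adenoma with severe dysplasia"),))
        [v] = validate_all([r], u, [ADENOMA_DOC], t, IDENTITY)
        assert v.umls_found and v.supporting_sources == ("CHV",)
        assert v.literature_doc_ids == ()

    def test_literature_route_when_not_in_umls(self):
        t = _blocker_terminology()
        r = record("adenoma", "with", "severe", "dysplasia", subtypes=("C2",))
        [v] = validate_all([r], UmlsTables(), [ADENOMA_DOC, BLOCKED_DOC], t, IDENTITY)
        assert not v.umls_found and not v.position_supported
        assert v.literature_doc_ids == ("12626909",)

    def test_position_supported_via_subtype_path(self):
        t = _blocker_terminology()
        r = record("adenoma", "with", "severe", "dysplasia", subtypes=("C2",))
        u = UmlsTables(
            terms=(
                ("C0111", "CHV", "adenoma with severe dysplasia"),
                ("C0222", "SNOMEDCT_US", "colorectal adenoma with severe dysplasia"),
            ),
            isa=(("C0222", "C0111", "SNOMEDCT_US"),),
        )
        [v] = validate_all([r], u, [], t, IDENTITY)
        assert v.umls_found and v.position_supported

    def test_empty_evidence_sources(self):
        t = _blocker_terminology()
        r = record("adenoma", "with", "severe", "dysplasia", subtypes=("C2",))
        [v] = validate_all([r], UmlsTables(), [], t, IDENTITY)
        assert not v.umls_found and not v.position_supported
        assert v.supporting_sources == () and v.literature_doc_ids == ()

    def test_position_supported_implies_umls_found(self):
        t = _blocker_terminology()
        records = [record("adenoma", "with", "severe", "dysplasia", subtypes=("C2",))]
        for u in (
            UmlsTables(),
            UmlsTables(terms=(("C0111", "CHV", "adenoma with severe dysplasia"),)),
        ):
            for v in validate_all(records, u, [], t, IDENTITY):
                assert v.umls_found or not v.position_supported
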