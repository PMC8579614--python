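import pytest

from seqfca.fca import formalize_new_concepts
from seqfca.fixtures import paper_fixtures
from seqfca.preprocess import build_context


@pytest.fixture(scope="session")
def fixtures_map():
    return paper_fixtures()


@pytest.fixture(scope="session")
def fig1(fixtures_map):
    return fixtures_map["fig1"]


@pytest.fixture(scope="session")
def fig1_full(fixtures_map):
    return fixtures_map["fig1_full"]


@pytest.fixture(scope="session")
def fig2(fixtures_map):
    return fixtures_map["fig2"]


@pytest.fixture(scope="session")
def fig4(fixtures_map):
    return fixtures_map["fig4"]


@pytest.fixture(scope="session")
def fig1_context(fig1):
    t, table = fig1
    return build_context(t.subhierarchy("C3262"), table)


@pytest.fixture(scope="session")
def fig1_candidates(fig1_context):
    return formalize_new_concepts(fig1_context)


def write_terminology_files(tmp_path, concept_rows, edge_rows):
    """Write raw TSV inputs; rows are (id, name, synonyms) / (child, parent)."""
    concepts = tmp_path / "concepts.tsv"
    lines = ["concept_id\tpreferred_name\tsynonyms"]
    lines += [f"{cid}\t{name}\t{syn}" for cid, name, syn in concept_rows]
    concepts.write_text("\n".join(lines) + "\n")
    hierarchy = tmp_path / "hierarchy.tsv"
    lines = ["child_id\tparent_id"]
    lines += [f"{c}\t{p}" for c, p in edge_rows]
    hierarchy.write_text("\n".join(lines) + "\n")
    return concepts, hierarchy
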