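import random

import pytest
from hypothesis import given, settings, strategies as st

from immunoscreen.ctd import (
    DEFAULT_ENDPOINTS,
    EndpointDefinition,
    MeshHierarchy,
    collect_endpoint_genes,
    expand_mesh_descendants,
    parse_disease_gene_file,
    parse_disease_vocabulary,
)
from immunoscreen.errors import ConfigurationError, InputError, ParseError

HEADER = "# GeneSymbol\tGeneID\tDiseaseName\tDiseaseID\tDirectEvidence\tInferenceScore\tPubMedIDs\n"


def write_dg(tmp_path, rows, name="dg.tsv"):
    p = tmp_path / name
    p.write_text(HEADER + "".join(rows))
    return p


def dg_row(symbol, disease, direct="", score="", refs=""):
    return f"{symbol}\t1\tdisease\t{disease}\t{direct}\t{score}\t{refs}\n"


class TestParseDiseaseGeneFile:
    def test_curated_filter_keeps_only_direct_rows(self, tmp_path):
        rows = [
            dg_row("a1", "MESH:D000001", direct="marker/mechanism"),
            dg_row("a2", "MESH:D000001", direct="therapeutic"),
            dg_row("a3", "MESH:D000002", direct="marker/mechanism"),
            dg_row("b1", "MESH:D000001", score="10.1"),
            dg_row("b2", "MESH:D000002", score="3.5"),
        ]
        records = parse_disease_gene_file(write_dg(tmp_path, rows), curated_only=True)
        assert len(records) == 3
        assert all(r.evidence_class == "direct" for r in records)
        assert {r.gene_symbol for r in records} == {"A1", "A2", "A3"}

    def test_comment_only_file_yields_no_records(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("# comment\n# another comment\n")
        assert parse_disease_gene_file(p) == []

    def test_record_count_matches_independent_line_counter(self, tmp_path):
        rng = random.Random(7)
        rows = []
        for i in range(50):
            direct = rng.choice(["marker/mechanism", "therapeutic", ""])
            rows.append(dg_row(f"G{i}", f"MESH:D{i:06d}", direct=direct))
        p = write_dg(tmp_path, rows)
        # oracle: naive line-by-line count, independent of the parser
        expected = sum(
            1 for line in p.read_text().splitlines()
            if line and not line.startswith("#")
        )
        assert len(parse_disease_gene_file(p, curated_only=False)) == expected

    def test_crlf_and_trailing_empty_columns_tolerated(self, tmp_path):
        p = tmp_path / "crlf.tsv"
        p.write_text(HEADER + "il6\t1\td\tMESH:D000001\tmarker/mechanism\t\t\t\r\n")
        (rec,) = parse_disease_gene_file(p)
        assert rec.gene_symbol == "IL6"

    def test_wrong_column_count_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(HEADER + "G1\t1\n")
        with pytest.raises(ParseError, match=":2"):
            parse_disease_gene_file(p)

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            parse_disease_gene_file(tmp_path / "nope.tsv")


def random_hierarchy(seed, n=50):
    """A random MeSH forest: node i may attach to 1-2 earlier nodes."""
    rng = random.Random(seed)
    h = MeshHierarchy()
    ids = [f"MESH:D{i:06d}" for i in range(1, n + 1)]
    for node in ids:
        h.nodes.add(node)
    for i, node in enumerate(ids[1:], start=1):
        if rng.random() < 0.8:
            for parent in rng.sample(ids[:i], k=min(i, rng.randint(1, 2))):
                h.add_link(node, parent)
    return h, ids


def fixpoint_expand(h, roots):
    """Oracle: iterate one-step child expansion to a fixpoint."""
    result = set(roots)
    while True:
        step = set(result)
        for node in result:
            step |= h.children_of(node)
        if step == result:
            return result
        result = step


class TestExpandMeshDescendants:
    def test_leaf_root_expands_to_itself(self):
        h = MeshHierarchy(nodes={"MESH:D000001"})
        assert expand_mesh_descendants(h, {"MESH:D000001"}) == {"MESH:D000001"}

    def test_linear_chain_expands_fully(self):
        h = MeshHierarchy()
        h.add_link("MESH:D000002", "MESH:D000001")
        h.add_link("MESH:D000003", "MESH:D000002")
        assert expand_mesh_descendants(h, {"MESH:D000001"}) == {
            "MESH:D000001", "MESH:D000002", "MESH:D000003"
        }

    def test_missing_root_is_configuration_error_naming_id(self):
        h = MeshHierarchy(nodes={"MESH:D000001"})
        with pytest.raises(ConfigurationError, match="MESH:D000404"):
            expand_mesh_descendants(h, {"MESH:D000404"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fixpoint_oracle_on_random_forest(self, seed):
        h, ids = random_hierarchy(seed)
        rng = random.Random(seed + 100)
        roots = set(rng.sample(ids, 3))
        assert expand_mesh_descendants(h, roots) == fixpoint_expand(h, roots)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), extra=st.integers(0, 49))
    def test_idempotent_and_monotone(self, seed, extra):
        h, ids = random_hierarchy(seed, n=50)
        rng = random.Random(seed)
        roots = set(rng.sample(ids, 2))
        expanded = expand_mesh_descendants(h, roots)
        # idempotence: expanding the expansion changes nothing
        assert expand_mesh_descendants(h, expanded) == expanded
        # monotonicity: adding a root never shrinks the expansion
        assert expand_mesh_descendants(h, roots | {ids[extra]}) >= expanded


class TestCollectEndpointGenes:
    def setup_method(self):
        self.h = MeshHierarchy()
        self.h.add_link("MESH:D000010", "MESH:D006967")  # child of hypersensitivity
        self.h.nodes.add("MESH:D001327")
        self.hyper = EndpointDefinition("hypersensitivity", ("MESH:D006967",))
        self.auto = EndpointDefinition("autoimmunity", ("MESH:D001327",))

    def records(self, tmp_path):
        rows = [dg_row("il6", "MESH:D000010", direct="marker/mechanism")]
        return parse_disease_gene_file(write_dg(tmp_path, rows))

    def test_gene_on_descendant_term_is_collected(self, tmp_path):
        eset = collect_endpoint_genes(self.records(tmp_path), self.hyper, self.h)
        assert {g.symbol for g in eset.genes} == {"IL6"}
        assert eset.provenance[next(iter(eset.genes))] == {"ctd"}
        assert "MESH:D000010" in eset.disease_terms_used

    def test_disjoint_subtree_yields_empty_set(self, tmp_path):
        eset = collect_endpoint_genes(self.records(tmp_path), self.auto, self.h)
        assert eset.genes == set()


def test_vocabulary_parser_builds_hierarchy(tmp_path):
    p = tmp_path / "vocab.tsv"
    p.write_text(
        "# DiseaseName\tDiseaseID\tParentIDs\n"
        "root\tMESH:D000001\t\n"
        "child\tMESH:D000002\tMESH:D000001|MESH:D000009\n"
        "omim thing\tOMIM:123\tMESH:D000001\n"
    )
    h = parse_disease_vocabulary(p)
    assert h.parent_links["MESH:D000002"] == {"MESH:D000001", "MESH:D000009"}
    assert "OMIM:123" in h.nodes


def test_default_endpoints_cover_the_four_axes():
    names = [e.name for e in DEFAULT_ENDPOINTS]
    assert names == ["hypersensitivity", "autoimmunity", "infection", "cancer"]
    roots = {e.name: set(e.mesh_root_ids) for e in DEFAULT_ENDPOINTS}
    assert roots["hypersensitivity"] == {"MESH:D006967"}
    assert roots["infection"] == {"MESH:D010272", "MESH:D001423", "MESH:D014777"}
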