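import itertools
import json
import math
import random
from fractions import Fraction

import pandas as pd
import pytest

from immunoscreen.ctd import EndpointGeneSet
from immunoscreen.errors import LookupError_, ParseError, UsageError
from immunoscreen.genes import canonicalize_gene
from immunoscreen.screening import (
    enrichment_tail,
    parse_chemical_gene_file,
    screen_chemical,
    top_interacting_genes,
    write_report,
)

HEADER = "# ChemicalName\tChemicalID\tGeneSymbol\tInteractionActions\tInteractionCount\tPubMedIDs\n"


def write_cg(tmp_path, rows):
    p = tmp_path / "cg.tsv"
    p.write_text(HEADER + "".join(rows))
    return p


def cg_row(chem, gene, count, refs=""):
    return f"{chem}\tID:{chem}\t{gene}\tincreases^expression\t{count}\t{refs}\n"


def endpoint_set(name, *symbols):
    nodes = {canonicalize_gene(s) for s in symbols}
    return EndpointGeneSet(name, nodes, {g: {"ctd"} for g in nodes})


class TestParseChemicalGeneFile:
    def test_rows_aggregate_per_chemical_gene_pair(self, tmp_path):
        p = write_cg(tmp_path, [
            cg_row("chemA", "G1", 2, "111"),
            cg_row("chemA", "G1", 3, "111|222"),
        ])
        (rec,) = parse_chemical_gene_file(p)
        assert rec.interaction_count == 5
        assert rec.reference_count == 2  # distinct PubMed ids

    def test_one_chemical_four_genes(self, tmp_path):
        p = write_cg(tmp_path, [cg_row("chemA", f"G{i}", 1) for i in range(4)])
        assert len(parse_chemical_gene_file(p)) == 4

    def test_aggregates_match_pandas_groupby_oracle(self, tmp_path):
        rng = random.Random(13)
        rows = []
        for _ in range(60):
            chem = rng.choice(["chemA", "chemB", "chemC"])
            gene = rng.choice([f"G{i}" for i in range(8)])
            rows.append(cg_row(chem, gene, rng.randint(1, 9)))
        p = write_cg(tmp_path, rows)
        df = pd.read_csv(
            p, sep="\t", comment="#",
            names=["name", "id", "gene", "actions", "count", "refs"],
        )
        oracle = df.groupby(["name", "gene"])["count"].sum().to_dict()
        got = {
            (r.chemical_name, r.gene_symbol): r.interaction_count
            for r in parse_chemical_gene_file(p)
        }
        assert got == oracle

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(HEADER + "chemA\tID\n")
        with pytest.raises(ParseError, match=":2"):
            parse_chemical_gene_file(p)


class TestTopInteractingGenes:
    def test_ordered_by_interaction_count(self, tmp_path):
        p = write_cg(tmp_path, [
            cg_row("chemA", "G1", 5), cg_row("chemA", "G2", 3), cg_row("chemA", "G3", 1),
        ])
        top = top_interacting_genes(parse_chemical_gene_file(p), "chemA", n=2)
        assert [g.symbol for g, _ in top] == ["G1", "G2"]

    def test_tie_broken_alphabetically(self, tmp_path):
        p = write_cg(tmp_path, [cg_row("chemA", "GB", 2), cg_row("chemA", "GA", 2)])
        top = top_interacting_genes(parse_chemical_gene_file(p), "chemA", n=2)
        assert [g.symbol for g, _ in top] == ["GA", "GB"]

    def test_fewer_genes_than_n_returns_all(self, tmp_path):
        p = write_cg(tmp_path, [cg_row("chemA", "G1", 1)])
        assert len(top_interacting_genes(parse_chemical_gene_file(p), "chemA", n=10)) == 1

    def test_unknown_chemical_lists_near_matches(self, tmp_path):
        p = write_cg(tmp_path, [cg_row("bleomycin", "G1", 1)])
        with pytest.raises(LookupError_, match="bleomycin"):
            top_interacting_genes(parse_chemical_gene_file(p), "bleomycine", n=5)

    def test_matches_full_sort_oracle(self, tmp_path):
        rng = random.Random(29)
        rows = [
            cg_row("chemA", f"G{i:02d}", rng.randint(1, 5),
                   "|".join(str(rng.randint(1, 999)) for _ in range(rng.randint(0, 3))))
            for i in range(30)
        ]
        interactions = parse_chemical_gene_file(write_cg(tmp_path, rows))
        oracle = sorted(
            interactions,
            key=lambda r: (-r.interaction_count, -r.reference_count, r.gene_symbol),
        )[:10]
        got = top_interacting_genes(interactions, "chemA", n=10)
        assert [g.symbol for g, _ in got] == [r.gene_symbol for r in oracle]


class TestScreenChemical:
    @pytest.fixture()
    def endpoint_sets(self):
        return {
            "hypersensitivity": endpoint_set("hypersensitivity", "G1", "G2"),
            "autoimmunity": endpoint_set("autoimmunity", "G1", "G3"),
            "infection": endpoint_set("infection", "G4"),
            "cancer": endpoint_set("cancer", "G1"),
        }

    def test_all_endpoints_flagged_when_top_genes_span_them(self, tmp_path, endpoint_sets):
        p = write_cg(tmp_path, [cg_row("chemA", g, 9 - i) for i, g in enumerate(["G1", "G4"])])
        report = screen_chemical(parse_chemical_gene_file(p), "chemA", endpoint_sets)
        assert report.flagged == list(endpoint_sets)
        report.validate()

    def test_single_endpoint_profile_flags_only_it(self, tmp_path, endpoint_sets):
        p = write_cg(tmp_path, [cg_row("chemB", "G4", 5), cg_row("chemB", "X9", 4)])
        report = screen_chemical(parse_chemical_gene_file(p), "chemB", endpoint_sets)
        assert report.flagged == ["infection"]

    def test_no_hits_means_no_flags(self, tmp_path, endpoint_sets):
        p = write_cg(tmp_path, [cg_row("chemC", "Z1", 5), cg_row("chemC", "Z2", 4)])
        report = screen_chemical(parse_chemical_gene_file(p), "chemC", endpoint_sets)
        assert report.flagged == []
        assert all(not any(col.values()) for col in report.membership.values())

    def test_hit_count_identities(self, tmp_path, endpoint_sets):
        rng = random.Random(31)
        rows = [cg_row("chemD", f"G{i}", rng.randint(1, 9)) for i in range(1, 9)]
        report = screen_chemical(
            parse_chemical_gene_file(write_cg(tmp_path, rows)), "chemD", endpoint_sets
        )
        n = len(report.top_genes)
        assert all(report.hit_counts[e] <= n for e in report.endpoints)
        matrix_sum = sum(
            sum(col.values()) for col in report.membership.values()
        )
        assert matrix_sum == sum(report.hit_counts.values())

    def test_screening_invariant_to_row_order(self, tmp_path, endpoint_sets):
        rng = random.Random(37)
        rows = [cg_row("chemE", f"G{i%6}", rng.randint(1, 4)) for i in range(20)]
        r1 = screen_chemical(
            parse_chemical_gene_file(write_cg(tmp_path, rows)), "chemE", endpoint_sets
        )
        shuffled = rows[::-1]
        r2 = screen_chemical(
            parse_chemical_gene_file(write_cg(tmp_path, shuffled)), "chemE", endpoint_sets
        )
        assert [g.symbol for g, _ in r1.top_genes] == [g.symbol for g, _ in r2.top_genes]
        assert r1.hit_counts == r2.hit_counts

    def test_composite_matches_either_member(self, tmp_path):
        sets = {"a": endpoint_set("a", "HLA-DQA2/HLA-DQA1"), "b": endpoint_set("b", "X")}
        p = write_cg(tmp_path, [cg_row("chemF", "HLA-DQA1", 3)])
        report = screen_chemical(parse_chemical_gene_file(p), "chemF", sets)
        assert report.flagged == ["a"]


def tail_oracle(hits, n, successes, background):
    """Exact upper tail by enumeration over outcome counts (Fractions)."""
    total = math.comb(background, n)
    acc = Fraction(0)
    for k in range(hits, min(n, successes) + 1):
        acc += Fraction(math.comb(successes, k) * math.comb(background - successes, n - k), total)
    return float(acc)


class TestEnrichmentTail:
    def test_zero_hits_is_certain(self):
        assert enrichment_tail(0, 5, 3, 10) == 1.0

    def test_all_success_urn(self):
        assert enrichment_tail(3, 3, 10, 10) == pytest.approx(1.0)

    def test_example_matches_subset_enumeration(self):
        # literal enumeration over all 4-subsets of a 12-gene background
        background = range(12)
        successes = set(range(5))
        draws = list(itertools.combinations(background, 4))
        frac = sum(1 for d in draws if len(successes & set(d)) >= 2) / len(draws)
        assert enrichment_tail(2, 4, 5, 12) == pytest.approx(frac, abs=1e-12)

    def test_monotone_nonincreasing_in_hits(self):
        values = [enrichment_tail(h, 6, 8, 20) for h in range(7)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_bound_violations_rejected(self):
        with pytest.raises(UsageError):
            enrichment_tail(5, 3, 2, 10)
        with pytest.raises(UsageError):
            enrichment_tail(1, 3, 11, 10)

    def test_matches_enumeration_on_small_populations(self):
        for background in (1, 5, 12, 17):
            for successes in range(background + 1):
                for n in range(background + 1):
                    for hits in (0, 1, n // 2, n):
                        if hits > n:
                            continue
                        assert enrichment_tail(hits, n, successes, background) == pytest.approx(
                            tail_oracle(hits, n, successes, background), abs=1e-12
                        )


class TestWriteReport:
    @pytest.fixture()
    def report(self, tmp_path):
        sets = {"a": endpoint_set("a", *[f"G{i}" for i in range(10)]), "b": endpoint_set("b", "G0")}
        rows = [cg_row("chemA", f"G{i}", 20 - i) for i in range(12)]
        return screen_chemical(
            parse_chemical_gene_file(write_cg(tmp_path, rows)), "chemA", sets
        )

    def test_markdown_has_one_body_row_per_top_gene(self, report, tmp_path):
        path = write_report(report, "markdown", tmp_path / "r.md")
        body = [l for l in path.read_text().splitlines() if l.startswith("| G")]
        assert len(body) == 10
        assert "×" in path.read_text()

    def test_json_round_trips_the_report(self, report, tmp_path):
        path = write_report(report, "json", tmp_path / "r.json")
        payload = json.loads(path.read_text())
        assert payload["chemical"] == report.chemical
        assert payload["hit_counts"] == report.hit_counts
        assert payload["endpoint_flagged"] == report.endpoint_flagged
        assert [g["symbol"] for g in payload["top_genes"]] == [
            g.symbol for g, _ in report.top_genes
        ]

    def test_tsv_appends_hits_and_flags(self, report, tmp_path):
        path = write_report(report, "tsv", tmp_path / "r.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("gene\t")
        assert lines[-2].startswith("hit_count\t")
        assert lines[-1].startswith("flagged\t")

    def test_unknown_format_rejected(self, report, tmp_path):
        with pytest.raises(UsageError):
            write_report(report, "xlsx", tmp_path / "r.xlsx")
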