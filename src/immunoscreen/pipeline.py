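"""End-to-end pipeline: endpoint assembly -> overlap -> secretome -> ranking -> screening.

Every stage writes its artifact into the output directory and registers it
in a machine-readable run manifest with a SHA-256 digest, so two runs on
identical inputs and config are byte-for-byte comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .biomarker import rank_candidates, write_candidates
from .config import PipelineConfig
from .ctd import (
    EndpointGeneSet,
    collect_endpoint_genes,
    parse_disease_gene_file,
    parse_disease_vocabulary,
)
from .errors import ImmunoscreenError
from .go import (
    coverage_vs_ctd,
    genes_for_processes,
    parse_gaf,
    parse_obo,
    select_processes,
)
from .genes import GeneNode, merge_nodes
from .overlap import build_network, export_graph, venn_partition, write_region_summary
from .screening import parse_chemical_gene_file, screen_chemical, write_report
from .secretome import filter_secreted, parse_uniprot_table, write_unresolved

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Handles on everything a pipeline run computed and wrote."""

    endpoint_sets: dict[str, EndpointGeneSet]
    partition: object
    reports: dict[str, object] = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    go_coverage: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    out_dir: Path = Path("out")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ImmunoscreenError):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage the configured inputs allow and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # --- endpoint gene sets from CTD ---------------------------------------
    with _stage("build-endpoints"):
        hierarchy = parse_disease_vocabulary(config.input_path("disease_vocabulary"))
        records = parse_disease_gene_file(
            config.input_path("disease_gene"), curated_only=config.curated_only
        )
        endpoint_sets = {
            ep.name: collect_endpoint_genes(records, ep, hierarchy)
            for ep in config.endpoints
        }

    # --- GO coverage diagnostic (and optional union) -----------------------
    go_coverage: dict[str, float] = {}
    obo_path = config.input_path("obo", required=False)
    gaf_path = config.input_path("gaf", required=False)
    if obo_path and gaf_path:
        with _stage("go-coverage"):
            ontology = parse_obo(obo_path)
            annotations = parse_gaf(gaf_path)
            for ep in config.endpoints:
                if not ep.go_keywords:
                    continue
                processes = select_processes(ontology, ep.go_keywords)
                genes = genes_for_processes(
                    annotations, ontology, processes, propagate=config.propagate
                )
                go_coverage[ep.name] = coverage_vs_ctd(
                    genes, endpoint_sets[ep.name].genes
                )
                if config.union_go:
                    eset = endpoint_sets[ep.name]
                    merged = merge_nodes(eset.genes | genes)
                    provenance: dict[GeneNode, set[str]] = {}
                    for g in merged:
                        tags = set(eset.provenance.get(g, set()))
                        if g in genes:
                            tags.add("go")
                        provenance[g] = tags or {"go"}
                    eset.genes = merged
                    eset.provenance = provenance
            cov_path = out / "go_coverage.tsv"
            with open(cov_path, "w") as fh:
                fh.write("endpoint\tcoverage\n")
                for name in sorted(go_coverage):
                    fh.write(f"{name}\t{go_coverage[name]:.6f}\n")
            outputs["go_coverage"] = str(cov_path)

    with _stage("build-endpoints"):
        sets_path = out / "endpoint_sets.tsv"
        with open(sets_path, "w") as fh:
            fh.write("endpoint\tsymbol\tprovenance\n")
            for name in (e.name for e in config.endpoints):
                eset = endpoint_sets[name]
                for g in sorted(eset.genes):
                    tags = ",".join(sorted(eset.provenance[g]))
                    fh.write(f"{name}\t{g.symbol}\t{tags}\n")
        outputs["endpoint_sets"] = str(sets_path)

    # --- Venn partition and networks ---------------------------------------
    with _stage("overlap"):
        partition = venn_partition(
            {name: eset.genes for name, eset in endpoint_sets.items()}
        )
        venn_path = out / "venn_regions.json"
        write_region_summary(partition, venn_path)
        outputs["venn_regions"] = str(venn_path)
        members_path = out / "venn_members.json"
        with open(members_path, "w") as fh:
            json.dump(
                {
                    "&".join(sig): sorted(g.symbol for g in genes)
                    for sig, genes in partition.regions.items()
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        outputs["venn_members"] = str(members_path)

    # --- secretome refinement ----------------------------------------------
    annotations_table = None
    uniprot_path = config.input_path("uniprot", required=False)
    secreted_result = None
    if uniprot_path:
        with _stage("secretome"):
            annotations_table = parse_uniprot_table(uniprot_path)
            secreted_result = filter_secreted(partition.universe, annotations_table)
            write_unresolved(secreted_result, out / "unresolved_symbols.tsv")
            outputs["unresolved_symbols"] = str(out / "unresolved_symbols.tsv")
            secreted_sets = {
                name: {
                    g for g in eset.genes
                    if g in secreted_result.secreted
                }
                for name, eset in endpoint_sets.items()
            }
            if sum(1 for s in secreted_sets.values() if s) >= 2:
                secreted_partition = venn_partition(
                    {n: s for n, s in secreted_sets.items()}
                )
                secreted_net = build_network(
                    secreted_partition, annotations_table,
                    exclude=config.exclude_endpoints,
                )
                for p in export_graph(secreted_net, "tsv", out / "secreted_network"):
                    outputs[p.name] = str(p)

    with _stage("overlap"):
        network = build_network(
            partition, annotations_table, exclude=config.exclude_endpoints
        )
        outputs["graphml"] = str(
            export_graph(network, "graphml", out / "network.graphml")[0]
        )
        for p in export_graph(network, "tsv", out / "network"):
            outputs[p.name] = str(p)
        outputs["statements"] = str(
            export_graph(network, "statements", out / "network_statements.cql")[0]
        )

    # --- chemical screening and biomarker ranking --------------------------
    interactions = None
    reports: dict[str, object] = {}
    chem_path = config.input_path("chemical_gene", required=False)
    if chem_path:
        with _stage("screen"):
            interactions = parse_chemical_gene_file(chem_path)
            wanted = config.screen_chemicals or tuple(
                sorted({r.chemical_name for r in interactions})
            )
            for chemical in wanted:
                report = screen_chemical(
                    interactions, chemical, endpoint_sets,
                    n=config.top_n, threshold=config.threshold,
                    enrichment=config.enrichment,
                )
                safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in chemical)
                for fmt, ext in (("tsv", "tsv"), ("markdown", "md"), ("json", "json")):
                    p = write_report(report, fmt, out / f"screen_{safe}.{ext}")
                    outputs[p.name] = str(p)
                reports[chemical] = report

    with _stage("rank"):
        candidates = rank_candidates(partition, annotations_table, interactions)
        outputs["ranked_biomarkers"] = str(
            write_candidates(candidates, out / "ranked_biomarkers.tsv")
        )

    # --- run manifest -------------------------------------------------------
    manifest = {
        "version": __version__,
        "parameters": {
            "curated_only": config.curated_only,
            "union_go": config.union_go,
            "propagate": config.propagate,
            "exclude_endpoints": list(config.exclude_endpoints),
            "top_n": config.top_n,
            "threshold": config.threshold,
            "enrichment": config.enrichment,
            "seed": config.seed,
        },
        "inputs": {
            key: {"path": str(path), "sha256": _digest(Path(path))}
            for key, path in config.inputs.items()
            if Path(path).exists()
        },
        "outputs": {
            key: {"path": path, "sha256": _digest(Path(path))}
            for key, path in sorted(outputs.items())
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        endpoint_sets=endpoint_sets,
        partition=partition,
        reports=reports,
        candidates=candidates,
        go_coverage=go_coverage,
        outputs=outputs,
        out_dir=out,
    )
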