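"""Gene Ontology ingestion and endpoint process selection.

Each endpoint framework names the biological processes that initiate its
disturbance (mast-cell degranulation for hypersensitivity, loss of
tolerance for autoimmunity, ...).  This module selects matching
``biological_process`` terms from an OBO ontology by keyword, collects the
genes annotated to them (optionally propagated up ``is_a`` ancestors), and
quantifies how much of that GO-derived gene set the CTD disease mining
already covers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import obonet

from .errors import ConfigurationError, InputError, ParseError
from .genes import GeneNode, canonicalize_gene, merge_nodes

__all__ = [
    "GOTerm",
    "AnnotationRecord",
    "GOProcessSet",
    "parse_obo",
    "parse_gaf",
    "select_processes",
    "genes_for_processes",
    "coverage_vs_ctd",
]

GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class GOTerm:
    id: str
    name: str
    namespace: str
    is_a_parents: frozenset[str] = frozenset()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.id):
            raise ValueError(f"not a GO identifier: {self.id!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF row: a gene annotated to a GO term with a qualifier."""

    gene_symbol: str
    go_id: str
    qualifier: str = ""
    evidence_code: str = ""

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.go_id):
            raise ValueError(f"not a GO identifier: {self.go_id!r}")

    @property
    def negated(self) -> bool:
        return "NOT" in {q.strip().upper() for q in self.qualifier.split("|")}


@dataclass
class GOProcessSet:
    """Selected biological processes for one endpoint plus their genes."""

    endpoint: str
    terms: dict[str, str]  # id -> name
    genes: set[GeneNode]


def parse_obo(path: str | Path) -> dict[str, GOTerm]:
    """Parse an OBO 1.2 file into a map of GO id -> :class:`GOTerm`.

    Obsolete terms are kept and flagged rather than dropped so that the
    selection step can exclude them explicitly.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"ontology file not found: {p}")
    try:
        graph = obonet.read_obo(p, ignore_obsolete=False)
    except Exception as exc:  # malformed stanza
        raise ParseError(f"{p}: malformed OBO stanza: {exc}") from exc
    ontology: dict[str, GOTerm] = {}
    for node_id, data in graph.nodes(data=True):
        parents = frozenset(
            parent for _, parent, key in graph.out_edges(node_id, keys=True)
            if key == "is_a"
        )
        ontology[node_id] = GOTerm(
            id=node_id,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            is_a_parents=parents,
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
    return ontology


def parse_gaf(path: str | Path) -> list[AnnotationRecord]:
    """Parse a GAF 2.x TSV (``!`` comment lines; 15 or 17 columns).

    Column 3 is the gene symbol, column 4 the qualifier, column 5 the GO id.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"annotation file not found: {p}")
    records: list[AnnotationRecord] = []
    with open(p, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{p}:{lineno}: expected >= 7 GAF columns")
            records.append(
                AnnotationRecord(
                    gene_symbol=fields[2].strip().upper(),
                    go_id=fields[4].strip(),
                    qualifier=fields[3].strip(),
                    evidence_code=fields[6].strip(),
                )
            )
    return records


def select_processes(
    ontology: Mapping[str, GOTerm], keywords: Iterable[str]
) -> set[str]:
    """Non-obsolete biological_process terms whose name contains any keyword.

    Matching is case-insensitive substring - a deliberately simple,
    auditable rule; an explicit term-ID list in the config overrides it.
    """
    keywords = [k.lower() for k in keywords if str(k).strip()]
    if not keywords:
        raise ConfigurationError("process selection requires >= 1 keyword")
    return {
        term.id
        for term in ontology.values()
        if term.namespace == "biological_process"
        and not term.obsolete
        and any(k in term.name.lower() for k in keywords)
    }


def _ancestors(ontology: Mapping[str, GOTerm], go_id: str) -> set[str]:
    """All is_a ancestors of ``go_id`` (exclusive), ignoring unknown parents."""
    seen: set[str] = set()
    frontier = [go_id]
    while frontier:
        node = frontier.pop()
        term = ontology.get(node)
        if term is None:
            continue
        for parent in term.is_a_parents:
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return seen


def genes_for_processes(
    annotations: Iterable[AnnotationRecord],
    ontology: Mapping[str, GOTerm],
    process_ids: Iterable[str],
    propagate: bool = True,
) -> set[GeneNode]:
    """Genes annotated to any of ``process_ids``.

    With ``propagate=True`` an annotation to a term also counts for every
    ``is_a`` ancestor of that term (the standard true-path closure), so a
    gene annotated below a selected process is included.  Rows whose
    qualifier carries ``NOT`` never contribute.
    """
    process_ids = set(process_ids)
    unknown = process_ids - set(ontology)
    if unknown:
        raise ConfigurationError(
            f"unknown GO id(s): {', '.join(sorted(unknown))}"
        )
    genes: set[GeneNode] = set()
    for rec in annotations:
        if rec.negated:
            continue
        hit = rec.go_id in process_ids
        if not hit and propagate and rec.go_id in ontology:
            hit = bool(_ancestors(ontology, rec.go_id) & process_ids)
        if hit:
            genes.add(canonicalize_gene(rec.gene_symbol))
    return merge_nodes(genes)


def coverage_vs_ctd(
    go_genes: Iterable[GeneNode], ctd_genes: Iterable[GeneNode]
) -> float:
    """Fraction of GO-derived genes already present in the CTD-derived set.

    Returns 1.0 for an empty GO set (vacuous coverage).  Composite nodes
    match through either member.
    """
    from .genes import SymbolIndex

    go_genes = set(go_genes)
    if not go_genes:
        return 1.0
    index = SymbolIndex(ctd_genes)
    covered = sum(1 for g in go_genes if g in index)
    return covered / len(go_genes)
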