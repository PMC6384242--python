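"""CTD-dialect ingestion: disease-gene associations and MeSH hierarchy.

The Comparative Toxicogenomics Database distributes curated disease-gene
associations as TSV flat files whose data rows follow ``#``-prefixed header
comments.  An immune health endpoint is defined by one or more MeSH root
descriptors (e.g. hypersensitivity = D006967); the endpoint's gene set is
the union of curated genes attached to the root or any descendant disease
term, so the MeSH polyhierarchy must be expanded to the full subtree first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError, ParseError
from .genes import GeneNode, canonicalize_gene, merge_nodes

__all__ = [
    "EndpointDefinition",
    "DiseaseGeneRecord",
    "MeshHierarchy",
    "EndpointGeneSet",
    "DEFAULT_ENDPOINTS",
    "parse_disease_gene_file",
    "parse_disease_vocabulary",
    "expand_mesh_descendants",
    "collect_endpoint_genes",
]

MESH_ID_RE = re.compile(r"^MESH:D\d+$")

#: Canonical endpoint order used for Venn signatures and reports.
ENDPOINT_ORDER = ("hypersensitivity", "autoimmunity", "infection", "cancer")


def _check_mesh_id(mesh_id: str) -> str:
    if not MESH_ID_RE.match(mesh_id):
        raise ConfigurationError(f"not a MeSH descriptor ID: {mesh_id!r}")
    return mesh_id


@dataclass(frozen=True)
class EndpointDefinition:
    """One immune health endpoint: MeSH roots plus GO keyword matchers."""

    name: str
    mesh_root_ids: tuple[str, ...]
    go_keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.mesh_root_ids:
            raise ConfigurationError(f"endpoint {self.name!r} has no MeSH roots")
        for mid in self.mesh_root_ids:
            _check_mesh_id(mid)


#: The four endpoints with their disease-root descriptors.  Infection merges
#: parasitic (D010272), bacterial/mycoses (D001423) and virus (D014777)
#: diseases into one endpoint.
DEFAULT_ENDPOINTS: tuple[EndpointDefinition, ...] = (
    EndpointDefinition(
        "hypersensitivity", ("MESH:D006967",),
        ("hypersensitivity", "allerg", "mast cell"),
    ),
    EndpointDefinition(
        "autoimmunity", ("MESH:D001327",),
        ("autoimmun", "tolerance", "self antigen"),
    ),
    EndpointDefinition(
        "infection", ("MESH:D010272", "MESH:D001423", "MESH:D014777"),
        ("infection", "defense response", "bacterium", "virus"),
    ),
    EndpointDefinition(
        "cancer", ("MESH:D009369",),
        ("tumor", "neoplas", "apoptotic", "proliferation"),
    ),
)


@dataclass(frozen=True)
class DiseaseGeneRecord:
    """One disease-gene association row after evidence classification."""

    gene_symbol: str
    disease_id: str
    evidence_class: str  # "direct" | "inferred"
    direct_evidence_label: str = ""
    reference_count: int = 0

    def __post_init__(self) -> None:
        direct = bool(self.direct_evidence_label.strip())
        if (self.evidence_class == "direct") != direct:
            raise ValueError(
                "evidence_class must be 'direct' iff a direct-evidence label is present"
            )
        if self.reference_count < 0:
            raise ValueError("reference_count must be >= 0")


@dataclass
class MeshHierarchy:
    """Child-to-parent links over MeSH descriptor IDs (a polyhierarchy)."""

    nodes: set[str] = field(default_factory=set)
    parent_links: dict[str, set[str]] = field(default_factory=dict)

    def children_of(self, parent: str) -> set[str]:
        return {c for c, ps in self.parent_links.items() if parent in ps}

    def add_link(self, child: str, parent: str) -> None:
        self.nodes.add(child)
        self.nodes.add(parent)
        self.parent_links.setdefault(child, set()).add(parent)


@dataclass
class EndpointGeneSet:
    """The resolved gene set for one endpoint with per-gene provenance."""

    endpoint: str
    genes: set[GeneNode]
    provenance: dict[GeneNode, set[str]]
    disease_terms_used: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g in self.genes:
            if not self.provenance.get(g):
                raise ValueError(f"gene {g.symbol} lacks a provenance tag")


def _data_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment rows of a CTD TSV."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"input file not found: {p}")
    with open(p, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def parse_disease_gene_file(
    path: str | Path, curated_only: bool = True
) -> list[DiseaseGeneRecord]:
    """Parse a CTD disease-gene TSV into :class:`DiseaseGeneRecord` rows.

    Columns: GeneSymbol, GeneID, DiseaseName, DiseaseID, DirectEvidence,
    InferenceScore, PubMedIDs.  Rows with a non-empty DirectEvidence field
    are "direct" (manually curated); the rest are "inferred" and dropped
    when ``curated_only`` is true.  Symbols are uppercased.
    """
    records: list[DiseaseGeneRecord] = []
    for lineno, fields in _data_rows(path):
        # tolerate trailing empty columns
        while len(fields) > 7 and fields[-1] == "":
            fields.pop()
        if len(fields) < 4 or len(fields) > 7:
            raise ParseError(
                f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}"
            )
        fields += [""] * (7 - len(fields))
        symbol, _gene_id, _name, disease_id, direct_ev, _score, pubmed = fields
        direct_ev = direct_ev.strip()
        if curated_only and not direct_ev:
            continue
        n_refs = len([p for p in pubmed.split("|") if p.strip()])
        records.append(
            DiseaseGeneRecord(
                gene_symbol=symbol.strip().upper(),
                disease_id=disease_id.strip(),
                evidence_class="direct" if direct_ev else "inferred",
                direct_evidence_label=direct_ev,
                reference_count=n_refs,
            )
        )
    return records


def parse_disease_vocabulary(path: str | Path) -> MeshHierarchy:
    """Parse a CTD disease-vocabulary TSV into a :class:`MeshHierarchy`.

    Columns: DiseaseName, DiseaseID, ParentIDs (pipe-separated MESH: IDs).
    Non-MeSH rows (e.g. OMIM-rooted terms) are kept as nodes but only
    ``MESH:`` parent links are followed.
    """
    hierarchy = MeshHierarchy()
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
        disease_id = fields[1].strip()
        hierarchy.nodes.add(disease_id)
        parents = fields[2].strip() if len(fields) > 2 else ""
        for parent in parents.split("|"):
            parent = parent.strip()
            if parent and parent.startswith("MESH:"):
                hierarchy.add_link(disease_id, parent)
    return hierarchy


def expand_mesh_descendants(hierarchy: MeshHierarchy, roots: Iterable[str]) -> set[str]:
    """Transitive closure of the child-of relation from ``roots`` (inclusive).

    Raises :class:`ConfigurationError` when a root is absent from the
    hierarchy, naming the offending ID.
    """
    roots = set(roots)
    missing = roots - hierarchy.nodes
    if missing:
        raise ConfigurationError(
            f"MeSH root(s) not in disease vocabulary: {', '.join(sorted(missing))}"
        )
    # invert child->parent links once, then BFS downwards
    children: dict[str, set[str]] = {}
    for child, parents in hierarchy.parent_links.items():
        for parent in parents:
            children.setdefault(parent, set()).add(child)
    seen = set(roots)
    frontier = list(roots)
    while frontier:
        node = frontier.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen


def collect_endpoint_genes(
    records: Sequence[DiseaseGeneRecord],
    endpoint: EndpointDefinition,
    hierarchy: MeshHierarchy,
) -> EndpointGeneSet:
    """Union of genes attached to any disease term in the endpoint's subtree.

    ``records`` should already carry the desired evidence filter (see
    :func:`parse_disease_gene_file`).  Every collected gene is tagged with
    provenance ``"ctd"``.
    """
    terms = expand_mesh_descendants(hierarchy, endpoint.mesh_root_ids)
    if not terms:
        raise ConfigurationError(f"endpoint {endpoint.name!r}: empty MeSH expansion")
    genes: set[GeneNode] = set()
    for rec in records:
        if rec.disease_id in terms:
            genes.add(canonicalize_gene(rec.gene_symbol))
    genes = merge_nodes(genes)
    return EndpointGeneSet(
        endpoint=endpoint.name,
        genes=genes,
        provenance={g: {"ctd"} for g in genes},
        disease_terms_used=terms,
    )
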