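"""Secretome annotation: restrict gene sets to plausible circulating biomarkers.

A candidate biomarker must be measurable in plasma, so endpoint gene sets
are refined to proteins UniProt marks as secreted - either by the
``Secreted`` keyword or by a subcellular-location string mentioning
"Secreted".  Genes absent from the annotation table are excluded from the
secreted network but reported as unresolved rather than silently kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError, ParseError
from .genes import GeneNode

__all__ = [
    "SecretomeAnnotation",
    "SecretedFilterResult",
    "parse_uniprot_table",
    "filter_secreted",
]


@dataclass(frozen=True)
class SecretomeAnnotation:
    gene_symbol: str
    secreted: bool
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.secreted != bool(self.evidence):
            raise ValueError("secreted flag must match presence of evidence")


@dataclass
class SecretedFilterResult:
    """Outcome of the secretome refinement of a gene set."""

    secreted: set[GeneNode]
    not_secreted: set[GeneNode]
    unresolved: set[GeneNode]


def parse_uniprot_table(path: str | Path) -> dict[str, SecretomeAnnotation]:
    """Parse a UniProt-dialect TSV into symbol -> :class:`SecretomeAnnotation`.

    Required columns: GeneSymbol, Keywords (semicolon-separated),
    SubcellularLocation (free text).  A protein is secreted when Keywords
    contains the exact token ``Secreted`` OR the location mentions
    "secreted" (case-insensitive).
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"annotation table not found: {p}")
    annotations: dict[str, SecretomeAnnotation] = {}
    with open(p, newline="") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.lstrip("#").strip() for h in fields]
                missing = {"GeneSymbol", "Keywords", "SubcellularLocation"} - set(header)
                if missing:
                    raise ParseError(
                        f"{p}: missing column(s): {', '.join(sorted(missing))}"
                    )
                continue
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            row = dict(zip(header, fields))
            symbol = row["GeneSymbol"].strip().upper()
            keywords = [k.strip() for k in row["Keywords"].split(";") if k.strip()]
            location = row["SubcellularLocation"].strip()
            evidence = ""
            if "Secreted" in keywords:
                evidence = "keyword:Secreted"
            elif "secreted" in location.lower():
                evidence = f"location:{location}"
            annotations[symbol] = SecretomeAnnotation(
                gene_symbol=symbol, secreted=bool(evidence), evidence=evidence
            )
    return annotations


def filter_secreted(
    genes: Iterable[GeneNode],
    annotations: Mapping[str, SecretomeAnnotation],
) -> SecretedFilterResult:
    """Partition ``genes`` into secreted / not-secreted / unresolved.

    A composite node is kept if ANY member is annotated secreted (the
    molecule is plasma-detectable if either gene product is); it is
    unresolved only when no member appears in the table.
    """
    secreted: set[GeneNode] = set()
    not_secreted: set[GeneNode] = set()
    unresolved: set[GeneNode] = set()
    for g in set(genes):
        member_annots = [annotations[m] for m in g.members if m in annotations]
        if not member_annots:
            unresolved.add(g)
        elif any(a.secreted for a in member_annots):
            secreted.add(g)
        else:
            not_secreted.add(g)
    return SecretedFilterResult(secreted, not_secreted, unresolved)


def write_unresolved(result: SecretedFilterResult, path: str | Path) -> None:
    """Write the unresolved-symbol side list as a one-column TSV."""
    with open(path, "w") as fh:
        fh.write("UnresolvedSymbol\n")
        for g in sorted(result.unresolved):
            fh.write(f"{g.symbol}\n")
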