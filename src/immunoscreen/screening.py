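"""Chemical/food-substance screening against endpoint gene sets.

A substance's curated top interacting genes (from the CTD chemical-gene
table) are mapped onto the four endpoint gene sets, producing a gene x
endpoint cross matrix: a cross means the gene is involved in that
endpoint, and an endpoint is flagged when at least ``threshold`` of the
top genes fall in its set.  An optional hypergeometric upper tail scores
how surprising the hit count is against the background of all curated
genes.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .ctd import EndpointGeneSet
from .errors import LookupError_, ParseError, UsageError
from .genes import GeneNode, SymbolIndex, canonicalize_gene

__all__ = [
    "ChemicalGeneInteraction",
    "ScreeningReport",
    "parse_chemical_gene_file",
    "top_interacting_genes",
    "screen_chemical",
    "enrichment_tail",
    "write_report",
]


@dataclass(frozen=True)
class ChemicalGeneInteraction:
    """Aggregated curated interactions for one (chemical, gene) pair."""

    chemical_id: str
    chemical_name: str
    gene_symbol: str
    interaction_count: int
    reference_count: int = 0

    def __post_init__(self) -> None:
        if self.interaction_count < 1:
            raise ValueError("interaction_count must be >= 1")
        if self.reference_count < 0:
            raise ValueError("reference_count must be >= 0")


@dataclass
class ScreeningReport:
    """Top-gene x endpoint membership matrix with hit counts and flags."""

    chemical: str
    top_genes: list[tuple[GeneNode, tuple[int, int]]]  # (node, (n_int, n_ref))
    endpoints: list[str]
    membership: dict[str, dict[str, bool]]  # symbol -> endpoint -> bool
    hit_counts: dict[str, int]
    threshold: int = 1
    enrichment: dict[str, float] | None = None

    @property
    def endpoint_flagged(self) -> dict[str, bool]:
        return {e: self.hit_counts[e] >= self.threshold for e in self.endpoints}

    @property
    def flagged(self) -> list[str]:
        return [e for e in self.endpoints if self.endpoint_flagged[e]]

    def validate(self) -> None:
        for e in self.endpoints:
            col = sum(self.membership[g.symbol][e] for g, _ in self.top_genes)
            if col != self.hit_counts[e]:
                raise AssertionError(f"hit_counts[{e}] inconsistent with matrix")


def parse_chemical_gene_file(path: str | Path) -> list[ChemicalGeneInteraction]:
    """Parse a CTD chemical-gene TSV, aggregating rows per (chemical, gene).

    Columns: ChemicalName, ChemicalID, GeneSymbol, InteractionActions,
    InteractionCount, PubMedIDs.  Interaction counts are summed across rows
    and reference_count is the number of distinct PubMed ids.
    """
    from .ctd import _data_rows

    sums: dict[tuple[str, str, str], int] = {}
    refs: dict[tuple[str, str, str], set[str]] = {}
    for lineno, fields in _data_rows(path):
        while len(fields) > 6 and fields[-1] == "":
            fields.pop()
        if len(fields) < 3 or len(fields) > 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
            )
        fields += [""] * (6 - len(fields))
        name, chem_id, symbol, _actions, count, pubmed = fields
        try:
            n = int(count) if count.strip() else 1
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad InteractionCount {count!r}") from exc
        key = (chem_id.strip(), name.strip(), symbol.strip().upper())
        sums[key] = sums.get(key, 0) + n
        refs.setdefault(key, set()).update(
            p.strip() for p in pubmed.split("|") if p.strip()
        )
    return [
        ChemicalGeneInteraction(
            chemical_id=chem_id,
            chemical_name=name,
            gene_symbol=symbol,
            interaction_count=total,
            reference_count=len(refs[(chem_id, name, symbol)]),
        )
        for (chem_id, name, symbol), total in sorted(sums.items())
    ]


def _rows_for_chemical(
    interactions: Sequence[ChemicalGeneInteraction], chemical: str
) -> list[ChemicalGeneInteraction]:
    wanted = chemical.strip().lower()
    rows = [
        r for r in interactions
        if r.chemical_id.lower() == wanted or r.chemical_name.lower() == wanted
    ]
    if not rows:
        known = sorted({r.chemical_name for r in interactions})
        near = difflib.get_close_matches(chemical, known, n=5, cutoff=0.4)
        raise LookupError_(
            f"chemical {chemical!r} not in interaction table"
            + (f"; close matches: {', '.join(near)}" if near else "")
        )
    return rows


def top_interacting_genes(
    interactions: Sequence[ChemicalGeneInteraction],
    chemical: str,
    n: int = 10,
    rank_by: str = "interactions",
) -> list[tuple[GeneNode, tuple[int, int]]]:
    """The chemical's top-``n`` curated genes with their ranking key.

    Sorted by interaction_count desc, then reference_count desc, then
    symbol asc (``rank_by="references"`` swaps the two count keys).  If
    fewer than ``n`` distinct genes exist, all are returned.
    """
    if n < 1:
        raise UsageError("n must be a positive integer")
    rows = _rows_for_chemical(interactions, chemical)
    if rank_by == "interactions":
        key = lambda r: (-r.interaction_count, -r.reference_count, r.gene_symbol)
    elif rank_by == "references":
        key = lambda r: (-r.reference_count, -r.interaction_count, r.gene_symbol)
    else:
        raise UsageError(f"rank_by must be 'interactions' or 'references', got {rank_by!r}")
    ranked = sorted(rows, key=key)[:n]
    return [
        (canonicalize_gene(r.gene_symbol), (r.interaction_count, r.reference_count))
        for r in ranked
    ]


def screen_chemical(
    interactions: Sequence[ChemicalGeneInteraction],
    chemical: str,
    endpoint_sets: Mapping[str, EndpointGeneSet],
    n: int = 10,
    threshold: int = 1,
    enrichment: bool = False,
    background_size: int | None = None,
    rank_by: str = "interactions",
) -> ScreeningReport:
    """Screen one chemical: membership matrix, hit counts, endpoint flags.

    ``membership[g][e]`` is true when top gene ``g`` lies in endpoint set
    ``e`` (composites match either member).  With ``enrichment``, each
    endpoint also gets the hypergeometric upper-tail probability of its
    hit count; the background defaults to all distinct genes in the
    interaction table.
    """
    top = top_interacting_genes(interactions, chemical, n=n, rank_by=rank_by)
    endpoints = list(endpoint_sets)
    indexes = {e: SymbolIndex(endpoint_sets[e].genes) for e in endpoints}
    membership = {
        g.symbol: {e: g in indexes[e] for e in endpoints} for g, _ in top
    }
    hit_counts = {
        e: sum(membership[g.symbol][e] for g, _ in top) for e in endpoints
    }
    tails: dict[str, float] | None = None
    if enrichment:
        if background_size is None:
            background_size = len({r.gene_symbol for r in interactions})
        tails = {}
        for e in endpoints:
            successes = sum(
                1 for _ in endpoint_sets[e].genes
            )
            successes = min(successes, background_size)
            tails[e] = enrichment_tail(
                hit_counts[e], len(top), successes, background_size
            )
    report = ScreeningReport(
        chemical=chemical,
        top_genes=top,
        endpoints=endpoints,
        membership=membership,
        hit_counts=hit_counts,
        threshold=threshold,
        enrichment=tails,
    )
    report.validate()
    return report


def enrichment_tail(
    hits: int, n: int, endpoint_set_size: int, background_size: int
) -> float:
    """Hypergeometric upper tail P(X >= hits).

    Drawing ``n`` genes without replacement from a background of
    ``background_size`` genes of which ``endpoint_set_size`` belong to the
    endpoint set.
    """
    if not (0 <= hits <= n <= background_size):
        raise UsageError(
            f"need 0 <= hits <= n <= background: {hits}, {n}, {background_size}"
        )
    if not (0 <= endpoint_set_size <= background_size):
        raise UsageError("endpoint_set_size must be within the background")
    if hits == 0:
        return 1.0
    return float(hypergeom.sf(hits - 1, background_size, endpoint_set_size, n))


def write_report(report: ScreeningReport, fmt: str, path: str | Path) -> Path:
    """Render a report as TSV, markdown (crosses) or JSON."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("gene\tinteractions\treferences\t" + "\t".join(report.endpoints) + "\n")
            for g, (n_int, n_ref) in report.top_genes:
                row = [g.symbol, str(n_int), str(n_ref)] + [
                    str(report.membership[g.symbol][e]).lower()
                    for e in report.endpoints
                ]
                fh.write("\t".join(row) + "\n")
            fh.write(
                "hit_count\t\t\t"
                + "\t".join(str(report.hit_counts[e]) for e in report.endpoints) + "\n"
            )
            fh.write(
                "flagged\t\t\t"
                + "\t".join(
                    str(report.endpoint_flagged[e]).lower() for e in report.endpoints
                ) + "\n"
            )
    elif fmt == "markdown":
        with open(path, "w") as fh:
            fh.write(f"# Screening: {report.chemical}\n\n")
            fh.write("| gene | " + " | ".join(report.endpoints) + " |\n")
            fh.write("|" + "---|" * (len(report.endpoints) + 1) + "\n")
            for g, _ in report.top_genes:
                cells = [
                    "×" if report.membership[g.symbol][e] else ""
                    for e in report.endpoints
                ]
                fh.write("| " + " | ".join([g.symbol] + cells) + " |\n")
            fh.write(
                "| **hits** | "
                + " | ".join(str(report.hit_counts[e]) for e in report.endpoints)
                + " |\n"
            )
            fh.write("\nFlagged endpoints: " + (", ".join(report.flagged) or "none") + "\n")
    elif fmt == "json":
        payload = {
            "chemical": report.chemical,
            "threshold": report.threshold,
            "endpoints": report.endpoints,
            "top_genes": [
                {"symbol": g.symbol, "interactions": n_int, "references": n_ref}
                for g, (n_int, n_ref) in report.top_genes
            ],
            "membership": report.membership,
            "hit_counts": report.hit_counts,
            "endpoint_flagged": report.endpoint_flagged,
            "enrichment": report.enrichment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise UsageError(f"unknown report format: {fmt!r} (tsv|markdown|json)")
    return path
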