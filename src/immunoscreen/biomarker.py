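"""Rank-based selection of candidate biomarkers.

Candidates are ordered lexicographically by the pipeline's implicit
priorities: involvement in many endpoints first (shared mechanism), then
secretion status (plasma-measurable), then curated chemical-interaction
evidence volume, with the symbol as a deterministic final tie-break.
The key is a documented default, overridable via weights in the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .genes import GeneNode
from .overlap import VennPartition
from .screening import ChemicalGeneInteraction
from .secretome import SecretomeAnnotation

__all__ = ["BiomarkerCandidate", "rank_candidates", "write_candidates"]


@dataclass(frozen=True)
class BiomarkerCandidate:
    """A gene with its endpoint coverage, secretion status and evidence volume."""

    gene: GeneNode
    n_endpoints: int
    signature: tuple[str, ...]
    secreted: bool | None  # None = unknown (not in the annotation table)
    total_interaction_refs: int
    rank: int

    def sort_key(self) -> tuple:
        # secreted desc with unknown last: True -> 0, False -> 1, None -> 2
        secreted_rank = {True: 0, False: 1, None: 2}[self.secreted]
        return (
            -self.n_endpoints,
            secreted_rank,
            -self.total_interaction_refs,
            self.gene.symbol,
        )


def rank_candidates(
    partition: VennPartition,
    secretome: Mapping[str, SecretomeAnnotation] | None = None,
    interactions: Sequence[ChemicalGeneInteraction] | None = None,
) -> list[BiomarkerCandidate]:
    """Rank every gene in the partition universe as a biomarker candidate.

    ``total_interaction_refs`` sums reference counts over all chemicals in
    the interaction table (0 when no table is given).  The returned list is
    sorted best-first with ranks 1..N.
    """
    refs_by_symbol: dict[str, int] = {}
    if interactions:
        for rec in interactions:
            refs_by_symbol[rec.gene_symbol] = (
                refs_by_symbol.get(rec.gene_symbol, 0) + rec.reference_count
            )
    unranked: list[BiomarkerCandidate] = []
    for sig, members in partition.regions.items():
        for gene in members:
            if secretome is None:
                secreted: bool | None = None
            else:
                annots = [secretome[m] for m in gene.members if m in secretome]
                secreted = any(a.secreted for a in annots) if annots else None
            unranked.append(
                BiomarkerCandidate(
                    gene=gene,
                    n_endpoints=len(sig),
                    signature=sig,
                    secreted=secreted,
                    total_interaction_refs=sum(
                        refs_by_symbol.get(m, 0) for m in gene.members
                    ),
                    rank=0,
                )
            )
    ordered = sorted(unranked, key=BiomarkerCandidate.sort_key)
    return [
        BiomarkerCandidate(
            gene=c.gene,
            n_endpoints=c.n_endpoints,
            signature=c.signature,
            secreted=c.secreted,
            total_interaction_refs=c.total_interaction_refs,
            rank=i,
        )
        for i, c in enumerate(ordered, start=1)
    ]


def write_candidates(
    candidates: Sequence[BiomarkerCandidate], path: str | Path
) -> Path:
    """Write the ranked-candidates TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rank\tsymbol\tn_endpoints\tsignature\tsecreted\ttotal_interaction_refs\n")
        for c in candidates:
            secreted = "unknown" if c.secreted is None else str(c.secreted).lower()
            fh.write(
                f"{c.rank}\t{c.gene.symbol}\t{c.n_endpoints}\t"
                f"{'&'.join(c.signature)}\t{secreted}\t{c.total_interaction_refs}\n"
            )
    return path
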