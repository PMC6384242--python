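"""Gene identity for the screening pipeline.

Genes are identified by HGNC-style symbol strings.  A handful of molecules
are reported as slash-joined composites (e.g. ``HLA-DQA2/HLA-DQA1``, two
closely related loci treated as one measurable molecule); those are kept as
a single :class:`GeneNode` whose ``members`` lists the atomic symbols, and
set membership resolves through *either* member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ParseError

__all__ = ["GeneNode", "canonicalize_gene", "SymbolIndex"]


@dataclass(frozen=True, order=True)
class GeneNode:
    """A gene (or slash-joined composite molecule) identified by symbol.

    Attributes
    ----------
    symbol:
        Canonical uppercase symbol; for composites the members joined by "/".
    members:
        Tuple of one or two atomic symbols, none containing "/".
    """

    symbol: str
    members: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.members:
            object.__setattr__(self, "members", (self.symbol,))
        if self.symbol != "/".join(self.members):
            raise ValueError(
                f"symbol {self.symbol!r} does not equal joined members {self.members!r}"
            )
        if any("/" in m or not m for m in self.members):
            raise ValueError(f"invalid atomic members: {self.members!r}")

    @property
    def is_composite(self) -> bool:
        return len(self.members) > 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.symbol


def canonicalize_gene(symbol: str) -> GeneNode:
    """Normalise a raw symbol string into a :class:`GeneNode`.

    Uppercases, trims surrounding whitespace, strips whitespace around "/"
    so ``"HLA-DQA2/ HLA-DQA1"`` becomes one composite node with two members.

    Raises
    ------
    ParseError
        If the symbol is empty or whitespace-only, or a slash-part is empty.
    """
    if symbol is None or not str(symbol).strip():
        raise ParseError(f"empty gene symbol: {symbol!r}")
    parts = [p.strip().upper() for p in str(symbol).strip().split("/")]
    if any(not p for p in parts):
        raise ParseError(f"malformed composite gene symbol: {symbol!r}")
    return GeneNode("/".join(parts), tuple(parts))


class SymbolIndex:
    """Membership lookup over a set of :class:`GeneNode`.

    Maps every atomic member symbol to its node so that a composite node is
    found by either member, and a query composite matches if any of its
    members is present.
    """

    def __init__(self, genes: Iterable[GeneNode]):
        self._by_member: dict[str, GeneNode] = {}
        self._nodes: set[GeneNode] = set()
        for g in genes:
            self._nodes.add(g)
            for m in g.members:
                self._by_member.setdefault(m, g)

    @property
    def nodes(self) -> frozenset[GeneNode]:
        return frozenset(self._nodes)

    def resolve(self, query: GeneNode | str) -> GeneNode | None:
        """Return the stored node matching ``query`` by any member, else None."""
        node = canonicalize_gene(query) if isinstance(query, str) else query
        if node in self._nodes:
            return node
        for m in node.members:
            if m in self._by_member:
                return self._by_member[m]
        return None

    def __contains__(self, query: object) -> bool:
        if not isinstance(query, (GeneNode, str)):
            return False
        return self.resolve(query) is not None


def merge_nodes(genes: Iterable[GeneNode]) -> set[GeneNode]:
    """Deduplicate nodes by symbol, folding atomic symbols into composites.

    If both ``HLA-DQA1`` and ``HLA-DQA2/HLA-DQA1`` occur, only the composite
    is kept: the composite is the molecule-level identity used in reports.
    """
    nodes = set(genes)
    composite_members: dict[str, GeneNode] = {}
    for g in nodes:
        if g.is_composite:
            for m in g.members:
                composite_members[m] = g
    return {g for g in nodes if g.is_composite or g.symbol not in composite_members}


def index_sets(sets: Mapping[str, Iterable[GeneNode]]) -> dict[str, SymbolIndex]:
    """Build a :class:`SymbolIndex` per named gene set."""
    return {name: SymbolIndex(genes) for name, genes in sets.items()}
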