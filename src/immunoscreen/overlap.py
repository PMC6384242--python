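"""Venn partition and unique-vs-shared network over endpoint gene sets.

The union of the endpoint gene sets decomposes into at most ``2^k - 1``
disjoint regions indexed by membership signature - the exact subset of
endpoints containing a gene.  Genes shared by all four endpoints are the
core overlap; genes with a singleton signature are endpoint-unique.  The
same structure is exported as a bipartite gene-endpoint network for graph
database loading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .ctd import ENDPOINT_ORDER
from .errors import UsageError
from .genes import GeneNode, SymbolIndex
from .secretome import SecretomeAnnotation

__all__ = [
    "VennPartition",
    "venn_partition",
    "intersect_all",
    "build_network",
    "export_graph",
    "canonical_signature",
]

Signature = tuple[str, ...]


def canonical_endpoint_order(names: Iterable[str]) -> list[str]:
    """Fixed global ordering: the four canonical endpoints first, then others."""
    names = list(dict.fromkeys(names))
    rank = {name: i for i, name in enumerate(ENDPOINT_ORDER)}
    return sorted(names, key=lambda n: (rank.get(n, len(rank)), n))


def canonical_signature(names: Iterable[str]) -> Signature:
    """A membership signature as a canonically ordered tuple of endpoint names."""
    return tuple(canonical_endpoint_order(names))


@dataclass
class VennPartition:
    """Disjoint region map over endpoint gene sets, keyed by signature."""

    endpoint_names: list[str]
    regions: dict[Signature, set[GeneNode]]
    universe: set[GeneNode] = field(default_factory=set)

    def region(self, *names: str) -> set[GeneNode]:
        """The region whose signature is exactly ``names`` (any order)."""
        return self.regions.get(canonical_signature(names), set())

    def signature_of(self, gene: GeneNode) -> Signature | None:
        for sig, members in self.regions.items():
            if gene in members:
                return sig
        return None

    def region_sizes(self) -> dict[str, int]:
        """Signature (joined by ``&``) -> region size, for the JSON summary."""
        return {
            "&".join(sig): len(members)
            for sig, members in sorted(self.regions.items())
        }

    def membership(self, gene: GeneNode) -> set[str]:
        sig = self.signature_of(gene)
        return set(sig) if sig else set()

    def validate(self) -> None:
        """Assert the partition laws: disjoint regions covering the universe."""
        seen: set[GeneNode] = set()
        total = 0
        for sig, members in self.regions.items():
            if seen & members:
                raise AssertionError(f"regions are not disjoint at {sig}")
            seen |= members
            total += len(members)
        if seen != self.universe or total != len(self.universe):
            raise AssertionError("regions do not cover the universe exactly")


def venn_partition(sets: Mapping[str, Iterable[GeneNode]]) -> VennPartition:
    """Assign every gene in the union to its exact membership signature.

    Composite nodes are matched through either member, so a set containing
    ``HLA-DQA1`` and another containing ``HLA-DQA2/HLA-DQA1`` agree on the
    composite molecule.
    """
    if len(sets) < 2 or len(sets) > 8:
        raise UsageError(f"venn_partition needs 2-8 sets, got {len(sets)}")
    names = canonical_endpoint_order(sets.keys())
    indexes = {name: SymbolIndex(sets[name]) for name in names}
    universe: set[GeneNode] = set()
    for idx in indexes.values():
        # composites subsume their members across sets
        for g in idx.nodes:
            resolved = None
            for other in indexes.values():
                cand = other.resolve(g)
                if cand is not None and cand.is_composite:
                    resolved = cand
                    break
            universe.add(resolved if resolved is not None else g)
    regions: dict[Signature, set[GeneNode]] = {}
    for gene in universe:
        sig = canonical_signature(n for n in names if gene in indexes[n])
        if sig:
            regions.setdefault(sig, set()).add(gene)
    partition = VennPartition(endpoint_names=names, regions=regions, universe=universe)
    partition.validate()
    return partition


def intersect_all(sets: Mapping[str, Iterable[GeneNode]]) -> set[GeneNode]:
    """Genes shared by every set (the all-endpoints core region)."""
    partition = venn_partition(sets)
    return partition.region(*partition.endpoint_names)


def build_network(
    partition: VennPartition,
    secretome: Mapping[str, SecretomeAnnotation] | None = None,
    exclude: Iterable[str] = (),
) -> nx.Graph:
    """Bipartite gene-endpoint graph carrying signature and secretion flags.

    ``exclude`` drops endpoints from the exported view (the figure-style
    network omits cancer for clarity) without recomputing the partition.
    """
    exclude = set(exclude)
    names = [n for n in partition.endpoint_names if n not in exclude]
    graph = nx.Graph()
    set_sizes: dict[str, int] = {n: 0 for n in names}
    for sig, members in partition.regions.items():
        for name in sig:
            if name in set_sizes:
                set_sizes[name] += len(members)
    for name in names:
        graph.add_node(name, kind="endpoint", set_size=set_sizes[name])
    for sig, members in sorted(partition.regions.items()):
        visible = tuple(n for n in sig if n not in exclude)
        if not visible:
            continue
        for gene in sorted(members):
            attrs = {"kind": "gene", "signature": "&".join(visible)}
            if secretome is not None:
                annots = [secretome[m] for m in gene.members if m in secretome]
                attrs["secreted"] = any(a.secreted for a in annots)
            graph.add_node(gene.symbol, **attrs)
            for name in visible:
                graph.add_edge(gene.symbol, name)
    return graph


def export_graph(network: nx.Graph, fmt: str, out: str | Path) -> list[Path]:
    """Write the network as GraphML, a nodes/edges TSV pair, or a statement script.

    ``out`` is a file path for ``graphml``/``statements`` and a directory
    prefix for ``tsv`` (writes ``<out>.nodes.tsv`` and ``<out>.edges.tsv``).
    Returns the paths written.
    """
    out = Path(out)
    if fmt == "graphml":
        nx.write_graphml(network, out, named_key_ids=True, edge_id_from_attribute=None)
        return [out]
    if fmt == "tsv":
        nodes_path = out.with_suffix(out.suffix + ".nodes.tsv")
        edges_path = out.with_suffix(out.suffix + ".edges.tsv")
        with open(nodes_path, "w") as fh:
            fh.write("id\tkind\tsignature\tsecreted\n")
            for node in sorted(network.nodes):
                data = network.nodes[node]
                fh.write(
                    f"{node}\t{data.get('kind', '')}\t{data.get('signature', '')}"
                    f"\t{str(data.get('secreted', '')).lower()}\n"
                )
        with open(edges_path, "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in sorted(tuple(sorted(e)) for e in network.edges):
                fh.write(f"{u}\t{v}\n")
        return [nodes_path, edges_path]
    if fmt == "statements":
        lines = []
        for node in sorted(network.nodes):
            data = network.nodes[node]
            props = ", ".join(
                f"{k}: {json.dumps(v)}" for k, v in sorted(data.items())
            )
            label = "Endpoint" if data.get("kind") == "endpoint" else "Gene"
            lines.append(
                f"CREATE (:{label} {{id: {json.dumps(node)}, {props}}});"
            )
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            lines.append(
                f"MATCH (a {{id: {json.dumps(u)}}}), (b {{id: {json.dumps(v)}}}) "
                f"CREATE (a)-[:INVOLVED_IN]->(b);"
            )
        out.write_text("\n".join(lines) + "\n")
        return [out]
    raise UsageError(f"unknown export format: {fmt!r} (graphml|tsv|statements)")


def write_region_summary(partition: VennPartition, path: str | Path) -> None:
    """Write the Venn region-size JSON summary (signature -> count)."""
    with open(path, "w") as fh:
        json.dump(partition.region_sizes(), fh, indent=2, sort_keys=True)
        fh.write("\n")
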