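"""Synthetic knowledge-base fixtures with planted ground truth.

Generates self-consistent CTD/OBO/GAF/UniProt-dialect files in which the
endpoint gene sets, Venn region contents, secreted subsets and per-chemical
top genes are *planted* and recorded in a manifest, so the whole pipeline
can be tested for exact recovery without the external databases.  Decoy
gene symbols come from a synthetic alphabet (``SYN0001``...) so fixtures
can never be mistaken for biological claims.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ctd import DEFAULT_ENDPOINTS, ENDPOINT_ORDER, EndpointDefinition
from .errors import ConfigurationError
from .genes import canonicalize_gene
from .overlap import canonical_signature

__all__ = [
    "FixtureConfig",
    "FixtureManifest",
    "generate_fixture",
    "paper_core_fixture",
    "CORE_OVERLAP_MOLECULES",
]

#: The 15 molecules shared by all four endpoint gene sets in the worked
#: example (the composite HLA-DQA2/HLA-DQA1 counts as one molecule).
CORE_OVERLAP_MOLECULES: tuple[str, ...] = (
    "ALB", "HLA-DPB1", "HLA-DQA2/HLA-DQA1", "HLA-DRB1", "ICAM1", "IFNG",
    "IL1B", "IL4", "IL6", "IL10", "IL12B", "IL18", "MPO", "CCL2", "TNF",
)


@dataclass(frozen=True)
class ChemicalSpec:
    """One planted chemical: its intended endpoint-hit pattern and top-n size."""

    name: str
    hit_pattern: frozenset[str]
    n_genes: int = 10


@dataclass
class FixtureConfig:
    seed: int = 0
    region_sizes: dict[tuple[str, ...], int] = field(default_factory=dict)
    region_genes: dict[tuple[str, ...], tuple[str, ...]] = field(default_factory=dict)
    secreted_fraction: float = 0.4
    chemicals: tuple[ChemicalSpec, ...] = ()
    mesh_depth: int = 3
    decoy_genes: int = 12
    endpoints: tuple[EndpointDefinition, ...] = DEFAULT_ENDPOINTS

    def __post_init__(self) -> None:
        if not 0.0 <= self.secreted_fraction <= 1.0:
            raise ConfigurationError("secreted_fraction must lie in [0, 1]")
        if any(n < 0 for n in self.region_sizes.values()):
            raise ConfigurationError("region sizes must be non-negative")
        if self.mesh_depth < 1:
            raise ConfigurationError("mesh_depth must be >= 1")
        names = {e.name for e in self.endpoints}
        for sig in set(self.region_sizes) | set(self.region_genes):
            if not sig or not set(sig) <= names:
                raise ConfigurationError(f"bad region signature: {sig!r}")
        for spec in self.chemicals:
            if not spec.hit_pattern <= names:
                raise ConfigurationError(
                    f"chemical {spec.name!r}: unknown endpoints in hit pattern"
                )
            if spec.n_genes < 1:
                raise ConfigurationError(f"chemical {spec.name!r}: n_genes must be >= 1")


@dataclass
class FixtureManifest:
    """Ground truth planted into a generated fixture."""

    endpoint_sets: dict[str, list[str]]
    regions: dict[str, list[str]]  # "&"-joined signature -> symbols
    secreted: list[str]
    chemicals: dict[str, dict]  # name -> {top_genes, expected_flags}
    files: dict[str, str]
    seed: int

    def to_json(self) -> str:
        # file names only: the manifest must not depend on where it lives
        return json.dumps(
            {
                "seed": self.seed,
                "endpoint_sets": self.endpoint_sets,
                "regions": self.regions,
                "secreted": self.secreted,
                "chemicals": self.chemicals,
                "files": {k: Path(v).name for k, v in self.files.items()},
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


def _mesh_tree(
    endpoints: Sequence[EndpointDefinition], depth: int, rng: random.Random
) -> tuple[list[tuple[str, str, str]], dict[str, list[str]]]:
    """Synthesize descendant terms (1..depth levels) under every root.

    Returns vocabulary rows (name, id, parents) and endpoint -> subtree terms.
    """
    rows: list[tuple[str, str, str]] = []
    subtree: dict[str, list[str]] = {}
    counter = 9700000
    for ep in endpoints:
        terms: list[str] = []
        for root in ep.mesh_root_ids:
            rows.append((f"{ep.name} root", root, ""))
            terms.append(root)
            parents = [root]
            for _ in range(depth):
                level: list[str] = []
                for parent in parents:
                    for _ in range(rng.randint(1, 2)):
                        counter += 1
                        child = f"MESH:D{counter}"
                        rows.append((f"synthetic term {counter}", child, parent))
                        level.append(child)
                        terms.append(child)
                parents = level
        subtree[ep.name] = terms
    # a disjoint decoy subtree no endpoint claims
    rows.append(("unrelated root", "MESH:D9990000", ""))
    decoy_terms = []
    for i in range(1, 4):
        child = f"MESH:D999000{i}"
        rows.append((f"unrelated term {i}", child, "MESH:D9990000"))
        decoy_terms.append(child)
    subtree["_decoy"] = decoy_terms
    return rows, subtree


def _allocate_regions(config: FixtureConfig, rng: random.Random) -> dict[tuple[str, ...], list[str]]:
    regions: dict[tuple[str, ...], list[str]] = {}
    counter = 0
    for sig in sorted(set(config.region_sizes) | set(config.region_genes),
                      key=lambda s: canonical_signature(s)):
        csig = canonical_signature(sig)
        explicit = [canonicalize_gene(s).symbol for s in config.region_genes.get(sig, ())]
        need = max(config.region_sizes.get(sig, 0), len(explicit))
        symbols = list(explicit)
        while len(symbols) < need:
            counter += 1
            symbols.append(f"SYN{counter:04d}")
        if symbols:
            regions[csig] = symbols
    # cross-region duplicate symbols would break disjointness
    seen: set[str] = set()
    for symbols in regions.values():
        for s in symbols:
            if s in seen:
                raise ConfigurationError(f"symbol {s!r} planted in two regions")
            seen.add(s)
    return regions


def _pick_chemical_genes(
    spec: ChemicalSpec,
    regions: Mapping[tuple[str, ...], list[str]],
    decoys: Sequence[str],
    rng: random.Random,
) -> list[str]:
    """Top genes whose signatures are subsets of, and jointly cover, the pattern."""
    eligible: list[str] = []
    for sig, symbols in sorted(regions.items()):
        if set(sig) <= spec.hit_pattern:
            eligible.extend(symbols)
    chosen: list[str] = []
    for endpoint in sorted(spec.hit_pattern):
        candidates = [
            s for sig, symbols in sorted(regions.items())
            if endpoint in sig and set(sig) <= spec.hit_pattern
            for s in symbols if s not in chosen
        ]
        if not candidates:
            raise ConfigurationError(
                f"chemical {spec.name!r}: no gene can realize endpoint "
                f"{endpoint!r} within pattern {sorted(spec.hit_pattern)}"
            )
        chosen.append(rng.choice(candidates))
    fill_pool = [s for s in eligible if s not in chosen] + [
        d for d in decoys if d not in chosen
    ]
    if len(chosen) + len(fill_pool) < spec.n_genes:
        raise ConfigurationError(
            f"chemical {spec.name!r}: cannot reach {spec.n_genes} genes"
        )
    while len(chosen) < spec.n_genes:
        chosen.append(fill_pool.pop(0))
    return chosen[: spec.n_genes]


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> FixtureManifest:
    """Write all fixture files plus ``manifest.json`` into ``out_dir``.

    The same config (including seed) always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)

    vocab_rows, subtree = _mesh_tree(config.endpoints, config.mesh_depth, rng)
    regions = _allocate_regions(config, rng)
    endpoint_sets: dict[str, list[str]] = {e.name: [] for e in config.endpoints}
    for sig, symbols in sorted(regions.items()):
        for name in sig:
            endpoint_sets[name].extend(symbols)
    for name in endpoint_sets:
        endpoint_sets[name] = sorted(endpoint_sets[name])
    decoys = [f"DEC{i:04d}" for i in range(1, config.decoy_genes + 1)]

    files: dict[str, str] = {}

    # --- disease vocabulary -------------------------------------------------
    vocab_path = out / "disease_vocabulary.tsv"
    with open(vocab_path, "w") as fh:
        fh.write("# DiseaseName\tDiseaseID\tParentIDs\n")
        for name, disease_id, parents in vocab_rows:
            fh.write(f"{name}\t{disease_id}\t{parents}\n")
    files["disease_vocabulary"] = str(vocab_path)

    # --- disease-gene associations -----------------------------------------
    dg_path = out / "disease_gene.tsv"
    with open(dg_path, "w") as fh:
        fh.write(
            "# GeneSymbol\tGeneID\tDiseaseName\tDiseaseID\tDirectEvidence"
            "\tInferenceScore\tPubMedIDs\n"
        )
        gene_ids: dict[str, int] = {}

        def gid(symbol: str) -> int:
            return gene_ids.setdefault(symbol, 100000 + len(gene_ids))

        for ep in config.endpoints:
            terms = subtree[ep.name]
            for symbol in endpoint_sets[ep.name]:
                term = rng.choice(terms)
                label = rng.choice(["marker/mechanism", "therapeutic"])
                refs = "|".join(
                    str(rng.randint(10000000, 39999999))
                    for _ in range(rng.randint(1, 3))
                )
                fh.write(
                    f"{symbol}\t{gid(symbol)}\tsynthetic disease\t{term}"
                    f"\t{label}\t\t{refs}\n"
                )
            # inferred rows inside the subtree: must be dropped by the
            # curated filter or they would contaminate the planted sets
            for decoy in decoys[: max(2, len(decoys) // 3)]:
                term = rng.choice(terms)
                fh.write(
                    f"{decoy}\t{gid(decoy)}\tsynthetic disease\t{term}"
                    f"\t\t{rng.random() * 50:.2f}\t\n"
                )
        # curated decoy rows on the unrelated subtree
        for decoy in decoys:
            term = rng.choice(subtree["_decoy"])
            fh.write(
                f"{decoy}\t{gid(decoy)}\tunrelated disease\t{term}"
                f"\tmarker/mechanism\t\t{rng.randint(10000000, 39999999)}\n"
            )
    files["disease_gene"] = str(dg_path)

    # --- secretome table ----------------------------------------------------
    universe = sorted({s for symbols in regions.values() for s in symbols})
    secreted: list[str] = []
    up_path = out / "uniprot_annotations.tsv"
    with open(up_path, "w") as fh:
        fh.write("GeneSymbol\tKeywords\tSubcellularLocation\n")
        for symbol in universe + decoys:
            node = canonicalize_gene(symbol)
            any_secreted = False
            for member in node.members:
                if rng.random() < config.secreted_fraction:
                    any_secreted = True
                    fh.write(f"{member}\tCytokine;Secreted\tSecreted\n")
                else:
                    fh.write(f"{member}\tMembrane\tCell membrane\n")
            if any_secreted and symbol in universe:
                secreted.append(node.symbol)
    files["uniprot"] = str(up_path)

    # --- chemical-gene interactions ----------------------------------------
    chemicals: dict[str, dict] = {}
    cg_path = out / "chemical_gene.tsv"
    with open(cg_path, "w") as fh:
        fh.write(
            "# ChemicalName\tChemicalID\tGeneSymbol\tInteractionActions"
            "\tInteractionCount\tPubMedIDs\n"
        )
        for i, spec in enumerate(config.chemicals, start=1):
            chem_id = f"SYNCHEM:C{i:03d}"
            top = _pick_chemical_genes(spec, regions, decoys, rng)
            for j, symbol in enumerate(top):
                count = 100 - j  # strictly decreasing: ranks are unambiguous
                refs = "|".join(
                    str(rng.randint(10000000, 39999999))
                    for _ in range(rng.randint(1, 4))
                )
                fh.write(
                    f"{spec.name}\t{chem_id}\t{symbol}\t"
                    f"increases^expression\t{count}\t{refs}\n"
                )
            # below-cutoff filler rows never reach the top-n
            for k, decoy in enumerate(decoys[:3]):
                fh.write(
                    f"{spec.name}\t{chem_id}\t{decoy}FILL\t"
                    f"affects^binding\t{1}\t{rng.randint(10000000, 39999999)}\n"
                )
            chemicals[spec.name] = {
                "chemical_id": chem_id,
                "top_genes": [canonicalize_gene(s).symbol for s in top],
                "n_genes": spec.n_genes,
                "expected_flags": sorted(
                    spec.hit_pattern,
                    key=lambda n: ENDPOINT_ORDER.index(n) if n in ENDPOINT_ORDER else 99,
                ),
            }
    files["chemical_gene"] = str(cg_path)

    # --- GO layer -----------------------------------------------------------
    obo_path = out / "ontology.obo"
    gaf_path = out / "annotations.gaf"
    go_terms: dict[str, tuple[str, str]] = {}  # endpoint -> (parent id, child id)
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: syn\n")
        go_counter = 9100000
        for ep in config.endpoints:
            keyword = ep.go_keywords[0] if ep.go_keywords else ep.name
            go_counter += 1
            parent = f"GO:{go_counter % 10000000:07d}"
            go_counter += 1
            child = f"GO:{go_counter % 10000000:07d}"
            fh.write(
                f"\n[Term]\nid: {parent}\nname: {keyword} response\n"
                "namespace: biological_process\n"
            )
            fh.write(
                f"\n[Term]\nid: {child}\nname: regulation of {ep.name} process\n"
                f"namespace: biological_process\nis_a: {parent}\n"
            )
            go_terms[ep.name] = (parent, child)
        fh.write(
            "\n[Term]\nid: GO:9199998\nname: synthetic binding\n"
            "namespace: molecular_function\n"
        )
        fh.write(
            "\n[Term]\nid: GO:9199999\nname: withdrawn process\n"
            "namespace: biological_process\nis_obsolete: true\n"
        )
    with open(gaf_path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for ep in config.endpoints:
            parent, child = go_terms[ep.name]
            annotated = endpoint_sets[ep.name][:5]
            for symbol in annotated:
                for member in canonicalize_gene(symbol).members:
                    fh.write(
                        f"SYNDB\t{member}\t{member}\tinvolved_in\t{child}\t"
                        f"SYN:0001\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t"
                        f"20180101\tSYNDB\n"
                    )
            if decoys:
                fh.write(
                    f"SYNDB\t{decoys[0]}\t{decoys[0]}\tNOT|involved_in\t{parent}\t"
                    f"SYN:0001\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t"
                    f"20180101\tSYNDB\n"
                )
    files["obo"] = str(obo_path)
    files["gaf"] = str(gaf_path)

    manifest = FixtureManifest(
        endpoint_sets={
            name: sorted(canonicalize_gene(s).symbol for s in symbols)
            for name, symbols in endpoint_sets.items()
        },
        regions={
            "&".join(sig): sorted(canonicalize_gene(s).symbol for s in symbols)
            for sig, symbols in regions.items()
        },
        secreted=sorted(secreted),
        chemicals=chemicals,
        files=files,
        seed=config.seed,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    files["manifest"] = str(out / "manifest.json")
    return manifest


def random_fixture_config(seed: int) -> FixtureConfig:
    """A randomized but satisfiable fixture configuration for recovery tests."""
    rng = random.Random(seed)
    names = [e.name for e in DEFAULT_ENDPOINTS]
    region_sizes: dict[tuple[str, ...], int] = {}
    # always populate the singletons so every chemical pattern is realizable
    for name in names:
        region_sizes[(name,)] = rng.randint(2, 6)
    all_sigs = []
    for mask in range(1, 2 ** len(names)):
        sig = tuple(n for i, n in enumerate(names) if mask & (1 << i))
        if len(sig) > 1:
            all_sigs.append(sig)
    for sig in rng.sample(all_sigs, rng.randint(3, len(all_sigs))):
        region_sizes[canonical_signature(sig)] = rng.randint(1, 5)
    chemicals = []
    for i in range(rng.randint(1, 3)):
        pattern = frozenset(rng.sample(names, rng.randint(1, 4)))
        chemicals.append(ChemicalSpec(f"synchem-{seed}-{i}", pattern, rng.randint(4, 10)))
    return FixtureConfig(
        seed=seed,
        region_sizes=region_sizes,
        secreted_fraction=rng.uniform(0.2, 0.8),
        chemicals=tuple(chemicals),
        mesh_depth=rng.randint(1, 4),
        decoy_genes=rng.randint(10, 16),
    )


def paper_core_fixture(out_dir: str | Path) -> FixtureManifest:
    """The worked-example fixture: four endpoint sets of 20 genes each.

    Every endpoint set contains the printed 15-molecule core plus 5
    endpoint-unique synthetic decoys, with a bleomycin-like chemical
    hitting all four endpoints and a bortezomib-like chemical hitting
    only infection.
    """
    names = [e.name for e in DEFAULT_ENDPOINTS]
    config = FixtureConfig(
        seed=2018,
        region_sizes={(n,): 5 for n in names},
        region_genes={tuple(names): CORE_OVERLAP_MOLECULES},
        secreted_fraction=0.5,
        chemicals=(
            ChemicalSpec("bleomycin-like", frozenset(names), 10),
            ChemicalSpec("bortezomib-like", frozenset({"infection"}), 10),
        ),
        mesh_depth=2,
        decoy_genes=12,
    )
    return generate_fixture(config, out_dir)
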