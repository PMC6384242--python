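"""Pipeline configuration: YAML loading and the shipped endpoint defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .ctd import DEFAULT_ENDPOINTS, EndpointDefinition
from .errors import ConfigurationError, InputError

__all__ = ["PipelineConfig", "load_config", "default_endpoint_block"]


@dataclass
class PipelineConfig:
    endpoints: tuple[EndpointDefinition, ...]
    inputs: dict[str, str]
    out_dir: str = "out"
    curated_only: bool = True
    union_go: bool = False
    propagate: bool = True
    exclude_endpoints: tuple[str, ...] = ()
    top_n: int = 10
    threshold: int = 1
    enrichment: bool = False
    screen_chemicals: tuple[str, ...] = ()
    seed: int = 0

    REQUIRED_INPUTS = ("disease_gene", "disease_vocabulary")
    OPTIONAL_INPUTS = ("chemical_gene", "uniprot", "obo", "gaf")

    def __post_init__(self) -> None:
        if not self.endpoints:
            raise ConfigurationError("at least one endpoint must be defined")
        names = [e.name for e in self.endpoints]
        if len(set(names)) != len(names):
            raise ConfigurationError("endpoint names must be unique")
        for key in self.REQUIRED_INPUTS:
            if key not in self.inputs:
                raise ConfigurationError(f"missing required input path: {key}")
        if self.top_n < 1 or self.threshold < 1:
            raise ConfigurationError("top_n and threshold must be >= 1")

    def input_path(self, key: str, required: bool = True) -> Path | None:
        raw = self.inputs.get(key)
        if raw is None:
            if required:
                raise ConfigurationError(f"input {key!r} not configured")
            return None
        p = Path(raw)
        if not p.exists():
            raise InputError(f"input {key!r}: file not found: {p}")
        return p


def default_endpoint_block() -> list[dict[str, Any]]:
    """The shipped endpoint definitions as a YAML-ready block.

    Note: one widely circulated statement of the infection roots carries an
    8-digit "D0101272"; MeSH descriptors are 7 characters and the intended
    descriptor is parasitic diseases D010272, which is what ships here.
    """
    return [
        {
            "name": e.name,
            "mesh_root_ids": list(e.mesh_root_ids),
            "go_keywords": list(e.go_keywords),
        }
        for e in DEFAULT_ENDPOINTS
    ]


def _parse_endpoints(block: Any) -> tuple[EndpointDefinition, ...]:
    if not block:
        return DEFAULT_ENDPOINTS
    endpoints = []
    for item in block:
        endpoints.append(
            EndpointDefinition(
                name=str(item["name"]),
                mesh_root_ids=tuple(item["mesh_root_ids"]),
                go_keywords=tuple(item.get("go_keywords", ())),
            )
        )
    return tuple(endpoints)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML file."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"config file not found: {p}")
    with open(p) as fh:
        raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
    options = raw.get("options", {}) or {}
    return PipelineConfig(
        endpoints=_parse_endpoints(raw.get("endpoints")),
        inputs=dict(raw.get("inputs", {}) or {}),
        out_dir=str(raw.get("out_dir", "out")),
        curated_only=bool(options.get("curated_only", True)),
        union_go=bool(options.get("union_go", False)),
        propagate=bool(options.get("propagate", True)),
        exclude_endpoints=tuple(options.get("exclude_endpoints", ()) or ()),
        top_n=int(options.get("top_n", 10)),
        threshold=int(options.get("threshold", 1)),
        enrichment=bool(options.get("enrichment", False)),
        screen_chemicals=tuple(raw.get("screen_chemicals", ()) or ()),
        seed=int(raw.get("seed", 0)),
    )


def config_for_fixture(
    fixture_dir: str | Path, out_dir: str | Path, **options: Any
) -> PipelineConfig:
    """Convenience: a config wired to a generated fixture directory."""
    fixture_dir = Path(fixture_dir)
    inputs = {
        "disease_gene": str(fixture_dir / "disease_gene.tsv"),
        "disease_vocabulary": str(fixture_dir / "disease_vocabulary.tsv"),
        "chemical_gene": str(fixture_dir / "chemical_gene.tsv"),
        "uniprot": str(fixture_dir / "uniprot_annotations.tsv"),
        "obo": str(fixture_dir / "ontology.obo"),
        "gaf": str(fixture_dir / "annotations.gaf"),
    }
    return PipelineConfig(
        endpoints=DEFAULT_ENDPOINTS, inputs=inputs, out_dir=str(out_dir), **options
    )


def write_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialise a config back to YAML (used by ``simulate`` for convenience)."""
    payload = {
        "endpoints": [
            {
                "name": e.name,
                "mesh_root_ids": list(e.mesh_root_ids),
                "go_keywords": list(e.go_keywords),
            }
            for e in config.endpoints
        ],
        "inputs": dict(config.inputs),
        "out_dir": config.out_dir,
        "options": {
            "curated_only": config.curated_only,
            "union_go": config.union_go,
            "propagate": config.propagate,
            "exclude_endpoints": list(config.exclude_endpoints),
            "top_n": config.top_n,
            "threshold": config.threshold,
            "enrichment": config.enrichment,
        },
        "screen_chemicals": list(config.screen_chemicals),
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
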