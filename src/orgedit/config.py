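"""Run configuration: YAML file + CLI flag plumbing with strict validation.

Unknown keys are rejected by name; omitted keys take package defaults; a
dump/load round trip is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .differential import TestConfig
from .errors import ConfigError


@dataclass(frozen=True)
class PathsConfig:
    annotation: str | None = None
    counts: str | None = None
    alignments: str | None = None
    design: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic generator: 612 sites
    (576 mitochondrial + 36 plastid) over 24 transcripts, two replicates per
    genotype, effect fractions 14% increased / 3% decreased among
    mitochondrial sites with |Δ| in [0.15, 0.4]."""

    n_mito: int = 576
    n_plastid: int = 36
    n_transcripts: int = 24
    replicates: int = 2
    depth: int = 2000
    frac_increased: float = 0.14
    frac_decreased: float = 0.03
    delta_low: float = 0.15
    delta_high: float = 0.4
    base_extent_low: float = 0.2
    base_extent_high: float = 0.9
    error_rate: float = 0.0
    dispersion: float | None = None
    seed: int = 1


@dataclass(frozen=True)
class SplicingConfig:
    anchor: int = 6
    tolerance: int = 0


@dataclass(frozen=True)
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    test: TestConfig = field(default_factory=TestConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    splicing: SplicingConfig = field(default_factory=SplicingConfig)
    output_dir: str = "orgedit_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTION_TYPES = {
    "paths": PathsConfig,
    "test": TestConfig,
    "simulation": SimulationConfig,
    "splicing": SplicingConfig,
}


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        section = raw.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section, f"section {name!r}")
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return RunConfig(**kwargs)


def provenance(config: RunConfig, seed: int, extra: dict | None = None) -> dict:
    """Provenance block written next to every stage output (no timestamp, so
    identical runs produce byte-identical files)."""
    from . import __version__
    block = {"version": __version__, "config_hash": config.config_hash(),
             "seed": seed}
    if extra:
        block.update(extra)
    return block
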