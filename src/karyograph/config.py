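"""Validated pipeline configuration (YAML).

Unknown keys are rejected and all problems are reported in one aggregated
message; defaults mirror the stage functions' defaults so a minimal config is
valid.  The effective (defaults-filled) config is echoed into the output
directory for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesEntry(_Strict):
    id: str
    annotation: str
    format: str = "bed"
    genome_size: Optional[int] = None


class SimulateBlock(_Strict):
    tree: str = "(A:1,B:1,C:1,D:1,E:1,F:1);"
    n_ancestral_chromosomes: int = Field(18, ge=1)
    genes_per_chromosome: int = Field(150, ge=1)
    fusion_rate: float = Field(2.0, ge=0)
    fission_rate: float = Field(2.0, ge=0)
    translocation_rate: float = Field(0.5, ge=0)
    transposition_rate: float = Field(200.0, ge=0)
    gene_loss_rate: float = Field(0.0, ge=0)
    gene_dup_rate: float = Field(0.0, ge=0)


class AlgBlock(_Strict):
    resolutions: list[float] = [0.5, 1.0, 2.0]
    n_runs: int = Field(20, ge=2)
    min_support: int = Field(2, ge=1)
    co_threshold: float = Field(0.5, ge=0, le=1)


class MacroBlock(_Strict):
    min_fraction: float = Field(0.05, ge=0, le=1)
    min_count: int = Field(5, ge=1)


class MicroBlock(_Strict):
    max_intervening: list[int] = [0, 5]
    min_lens: list[int] = [2, 3, 4]


class UceBlock(_Strict):
    min_identity: float = Field(0.95, gt=0, le=1)
    window: int = Field(20, ge=2)


class TopologyBlock(_Strict):
    window_bins: int = Field(10, ge=1)
    min_prominence: float = Field(0.1, ge=0)


class AtacBlock(_Strict):
    n_peaks: int = Field(1000, ge=0)
    mean_distance: float = Field(100.0, gt=0)


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "karyograph_out"
    species: list[SpeciesEntry] = []
    clades: dict[str, list[str]] = {}
    orthogroups: Optional[str] = None
    simulate: SimulateBlock = SimulateBlock()
    alg: AlgBlock = AlgBlock()
    macro: MacroBlock = MacroBlock()
    micro: MicroBlock = MicroBlock()
    uce: UceBlock = UceBlock()
    topology: TopologyBlock = TopologyBlock()
    atac: AtacBlock = AtacBlock()


class ConfigError(ValueError):
    """Aggregated configuration problems."""


def validate_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    problems: list[str] = []
    try:
        cfg = PipelineConfig.model_validate(data)
    except ValidationError as e:
        for err in e.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            problems.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            f"invalid config {path}:\n  " + "\n  ".join(problems)
        ) from None
    for sp in cfg.species:
        p = (path.parent / sp.annotation).resolve() \
            if not Path(sp.annotation).is_absolute() else Path(sp.annotation)
        if not p.exists():
            problems.append(f"species {sp.id}: annotation not found: {sp.annotation}")
        else:
            sp.annotation = str(p)
    if cfg.orthogroups is not None:
        p = (path.parent / cfg.orthogroups).resolve() \
            if not Path(cfg.orthogroups).is_absolute() else Path(cfg.orthogroups)
        if not p.exists():
            problems.append(f"orthogroups table not found: {cfg.orthogroups}")
        else:
            cfg.orthogroups = str(p)
    for clade, members in cfg.clades.items():
        ids = {sp.id for sp in cfg.species}
        for m in members:
            if m not in ids:
                problems.append(f"clade {clade}: unknown species {m!r}")
    if problems:
        raise ConfigError(
            f"invalid config {path}:\n  " + "\n  ".join(problems)
        )
    return cfg


def echo_config(cfg: PipelineConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = outdir / "effective_config.yaml"
    with open(target, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
    return target
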