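"""Pipeline configuration: thresholds, stage toggles and input/output paths.

Loaded from YAML (``PipelineConfig.from_yaml``) with a flat override
mechanism used by the CLI.  When ``simulate`` is enabled the synthetic
generator provides every input; otherwise each enabled stage must point at
an existing file, checked up front before any stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from mirlocus.synthdata import SimulationConfig


@dataclass
class Thresholds:
    alpha: float = 0.05
    lfc_min: float = 1.0
    min_total_count: int = 10
    score_min: float = 150.0
    energy_max: float = -20.0
    score_scale: float = 1.5
    top_k: int = 10
    n_perm: int = 999
    n_clusters: int = 8

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.energy_max > 0:
            raise ValueError("energy_max must be <= 0")
        if self.top_k < 1 or self.n_perm < 1 or self.n_clusters < 1:
            raise ValueError("top_k, n_perm and n_clusters must be >= 1")


@dataclass
class Stages:
    simulate: bool = True
    profile: bool = True
    de: bool = True
    locus: bool = True
    targets: bool = True
    enrich: bool = True
    qpcr: bool = True


@dataclass
class InputPaths:
    """Only consulted when simulate is off."""

    annotation: str | None = None
    annotation_format: str | None = None
    counts: str | None = None
    samples: str | None = None
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    genesets: str | None = None
    reads_fasta: str | None = None
    qpcr: str | None = None


@dataclass
class PipelineConfig:
    outdir: str = "mirlocus_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: Stages = field(default_factory=Stages)
    inputs: InputPaths = field(default_factory=InputPaths)
    # locus definition; defaults to the simulated locus when simulating
    locus_name: str | None = None
    locus_chrom: str | None = None
    locus_start: int | None = None
    locus_end: int | None = None

    def __post_init__(self) -> None:
        self.simulation = _coerce(SimulationConfig, self.simulation)
        self.thresholds = _coerce(Thresholds, self.thresholds)
        self.stages = _coerce(Stages, self.stages)
        self.inputs = _coerce(InputPaths, self.inputs)

    def validate(self) -> None:
        self.thresholds.validate()
        self.simulation.validate()
        if not self.stages.simulate:
            needed = {
                "de": ["counts", "samples"],
                "locus": ["annotation"],
                "targets": ["mirna_fasta", "utr_fasta"],
                "enrich": ["genesets"],
                "profile": ["reads_fasta"],
                "qpcr": ["qpcr"],
            }
            for stage, keys in needed.items():
                if not getattr(self.stages, stage):
                    continue
                for key in keys:
                    path = getattr(self.inputs, key)
                    if path is None:
                        raise ValueError(
                            f"stage {stage!r} enabled without simulation but "
                            f"inputs.{key} is unset"
                        )
                    if not Path(path).exists():
                        raise FileNotFoundError(f"inputs.{key}: {path} does not exist")
            if self.stages.locus and (
                self.locus_chrom is None or self.locus_start is None or self.locus_end is None
            ):
                raise ValueError("locus stage needs locus_chrom/locus_start/locus_end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _coerce(cls, value):
    if isinstance(value, cls):
        return value
    if isinstance(value, dict):
        known = {f.name for f in fields(cls)}
        unknown = set(value) - known
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        coerced = {}
        for key, val in value.items():
            ftype = next(f.type for f in fields(cls) if f.name == key)
            coerced[key] = tuple(val) if isinstance(val, list) and "tuple" in str(ftype) else val
        return cls(**coerced)
    raise TypeError(f"cannot build {cls.__name__} from {type(value).__name__}")
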