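"""Pipeline configuration: strict keys, YAML round-trip."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

STAGES = ("score", "qsar", "screen", "doe", "bonds")


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: ["score", "screen", "doe", "bonds"])
    scores_path: str | None = None
    predictions_path: str | None = None
    env_path: str | None = None
    responses_path: str | None = None
    interactions_path: str | None = None
    structures_dir: str | None = None
    activity_path: str | None = None
    out_dir: str = "synergy_out"
    tie_policy: str = "average"
    weight_mode: str = "own_docking_scores"
    template: str = "BDEs-3"
    grid_spacing: float = 2.0
    grid_margin: float = 4.0
    steric_cutoff: float = 30.0
    min_sigma: float = 2.0
    seed: int = 0
    hydrophobic_set: list[str] = field(
        default_factory=lambda: ["ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"]
    )
    energy_unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
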