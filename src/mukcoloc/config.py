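"""Run configuration: the shared parameters of all stages, YAML round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidSpecError

#: Chromosomal locus labels used in reports (metadata only; the analysis is
#: agnostic to which operator array a channel carries).
DEFAULT_LOCI = {
    "ori1": "lacO array 15 kb counterclockwise of oriC",
    "ter3": "tetO array 50 kb clockwise of dif",
}

#: 13-bp palindromic matS consensus; injected via config, overridable.
DEFAULT_MATS_CONSENSUS = "GTGACRNYGTCAC"


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Every run writes its resolved config next to its outputs so results are
    reproducible from the artifact directory alone.
    """

    pixel_size_nm: float = 129.0
    coloc_threshold_nm: float = 258.0
    null_draws_per_cell: int = 10
    frame_interval_min: float = 5.0
    k_persist: int = 3
    cohesion_offset_min: float = 7.0
    min_separation_px: float = 2.0
    chip_window_bp: int = 2000
    chip_top_n: int = 26
    chip_bin_bp: int = 50
    chip_pseudocount: float = 0.5
    motif_consensus: str = DEFAULT_MATS_CONSENSUS
    motif_max_mismatch: int = 1
    seed: int = 0
    loci: dict = field(default_factory=lambda: dict(DEFAULT_LOCI))

    def validate(self) -> None:
        positive = (
            "pixel_size_nm",
            "coloc_threshold_nm",
            "frame_interval_min",
            "chip_window_bp",
            "chip_bin_bp",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"config field {name} must be > 0")
        if self.k_persist < 1:
            raise InvalidSpecError("config field k_persist must be >= 1")
        if self.cohesion_offset_min < 0:
            raise InvalidSpecError("config field cohesion_offset_min must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidSpecError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        config = cls(**data)
        config.validate()
        return config
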