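"""Run configuration: every tunable with its published default, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .flanks import EPCR_FLANK_LEN, SIGNATURE_FLANK_LEN, PrimerConstraints
from .mining import (
    DEFAULT_MAX_COMPOUND_INTERVAL,
    DEFAULT_MIN_REPEATS,
    HYPERVARIABLE_MIN_TRACT,
    MiningThresholds,
)

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_compound_interval: int = DEFAULT_MAX_COMPOUND_INTERVAL
    signature_flank_len: int = SIGNATURE_FLANK_LEN
    epcr_flank_len: int = EPCR_FLANK_LEN
    primer_min_len: int = 18
    primer_max_len: int = 27
    primer_min_tm: float = 57.0
    primer_max_tm: float = 63.0
    primer_min_gc: float = 30.0
    primer_max_gc: float = 70.0
    primer_min_product: int = 100
    primer_max_product: int = 300
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_upstream: int = 100
    tts_downstream: int = 1000
    hypervariable_min_tract: int = HYPERVARIABLE_MIN_TRACT
    seed: int = 0
    log_level: str = "INFO"

    def thresholds(self) -> MiningThresholds:
        return MiningThresholds(
            min_repeats=dict(self.min_repeats),
            max_compound_interval=self.max_compound_interval,
        )

    def primer_constraints(self) -> PrimerConstraints:
        return PrimerConstraints(
            min_len=self.primer_min_len,
            max_len=self.primer_max_len,
            min_tm=self.primer_min_tm,
            max_tm=self.primer_max_tm,
            min_gc=self.primer_min_gc,
            max_gc=self.primer_max_gc,
            min_product=self.primer_min_product,
            max_product=self.primer_max_product,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "min_repeats" in data:
        data["min_repeats"] = {int(k): int(v) for k, v in data["min_repeats"].items()}
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
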