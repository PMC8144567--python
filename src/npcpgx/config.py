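"""Pipeline configuration: serializable defaults and seed fan-out.

One global seed is fanned out to per-stage child seeds by stable hashing of
the stage name, so a stage can be rerun in isolation and reproduce exactly
what the full pipeline would have fed it.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml

from .simulate import DEFAULT_DOSES_UM, DEFAULT_SUBTYPE_FRACTIONS


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, stable across runs."""
    return (zlib.crc32(f"{stage}:{seed}".encode()) ^ seed) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "npcpgx_out"

    # cohort
    n_patients: int = 106
    subtype_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_FRACTIONS)
    )

    # dose-response
    doses_uM: list = field(default_factory=lambda: list(DEFAULT_DOSES_UM))
    n_reps: int = 3
    noise_sd: float = 5.0

    # synergy
    synergy_tol: float = 0.02
    synergy_min_points: int = 3
    fold_change_cut: float = 3.0
    ir_dose_gy: float = 4.0

    # variant filters
    max_pop_af: float = 0.0004
    min_t_depth: int = 20
    min_t_alt: int = 3
    max_n_alt: int = 1
    min_vaf: float = 0.05
    min_callers: int = 2

    # differential expression
    min_abs_log2fc: float = 1.0
    max_p: float = 0.05
    max_padj: float = 0.05

    # scoring
    label_quantile: float = 0.10
    ssgsea_alpha: float = 0.25
    null_n_genes: int = 105
    null_n_iter: int = 50

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        return child_seed(self.seed, stage)
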