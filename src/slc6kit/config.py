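"""Pipeline configuration: one place for every tunable default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults for the whole characterization pipeline.

    Hydropathy: ``window`` 19 / ``threshold`` 1.6 / ``min_tm_len`` 10 /
    ``merge_gap`` 5 is the classic Kyte-Doolittle membrane-protein
    setting. Alignment: BLOSUM62 with ClustalW-style protein penalties
    (open 10, extend 0.5). Distances default to the Poisson correction.
    PCR: no mismatches, exact 3-nt 3' anchor.
    """

    window: int = 19
    threshold: float = 1.6
    min_tm_len: int = 10
    merge_gap: int = 5
    n_term_side: str = "in"
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: str = "aligned_columns"
    min_occupancy: float = 0.5
    distance_model: str = "poisson_corrected"
    bootstrap_reps: int = 100
    seed: int = 0
    max_mismatch: int = 0
    anchor_3prime: int = 3
    max_amplicon_len: int = 5000

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
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

    def replace(self, **kwargs) -> "PipelineConfig":
        return self.from_dict({**self.to_dict(), **kwargs})
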