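"""Analysis thresholds, all surfaced in one configuration object.

Defaults are the cutoffs the study design fixes: differential expression at
P < 0.001 with fold change > 2, differential modification at P < 0.01 with
fold change > 1.5, replicate-discrepancy exclusion at P < 0.05, hybrid
mode-of-action tests at P < 0.001, allelic bias at P < 0.05, modification
calling at randomization P < 0.01, and siRNA clusters of >= 6 reads with
inter-read gaps <= 200 nt assigned to TE classes at >= 50% length overlap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class AnalysisConfig:
    p_expr: float = 0.001      # differential expression P cutoff
    p_mod: float = 0.01        # differential modification P cutoff
    fc_expr: float = 2.0       # expression fold-change cutoff
    fc_mod: float = 1.5        # modification fold-change cutoff
    p_replicate: float = 0.05  # replicate-discrepancy exclusion
    p_mode: float = 0.001      # hybrid-vs-MPV mode test
    p_ase: float = 0.05        # allelic-bias binomial test
    alpha_mod_call: float = 0.01   # randomization threshold for modified-gene calls
    n_randomizations: int = 1000
    active_quantile: float = 0.95  # intron-coverage quantile for active-gene calls
    min_reads: int = 6         # siRNA cluster: minimum reads
    max_gap: int = 200         # siRNA cluster: maximum inter-read gap, nt
    min_overlap_frac: float = 0.5  # TE assignment: minimum region-length overlap
    gap_mode: str = "start"    # siRNA gap measured start-to-start or end-to-start

    def __post_init__(self) -> None:
        for name in ("p_expr", "p_mod", "p_replicate", "p_mode", "p_ase",
                     "alpha_mod_call", "active_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in ("fc_expr", "fc_mod"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        if not 0 < self.min_overlap_frac <= 1:
            raise ValueError("min_overlap_frac must lie in (0,1]")
        if self.gap_mode not in ("start", "end"):
            raise ValueError("gap_mode must be 'start' or 'end'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
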