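"""Run configuration: every tunable of the pipeline in one flat mapping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass
class RunConfig:
    """Flat, losslessly-serializable pipeline configuration.

    Bin sizes in bp; windows in bins; S-phase duration in hours.  Defaults
    are the pipeline's standard operating point: 100-kb genome-wide /
    400-kb haplotype-resolved RT bins, 5-kb virtual-4C profiles against
    250-kb heatmap bins, sliding 200-kb windows at 80-kb steps for
    population RT, a 50-bin test window against a 1,200-bin background for
    far-cis calling, 250-bin trans windows, 201-fragment 4C smoothing, an
    FDR of 0.01, and a 10-hour S phase.
    """

    bin_size_genome: int = 100_000
    bin_size_haplotype: int = 400_000
    bin_size_profile: int = 5_000
    bin_size_heatmap: int = 250_000
    window_bp: int = 200_000
    step_bp: int = 80_000
    low_count_quantile: float = 0.05
    switch_delta: float = 0.5
    affected_delta: float = 0.4
    fdr: float = 0.01
    w_cis: int = 50
    bg_cis: int = 1200
    w_trans: int = 250
    fragment_window: int = 201
    s_hours: float = 10.0
    n_groups: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("low_count_quantile", "switch_delta", "affected_delta", "fdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for f in fields(self):
            if f.type == "int" and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
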