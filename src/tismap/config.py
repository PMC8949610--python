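"""Pipeline configuration.

Every threshold the pipeline uses lives here, with the defaults the analysis
was designed around: reads below mean Phred 7 or 1000 bp are removed, local
alignments must reach E < 1e-30, 500 bases of junction flank are extracted on
each side of a plasmid segment, and breakpoints within 100 bp cluster into
one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class QcThresholds:
    """Read-filter thresholds: remove reads with mean Q < 7 or length < 1000.

    The removal conditions are strict ``<``, so reads exactly at the
    boundaries are kept.  ``arithmetic_mean`` switches the quality average
    from the default probability-space mean to a plain arithmetic mean of
    Phred scores (sensitivity analysis only).
    """

    min_mean_q: float = 7.0
    min_length: int = 1000
    arithmetic_mean: bool = False

    def __post_init__(self) -> None:
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch rewards and affine gap costs (BLASTN-style defaults).

    A gap of length L costs ``gap_open + L * gap_extend``.  The defaults
    (+2/-3, open 5, extend 2) mirror the standard nucleotide local-alignment
    defaults, so hit/no-hit decisions track the tool this engine replaces.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        # expected score per aligned pair under uniform background must be
        # negative for local-alignment statistics to exist
        if 0.25 * self.match + 0.75 * self.mismatch >= 0:
            raise ValueError("expected score must be negative under uniform background")


@dataclass
class PipelineConfig:
    """All knobs for the integration-site pipeline.

    Defaults encode the published filtering rules (E-value gate 1e-30,
    500 bp flanks, one target / one HSP per flank) plus the decisions this
    package fixes itself (segment merge gap, cluster window, unit coverage
    fraction, seed length, X-drop).
    """

    qc: QcThresholds = field(default_factory=QcThresholds)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    evalue_max: float = 1e-30
    flank_len: int = 500
    min_flank_len: int = 50
    max_targets: int = 1
    max_hsps: int = 1
    seed_k: int = 11
    x_drop: int = 100
    merge_gap: int = 50
    cluster_window: int = 100
    min_support: int = 1
    unit_cover_frac: float = 0.9
    ambiguity_frac: float = 0.95
    peak_near_bp: int = 1000
    density_bin: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.qc, dict):
            self.qc = QcThresholds(**self.qc)
        if isinstance(self.scoring, dict):
            self.scoring = ScoringScheme(**self.scoring)
        for name in ("evalue_max", "flank_len", "min_flank_len", "seed_k", "x_drop",
                     "merge_gap", "cluster_window", "min_support", "peak_near_bp",
                     "density_bin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.unit_cover_frac <= 1):
            raise ValueError("unit_cover_frac must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
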