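"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Thresholds and window sizes used throughout the analysis.

    Defaults follow the study conditions: promoters are the 1,000 bp upstream
    of a TSS, motif scanning covers a ±1,500 bp window around each region
    center at a FIMO-style p-value cutoff of 1e-5, differential sites are
    called at BH-adjusted p <= 0.1, ChIP peaks are retained at >= 50%
    overlap with transcribed regions, and the ChIP-qPCR signal-to-noise
    reference line sits at 1.5.
    """

    promoter_length: int = 1000
    scan_window_halfwidth: int = 1500
    fimo_p_cutoff: float = 1e-5
    padj_cutoff: float = 0.1
    min_overlap_fraction: float = 0.5
    snr_reference: float = 1.5
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.promoter_length <= 0 or self.scan_window_halfwidth <= 0:
            raise ValueError("window sizes must be positive")
        if not (0 < self.fimo_p_cutoff <= 1):
            raise ValueError("fimo_p_cutoff must be in (0, 1]")
        if not (0 < self.padj_cutoff <= 1):
            raise ValueError("padj_cutoff must be in (0, 1]")
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
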