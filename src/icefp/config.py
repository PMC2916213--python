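"""Run configuration: every analysis threshold in one serialisable object.

Defaults are the study's published constants: 5x baseline RMS peak calling,
profile QC at 1e4 (ARISA) / 8e4 (T-RFLP) RFU cumulative height, binning
cut-offs of 1/2/4 bp by fragment-size range, presence thresholds of 1.0%
(ARISA) / 0.25% (T-RFLP) of cumulative height, phylotype identity thresholds
of 98% (bacteria) / 99% (archaea), two-sided alpha = 0.05, a -7 bp ARISA dye
offset, and subtype-to-OTU match tolerances of 1.0 / 2.5 bp.

Configs round-trip losslessly through a YAML file (``key: value`` text).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    assay: str = "ARISA"
    seed: int = 0
    output_dir: str = "icefp_out"
    # trace processing
    lowpass_cutoff: float = 0.1  # fraction of Nyquist
    peak_threshold_multiple: float = 5.0
    min_peak_separation_scans: int = 10
    recover_saturated: bool = True
    dye_offset_bp: dict = field(
        default_factory=lambda: {"ARISA": -7.0, "TRFLP": 0.0}
    )
    # profile QC and binning
    min_cumulative_height: dict = field(
        default_factory=lambda: {"ARISA": 1.0e4, "TRFLP": 8.0e4}
    )
    presence_threshold: dict = field(
        default_factory=lambda: {"ARISA": 0.010, "TRFLP": 0.0025}
    )
    bin_cutoffs_bp: tuple = (1.0, 2.0, 4.0)  # [70,700), [700,1200), >=1200
    presence_per_cell: bool = False
    # community statistics
    alpha: float = 0.05
    simprof_n_perm_expected: int = 999
    simprof_n_perm_p: int = 999
    simprof_confidence: float = 0.95
    log_covariate: bool = False
    # clone-library analysis
    phylotype_threshold: dict = field(
        default_factory=lambda: {"bacteria": 0.98, "archaea": 0.99}
    )
    libshuff_n_perm: int = 999
    libshuff_grid_step: float = 0.01
    match_tight_bp: float = 1.0
    match_loose_bp: float = 2.5
    offset_search_bp: tuple = (-15, 15)

    def __post_init__(self) -> None:
        if self.assay not in ("ARISA", "TRFLP"):
            raise ValueError(f"unknown assay {self.assay!r}")
        self.bin_cutoffs_bp = tuple(self.bin_cutoffs_bp)
        self.offset_search_bp = tuple(self.offset_search_bp)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["bin_cutoffs_bp"] = list(self.bin_cutoffs_bp)
        data["offset_search_bp"] = list(self.offset_search_bp)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
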