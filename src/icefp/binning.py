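"""Cross-sample OTU binning of size-calibrated fingerprint peaks.

Pools the calibrated peaks of all QC-passed profiles and bins them into
OTUs with size-dependent distance cut-offs (1 bp below 700 bp, 2 bp for
700-1200 bp, 4 bp above), using deterministic height-ranked greedy seeding:
peaks are visited in order of descending height, each peak that is not
within the cut-off of an existing seed becomes a new seed, and every peak is
then assigned to its nearest seed. Within a sample, multiple member peaks of
one bin have their heights summed, so total signal is conserved exactly.

Profile-level QC (minimum cumulative peak height) and the relative-height
presence/absence filter are also implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trace import Peak

__all__ = [
    "Profile",
    "OTUTable",
    "PresenceMatrix",
    "filter_profiles",
    "bin_cutoff_for_length",
    "bin_peaks",
    "presence_matrix",
    "signal_fraction",
    "core_otus",
    "MIN_CUMULATIVE_HEIGHT",
    "PRESENCE_THRESHOLD",
]

#: profile QC: minimum cumulative peak height (RFU) per assay
MIN_CUMULATIVE_HEIGHT = {"ARISA": 1.0e4, "TRFLP": 8.0e4}
#: presence filter: relative peak height an OTU must exceed in >= 1 sample
PRESENCE_THRESHOLD = {"ARISA": 0.010, "TRFLP": 0.0025}
#: peaks below this length (bp) are excluded from binning
MIN_FRAGMENT_LENGTH = 70.0


@dataclass
class Profile:
    """All called, size-calibrated peaks of one sample."""

    sample_id: str
    assay: str  # "ARISA" or "TRFLP"
    peaks: list[Peak]
    day_of_year: int | None = None
    horizon: str | None = None  # "I", "II", "III" or "SW"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ("ARISA", "TRFLP"):
            raise ValueError(f"unknown assay {self.assay!r}")

    @property
    def cumulative_height(self) -> float:
        return float(sum(p.height for p in self.peaks))


@dataclass
class OTUTable:
    """Binned heights (samples x OTUs) with per-bin representative lengths."""

    heights: pd.DataFrame  # index: sample ids, columns: bin ids
    lengths: pd.Series  # bin id -> representative fragment length (bp)
    metadata: pd.DataFrame  # per-sample assay / day / horizon

    def __post_init__(self) -> None:
        if list(self.heights.columns) != list(self.lengths.index):
            raise ValueError("heights columns and lengths index disagree")
        if not self.lengths.is_monotonic_increasing:
            raise ValueError("representative lengths must be increasing")


@dataclass
class PresenceMatrix:
    """Boolean samples x OTUs matrix after the relative-height filter."""

    presence: pd.DataFrame
    threshold_used: float

    def row_sets(self) -> dict[str, frozenset]:
        return {
            s: frozenset(self.presence.columns[self.presence.loc[s].to_numpy()])
            for s in self.presence.index
        }


def filter_profiles(
    profiles: Sequence[Profile],
    min_cumulative: dict[str, float] | None = None,
) -> tuple[list[Profile], list[dict]]:
    """Profile QC: retain profiles with cumulative height >= the assay's
    cut-off; return (retained, rejection log)."""
    if min_cumulative is None:
        min_cumulative = MIN_CUMULATIVE_HEIGHT
    if any(v <= 0 for v in min_cumulative.values()):
        raise ValueError("QC thresholds must be positive")
    if not profiles:
        warnings.warn("filter_profiles: no input profiles")
        return [], []
    retained, log = [], []
    for prof in profiles:
        threshold = min_cumulative[prof.assay]
        value = prof.cumulative_height
        if value >= threshold:
            retained.append(prof)
        else:
            log.append(
                {"sample_id": prof.sample_id, "assay": prof.assay,
                 "cumulative_height": value, "threshold": threshold}
            )
    return retained, log


def bin_cutoff_for_length(length_bp: float) -> float:
    """Size-dependent bin cut-off: 1 bp in [70, 700), 2 bp in [700, 1200),
    4 bp at >= 1200 bp."""
    if length_bp < MIN_FRAGMENT_LENGTH:
        raise ValueError(f"fragment length {length_bp} bp below 70 bp")
    if length_bp < 700:
        return 1.0
    if length_bp < 1200:
        return 2.0
    return 4.0


def bin_peaks(profiles: Sequence[Profile]) -> tuple[OTUTable, list[dict]]:
    """Bin the pooled peaks of all profiles into OTUs.

    Returns the OTU table and a log of excluded (< 70 bp) peaks. Bin ids are
    assigned in order of increasing representative length (height-weighted
    mean of member lengths).
    """
    records = []  # (length, height, sample_id)
    excluded = []
    for prof in profiles:
        for p in prof.peaks:
            if p.fragment_length is None:
                raise ValueError(
                    f"profile {prof.sample_id}: peak not size-calibrated"
                )
            if p.fragment_length < MIN_FRAGMENT_LENGTH:
                excluded.append(
                    {"sample_id": prof.sample_id,
                     "fragment_length": p.fragment_length,
                     "height": p.height, "reason": "below 70 bp"}
                )
                continue
            records.append((p.fragment_length, p.height, prof.sample_id))

    # descending height; ties toward the smaller length, then sample id
    records.sort(key=lambda r: (-r[1], r[0], r[2]))
    seeds: list[float] = []
    for length, _h, _s in records:
        cutoff = bin_cutoff_for_length(length)
        if not any(abs(length - s) < cutoff for s in seeds):
            seeds.append(length)
    seeds_arr = np.array(sorted(seeds))

    assignment: dict[tuple[str, int], float] = {}
    members: dict[int, list[tuple[float, float]]] = {}
    for length, height, sample in records:
        dists = np.abs(seeds_arr - length)
        k = int(np.argmin(dists))  # argmin tie -> smaller seed length
        assignment[(sample, k)] = assignment.get((sample, k), 0.0) + height
        members.setdefault(k, []).append((length, height))

    reps = {}
    for k, mem in members.items():
        lengths = np.array([m[0] for m in mem])
        hts = np.array([m[1] for m in mem])
        reps[k] = float(np.average(lengths, weights=hts))
    order = sorted(members, key=lambda k: reps[k])
    bin_ids = [f"OTU_{i+1:03d}" for i in range(len(order))]
    remap = {k: bin_ids[i] for i, k in enumerate(order)}

    sample_ids = [p.sample_id for p in profiles]
    heights = pd.DataFrame(0.0, index=sample_ids, columns=bin_ids)
    for (sample, k), h in assignment.items():
        heights.loc[sample, remap[k]] += h
    lengths = pd.Series({remap[k]: reps[k] for k in order})[bin_ids]
    metadata = pd.DataFrame(
        {
            "assay": [p.assay for p in profiles],
            "day_of_year": [p.day_of_year for p in profiles],
            "horizon": [p.horizon for p in profiles],
            "cumulative_height": [p.cumulative_height for p in profiles],
        },
        index=sample_ids,
    )
    return OTUTable(heights=heights, lengths=lengths, metadata=metadata), excluded


def presence_matrix(
    table: OTUTable,
    threshold: float,
    per_cell: bool = False,
) -> PresenceMatrix:
    """Relative-height presence/absence filter.

    An OTU column is retained iff its height exceeds ``threshold`` (as a
    fraction of the sample's cumulative height) in at least one sample; in
    retained columns a sample is scored present wherever its height is
    non-zero. ``per_cell=True`` switches to scoring each cell against the
    threshold instead.
    """
    if not 0 < threshold < 1:
        raise ValueError("presence threshold must be in (0, 1)")
    totals = table.heights.sum(axis=1)
    rel = table.heights.div(totals, axis=0)
    keep = (rel > threshold).any(axis=0)
    if per_cell:
        presence = rel.loc[:, keep] > threshold
    else:
        presence = table.heights.loc[:, keep] > 0
    return PresenceMatrix(presence=presence, threshold_used=threshold)


def signal_fraction(table: OTUTable, otu_subset: Iterable[str]) -> float:
    """Fraction of global cumulative binned height carried by a subset of
    OTUs (e.g. those present in every sample)."""
    subset = list(otu_subset)
    unknown = set(subset) - set(table.heights.columns)
    if unknown:
        raise ValueError(f"unknown OTUs: {sorted(unknown)}")
    total = float(table.heights.to_numpy().sum())
    if total == 0:
        raise ValueError("signal_fraction undefined for an empty table")
    if not subset:
        return 0.0
    return float(table.heights[subset].to_numpy().sum()) / total


def core_otus(matrix: PresenceMatrix) -> list[str]:
    """OTUs present in every sample of the presence matrix."""
    return list(matrix.presence.columns[matrix.presence.all(axis=0)])
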