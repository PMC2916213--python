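"""Electropherogram processing.

Turns a raw capillary-electrophoresis trace (fluorescence vs. scan index)
into a table of size-calibrated peaks:

1. low-pass Fourier filtering to suppress high-frequency detector noise,
2. baseline noise (RMS) estimation by iterative peak masking,
3. peak calling at a multiple of the baseline RMS (default 5x),
4. recovery of detector-saturated peak heights by fitting a Gaussian to the
   unclipped flank points,
5. fragment sizing against an internal ladder (monotone piecewise-linear
   interpolation) with a constant dye-offset correction for the migration
   difference between the sample and ladder fluorophores.

Heights are in relative fluorescence units (RFU), positions in scan indices
until calibration converts them to base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "Trace",
    "Peak",
    "LadderCalibration",
    "lowpass_filter",
    "estimate_noise_rms",
    "call_peaks",
    "recover_saturated_height",
    "calibrate_sizes",
    "fit_ladder",
    "read_trace_tsv",
    "write_trace_tsv",
]

#: fraction of the ceiling above which a point counts as clipped
SATURATION_TOL = 0.005
#: minimum run of clipped points for a peak to be flagged saturated
SATURATION_MIN_RUN = 3


@dataclass
class Trace:
    """A single-channel electropherogram at uniform scan spacing."""

    sample_id: str
    channel: str  # "sample" or "ladder"
    signal: np.ndarray
    saturation_ceiling: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise ValueError("Trace.signal must be a non-empty 1-D array")
        if self.saturation_ceiling is not None:
            if np.any(self.signal > self.saturation_ceiling + 1e-9):
                raise ValueError(
                    "Trace.signal exceeds the stated saturation ceiling"
                )

    @property
    def n_scans(self) -> int:
        return self.signal.size


@dataclass
class Peak:
    """One called peak; positions in scans until calibrated to bp."""

    apex_scan: float
    height: float
    area: float
    saturated: bool = False
    fragment_length: float | None = None
    extrapolated: bool = False
    note: str | None = None

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("Peak.height must be positive")


@dataclass(frozen=True)
class LadderCalibration:
    """Monotone scan -> bp mapping anchored at internal size-standard peaks."""

    anchor_scans: tuple[float, ...]
    anchor_lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.anchor_scans) != len(self.anchor_lengths):
            raise ValueError("anchor coordinate lists differ in length")
        if len(self.anchor_scans) < 2:
            raise ValueError("calibration requires at least 2 ladder anchors")
        if np.any(np.diff(self.anchor_scans) <= 0) or np.any(
            np.diff(self.anchor_lengths) <= 0
        ):
            raise ValueError("ladder anchors must be strictly increasing")

    def scan_to_bp(self, scans: np.ndarray | float) -> np.ndarray:
        return np.interp(scans, self.anchor_scans, self.anchor_lengths)

    def in_range(self, scans: np.ndarray | float) -> np.ndarray:
        s = np.asarray(scans, dtype=float)
        return (s >= self.anchor_scans[0]) & (s <= self.anchor_scans[-1])


def lowpass_filter(trace: Trace, cutoff: float = 0.1) -> Trace:
    """Remove frequency components above ``cutoff`` (fraction of Nyquist).

    Hard cutoff via forward/inverse real FFT; the DC component is always
    kept, so a constant trace passes unchanged and the operation is
    idempotent at a fixed cutoff.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    spectrum = np.fft.rfft(trace.signal)
    freqs = np.fft.rfftfreq(trace.n_scans)  # cycles per scan, Nyquist = 0.5
    spectrum[freqs > cutoff * 0.5] = 0.0
    filtered = np.fft.irfft(spectrum, n=trace.n_scans)
    if trace.saturation_ceiling is not None:
        # ringing at clipped plateaus can overshoot the ceiling slightly
        filtered = np.minimum(filtered, trace.saturation_ceiling)
    return replace(trace, signal=filtered, metadata=dict(trace.metadata))


def estimate_noise_rms(
    trace: Trace, mask_multiple: float = 3.0, max_iter: int = 50
) -> float:
    """Baseline RMS by iterative peak masking.

    Starting from the whole trace, points with |signal| above
    ``mask_multiple`` times the current RMS are excluded and the RMS
    re-estimated until the mask stabilises. Robust to a small fraction of
    scans being occupied by peaks.
    """
    x = trace.signal
    if x.size < 100:
        raise ValueError("noise estimation requires at least 100 scans")
    if np.all(x == 0):
        warnings.warn(f"{trace.sample_id}: all-zero trace, noise RMS = 0")
        return 0.0
    mask = np.ones(x.size, dtype=bool)
    for _ in range(max_iter):
        rms = float(np.sqrt(np.mean(x[mask] ** 2)))
        if rms == 0.0:
            break
        new_mask = np.abs(x) <= mask_multiple * rms
        if not new_mask.any():
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return float(np.sqrt(np.mean(x[mask] ** 2)))


def _plateau_runs(signal: np.ndarray, ceiling: float) -> np.ndarray:
    """Boolean mask of points considered clipped at the ceiling."""
    return signal >= ceiling * (1.0 - SATURATION_TOL)


def call_peaks(
    trace: Trace,
    noise_rms: float,
    threshold_multiple: float = 5.0,
    min_separation_scans: int = 10,
) -> list[Peak]:
    """Call local maxima with height strictly above threshold_multiple x RMS.

    No two apexes are returned within ``min_separation_scans`` (one nominal
    peak width). Flat-topped peaks at the saturation ceiling with at least
    :data:`SATURATION_MIN_RUN` clipped points are flagged ``saturated`` and
    their apex is placed at the plateau midpoint.
    """
    if noise_rms < 0:
        raise ValueError("noise_rms must be non-negative")
    threshold = threshold_multiple * noise_rms
    x = trace.signal
    idx, props = find_peaks(
        x, distance=max(1, min_separation_scans), plateau_size=(1, None)
    )
    peaks: list[Peak] = []
    for i, apex in enumerate(idx):
        left, right = props["left_edges"][i], props["right_edges"][i]
        apex_scan = 0.5 * (left + right)
        height = float(x[apex])
        if not height > threshold:  # strict ">"
            continue
        saturated = False
        if trace.saturation_ceiling is not None:
            clipped = _plateau_runs(x, trace.saturation_ceiling)
            if clipped[apex]:
                run_left = apex
                while run_left > 0 and clipped[run_left - 1]:
                    run_left -= 1
                run_right = apex
                while run_right < x.size - 1 and clipped[run_right + 1]:
                    run_right += 1
                if run_right - run_left + 1 >= SATURATION_MIN_RUN:
                    saturated = True
                    apex_scan = 0.5 * (run_left + run_right)
        lo = max(0, int(round(apex_scan)) - 3 * min_separation_scans)
        hi = min(x.size, int(round(apex_scan)) + 3 * min_separation_scans + 1)
        area = float(np.trapezoid(np.clip(x[lo:hi], 0, None)))
        peaks.append(
            Peak(apex_scan=apex_scan, height=height, area=area, saturated=saturated)
        )
    return peaks


def _gaussian(x: np.ndarray, amp: float, centre: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - centre) / sigma) ** 2)


def recover_saturated_height(
    trace: Trace, peak: Peak, window_scans: int = 60
) -> Peak:
    """Estimate a clipped peak's true height from its unclipped flanks.

    Fits a Gaussian (least squares) to the non-saturated points within
    ``window_scans`` of the apex; on success the peak's height becomes the
    fitted amplitude and its apex the fitted centre. Unsaturated peaks are
    returned unchanged; a failed or implausible fit (amplitude below the
    plateau) returns the peak unmodified with a diagnostic note.
    """
    if not peak.saturated or trace.saturation_ceiling is None:
        return peak
    x = trace.signal
    ceiling = trace.saturation_ceiling
    lo = max(0, int(round(peak.apex_scan)) - window_scans)
    hi = min(x.size, int(round(peak.apex_scan)) + window_scans + 1)
    scans = np.arange(lo, hi, dtype=float)
    vals = x[lo:hi]
    flank = ~_plateau_runs(vals, ceiling) & (vals > 0)
    if flank.sum() < 5:
        return replace(peak, note="saturation fit skipped: <5 flank points")
    plateau = vals[~flank]
    plateau_width = max(float((~flank).sum()), 1.0)
    p0 = (float(plateau.max() if plateau.size else ceiling), peak.apex_scan,
          plateau_width)
    try:
        popt, _ = curve_fit(
            _gaussian, scans[flank], vals[flank], p0=p0, maxfev=5000
        )
    except (RuntimeError, ValueError):
        return replace(peak, note="saturation fit failed to converge")
    amp, centre, _sigma = float(popt[0]), float(popt[1]), float(popt[2])
    if amp < peak.height:
        return replace(peak, note="saturation fit below plateau, kept observed")
    return replace(peak, height=amp, apex_scan=centre)


def calibrate_sizes(
    peaks: Sequence[Peak],
    ladder: LadderCalibration,
    dye_offset_bp: float = 0.0,
    drop_extrapolated: bool = True,
) -> list[Peak]:
    """Convert apex scans to fragment lengths in bp.

    Monotone piecewise-linear interpolation between ladder anchors, plus a
    constant dye-offset correction (e.g. -7 bp for the HEX-vs-ROX migration
    difference). Peaks outside the anchored range are flagged and, by
    default, excluded.
    """
    out: list[Peak] = []
    for p in peaks:
        inside = bool(ladder.in_range(p.apex_scan))
        if not inside and drop_extrapolated:
            continue
        bp = float(ladder.scan_to_bp(p.apex_scan)) + dye_offset_bp
        out.append(replace(p, fragment_length=bp, extrapolated=not inside))
    return out


def fit_ladder(
    ladder_trace: Trace,
    known_lengths: Sequence[float],
    threshold_multiple: float = 5.0,
    min_separation_scans: int = 10,
) -> LadderCalibration:
    """Build a calibration by pairing called ladder peaks with known sizes.

    The ``len(known_lengths)`` tallest peaks in the ladder channel, ordered
    by scan, are paired 1:1 with the known lengths.
    """
    noise = estimate_noise_rms(ladder_trace)
    peaks = call_peaks(
        ladder_trace, noise, threshold_multiple, min_separation_scans
    )
    if len(peaks) < len(known_lengths):
        raise ValueError(
            f"ladder channel for {ladder_trace.sample_id}: found "
            f"{len(peaks)} peaks, expected >= {len(known_lengths)}"
        )
    tallest = sorted(peaks, key=lambda p: -p.height)[: len(known_lengths)]
    anchors = sorted(p.apex_scan for p in tallest)
    return LadderCalibration(tuple(anchors), tuple(float(x) for x in known_lengths))


def write_trace_tsv(trace: Trace, path) -> None:
    """Write a trace as two-column TSV (scan_index, rfu)."""
    with open(path, "w") as fh:
        fh.write("scan_index\trfu\n")
        for i, v in enumerate(trace.signal):
            fh.write(f"{i}\t{v:.6g}\n")


def read_trace_tsv(
    path, sample_id: str, channel: str, saturation_ceiling: float | None = None
) -> Trace:
    """Read a two-column (scan_index, rfu) TSV written by write_trace_tsv."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim == 1:
        data = data[None, :]
    order = np.argsort(data[:, 0])
    return Trace(
        sample_id=sample_id,
        channel=channel,
        signal=data[order, 1],
        saturation_ceiling=saturation_ceiling,
    )
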