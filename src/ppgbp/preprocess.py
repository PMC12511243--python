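"""Signal conditioning: windowing, band-pass filtering, normalization and
derivative channels.

A raw recording is cut into overlapping windows (default 30 s with 25 s
overlap), each window is band-passed with a zero-phase 4th-order Chebyshev
type II filter (0.4-8 Hz stopband edges, 30 dB stopband attenuation),
min-max normalized to [0, 1], and differentiated twice — with
Savitzky-Golay smoothing after each difference — to obtain the velocity
(VPG) and acceleration (APG) plethysmograms.  The first difference is not
scaled by the sampling rate, so VPG/APG values are in per-sample units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .population import PPGRecording

__all__ = [
    "SegmentBundle",
    "segment",
    "bandpass_cheby2",
    "normalize",
    "derivatives",
    "condition",
    "n_windows",
]

#: Chebyshev II stopband attenuation (dB); the band edges are interpreted
#: as stopband edges.
CHEBY2_STOPBAND_DB = 30.0


@dataclass(frozen=True)
class SegmentBundle:
    """One conditioned window with its three aligned channels."""

    subject_id: str
    segment_index: int
    ppg: np.ndarray  # normalized, in [0, 1]
    vpg: np.ndarray  # len(ppg) - 1
    apg: np.ndarray  # len(ppg) - 2
    fs: float
    window_s: float
    overlap_s: float

    def __post_init__(self) -> None:
        n = round(self.window_s * self.fs)
        if len(self.ppg) != n:
            raise ValueError(f"ppg length {len(self.ppg)} != window samples {n}")
        if len(self.vpg) != n - 1 or len(self.apg) != n - 2:
            raise ValueError("vpg/apg lengths must be n-1 and n-2")
        if self.ppg.min() < -1e-12 or self.ppg.max() > 1 + 1e-12:
            raise ValueError("ppg must be normalized to [0, 1]")


def n_windows(duration: float, window_s: float, overlap_s: float) -> int:
    """Number of full windows: ``floor((duration - window)/stride) + 1``."""
    stride = window_s - overlap_s
    if stride <= 0:
        raise ValueError("window_s must exceed overlap_s")
    if duration < window_s:
        return 0
    return int(np.floor((duration - window_s) / stride + 1e-9)) + 1


def segment(
    recording: PPGRecording, window_s: float = 30.0, overlap_s: float = 25.0
) -> list[np.ndarray]:
    """Cut a recording into overlapping raw windows.

    Windows start every ``window_s - overlap_s`` seconds; only full
    windows are emitted.  A recording shorter than one window is an error.
    """
    if overlap_s < 0 or window_s <= overlap_s:
        raise ValueError("require window_s > overlap_s >= 0")
    if recording.duration < window_s:
        raise ValueError(
            f"recording {recording.subject_id} is {recording.duration} s, "
            f"shorter than one {window_s} s window — no segments can be produced"
        )
    fs = recording.fs
    win = round(window_s * fs)
    stride = round((window_s - overlap_s) * fs)
    count = n_windows(recording.duration, window_s, overlap_s)
    return [
        np.asarray(recording.samples[i * stride : i * stride + win], dtype=float)
        for i in range(count)
    ]


def bandpass_cheby2(
    x: np.ndarray,
    fs: float,
    low: float = 0.4,
    high: float = 8.0,
    order: int = 4,
    stopband_db: float = CHEBY2_STOPBAND_DB,
) -> np.ndarray:
    """Zero-phase Chebyshev type II band-pass.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    output has no group delay; the effective magnitude response is the
    squared design response.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={fs}")
    sos = sps.cheby2(order, stopband_db, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def normalize(x: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant input maps to all 0.5."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def derivatives(
    ppg: np.ndarray, fs: float, sg_window: int = 9, sg_order: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """First/second difference channels with Savitzky-Golay smoothing.

    VPG = smoothed first difference of the PPG; APG = smoothed first
    difference of the VPG.  Lengths are n-1 and n-2.  Differences are
    plain adjacent-sample differences (per-sample units, not scaled by
    ``fs``); ``fs`` is accepted for interface symmetry.
    """
    ppg = np.asarray(ppg, dtype=float)
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and exceed sg_order")
    if len(ppg) <= sg_window + 2:
        raise ValueError(
            f"input of {len(ppg)} samples too short for sg_window={sg_window}"
        )
    vpg = sps.savgol_filter(np.diff(ppg), sg_window, sg_order)
    apg = sps.savgol_filter(np.diff(vpg), sg_window, sg_order)
    return vpg, apg


def condition(
    recording: PPGRecording,
    window_s: float = 30.0,
    overlap_s: float = 25.0,
    low: float = 0.4,
    high: float = 8.0,
    order: int = 4,
    sg_window: int = 9,
    sg_order: int = 3,
) -> list[SegmentBundle]:
    """Full conditioning chain: segment -> band-pass -> normalize -> derivatives."""
    bundles = []
    for idx, raw in enumerate(segment(recording, window_s, overlap_s)):
        filtered = bandpass_cheby2(raw, recording.fs, low, high, order)
        ppg = normalize(filtered)
        vpg, apg = derivatives(ppg, recording.fs, sg_window, sg_order)
        bundles.append(
            SegmentBundle(
                subject_id=recording.subject_id,
                segment_index=idx,
                ppg=ppg,
                vpg=vpg,
                apg=apg,
                fs=recording.fs,
                window_s=window_s,
                overlap_s=overlap_s,
            )
        )
    return bundles
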