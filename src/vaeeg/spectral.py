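"""Segmentation and the channel-weighted frequency-power statistics.

Each 5-minute event is cut into non-overlapping 2-s windows.  For every
window and channel a tapered periodogram

    p[n, m, f] = | (1/Q) * sum_k w(k) x_n^m(k) exp(-i 2 pi f k T) |^2

is evaluated on the DFT frequency grid restricted to the 1-50 Hz
analysis range (note the plain 1/Q normalization — this is the
statistic's own convention, not a spectral-density convention).  The
scalar per-segment score is the frequency-weighted power averaged over
channels,

    S_n = (1/M) * sum_m sum_f f * p[n, m, f],

and the per-channel topography score averages over segments instead,

    S_m = (1/N) * sum_n sum_f f * p[n, m, f].

Restricting the sum over f to one band gives band-wise scores; the five
canonical bands partition the 1-50 Hz range, so band scores add up
exactly to the full-range score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .core import BandDefinition, Recording

__all__ = [
    "SegmentSet",
    "SpectraGrid",
    "SegmentScores",
    "ChannelScores",
    "segment_event",
    "periodogram",
    "segment_scores",
    "channel_scores",
    "event_scores",
]


@dataclass
class SegmentSet:
    """Non-overlapping windows of one event: array (N, channels, Q)."""

    event: str
    segments: np.ndarray
    window_seconds: float
    rate: float
    channel_labels: list[str]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def samples_per_segment(self) -> int:
        return self.segments.shape[2]


@dataclass
class SpectraGrid:
    """Per-segment, per-channel power on a discrete frequency grid."""

    p: np.ndarray                 # (N, channels, F)
    freqs: np.ndarray             # Hz
    window_fn: str
    T: float                      # sampling period, seconds
    channel_labels: list[str]

    @property
    def n_segments(self) -> int:
        return self.p.shape[0]

    @property
    def n_channels(self) -> int:
        return self.p.shape[1]


@dataclass
class SegmentScores:
    """Weighted spectral content per segment (Hz * uV^2)."""

    S: np.ndarray                 # (N,)
    band: BandDefinition


@dataclass
class ChannelScores:
    """Weighted spectral content per channel, with a decibel view."""

    S_m: dict[str, float]
    band: BandDefinition

    @property
    def S_m_dB(self) -> dict[str, float]:
        return {ch: float(10.0 * np.log10(v)) if v > 0 else float("-inf")
                for ch, v in self.S_m.items()}


def segment_event(recording: Recording, event: str,
                  window_seconds: float = 2.0) -> SegmentSet:
    """Cut one annotated event into non-overlapping windows.

    The trailing remainder shorter than one window is dropped; an event
    shorter than one window is an error.
    """
    q = window_seconds * recording.rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"window_seconds * rate = {q} must be an integer sample count")
    q = int(round(q))
    data = recording.event_data(event)      # raises KeyError if absent
    n = data.shape[1] // q
    if n == 0:
        raise ValueError(
            f"event {event!r} ({data.shape[1] / recording.rate:g} s) is "
            f"shorter than the {window_seconds:g}-s window")
    segments = data[:, : n * q].reshape(recording.n_channels, n, q)
    segments = np.ascontiguousarray(segments.transpose(1, 0, 2))
    return SegmentSet(event, segments, window_seconds, recording.rate,
                      list(recording.channel_labels))


def periodogram(segset: SegmentSet, window_fn: str = "hamming",
                f_lo: float = 1.0, f_hi: float = 50.0) -> SpectraGrid:
    """Tapered periodogram of every segment and channel.

    The frequency grid is the segment's DFT grid (0.5 Hz spacing for
    2-s windows) restricted to ``[f_lo, f_hi]`` inclusive.
    """
    if segset.n_segments == 0:
        raise ValueError("empty segment set")
    rate = segset.rate
    if f_hi > rate / 2.0 + 1e-9:
        raise ValueError(f"f_hi={f_hi} exceeds Nyquist ({rate / 2:g} Hz)")
    q = segset.samples_per_segment
    if window_fn in ("rectangular", "boxcar", None):
        w = np.ones(q)
        window_fn = "boxcar"
    else:
        w = get_window(window_fn, q)
    spectrum = np.fft.rfft(segset.segments * w, axis=2) / q
    p = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(q, d=1.0 / rate)
    mask = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    return SpectraGrid(np.ascontiguousarray(p[:, :, mask]), freqs[mask],
                       window_fn, 1.0 / rate, list(segset.channel_labels))


def _band_mask(grid: SpectraGrid, band: BandDefinition) -> np.ndarray:
    mask = band.contains(grid.freqs)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}] is disjoint "
            "from the spectral grid")
    return mask


def segment_scores(grid: SpectraGrid, band: BandDefinition) -> SegmentScores:
    """S_n: frequency-weighted band power averaged over channels."""
    mask = _band_mask(grid, band)
    weighted = grid.p[:, :, mask] * grid.freqs[mask]
    s = weighted.sum(axis=2).mean(axis=1)
    return SegmentScores(s, band)


def channel_scores(grid: SpectraGrid, band: BandDefinition) -> ChannelScores:
    """S_m: frequency-weighted band power averaged over segments."""
    if grid.n_segments == 0:
        raise ValueError("no segments in grid")
    mask = _band_mask(grid, band)
    weighted = grid.p[:, :, mask] * grid.freqs[mask]
    s = weighted.sum(axis=2).mean(axis=0)
    return ChannelScores(
        {ch: float(v) for ch, v in zip(grid.channel_labels, s)}, band)


def event_scores(recording: Recording, event: str,
                 band: BandDefinition, window_seconds: float = 2.0,
                 window_fn: str = "hamming") -> SegmentScores:
    """Convenience: segment an event and score it in one call."""
    segset = segment_event(recording, event, window_seconds)
    grid = periodogram(segset)
    return segment_scores(grid, band)
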