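"""Synthetic EEG session generator.

The study's raw recordings are not deposited, so every signal-level
stage is exercised on simulated sessions with known ground truth.  Each
channel is a sum of one band-limited sinusoid per frequency band (random
frequency inside the band, random phase, both redrawn every
analysis-window-length block so downstream rank tests see independent
segment scores) plus 1/f-shaped Gaussian background noise.  Eye blinks
are injected separately as frontally-weighted raised-cosine transients
at Poisson onsets, with the ground-truth onset times returned for
artifact-removal tests.

The default band-amplitude profiles make every treatment event
statistically identical (a null configuration); effect configurations
are built by scaling one band's amplitude in the MA events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import (
    BANDS,
    FRONTAL_CHANNELS,
    MA_EVENTS,
    MONTAGE_16,
    EventSchedule,
    Recording,
)

__all__ = [
    "SynthConfig",
    "default_band_powers",
    "contrast_band_powers",
    "generate_session",
    "inject_blinks",
]

#: Oscillatory amplitudes (microvolts) of a generic resting-state-like
#: treatment profile: strongest in delta/theta, a clear alpha rhythm,
#: weaker beta and little gamma.
_TREATMENT_PROFILE: dict[str, float] = {
    "delta": 20.0, "theta": 12.0, "alpha": 10.0, "beta": 5.0, "gamma": 2.0,
}

#: Rest/fixation blocks: slightly higher alpha (relaxed, reduced input).
_REST_PROFILE: dict[str, float] = {
    "delta": 18.0, "theta": 10.0, "alpha": 14.0, "beta": 4.0, "gamma": 2.0,
}

#: Blink projection weights over the montage: ocular artifacts dominate
#: the prefrontal electrodes and fade toward posterior sites.
DEFAULT_BLINK_WEIGHTS: dict[str, float] = {
    label: (1.0 if label in ("Fp1", "Fp2")
            else 0.5 if label in FRONTAL_CHANNELS
            else 0.05)
    for label in MONTAGE_16
}


def default_band_powers() -> dict[str, dict[str, float]]:
    """Null profiles: all six treatment events share one amplitude map."""
    profiles = {name: dict(_TREATMENT_PROFILE)
                for name in ("MA1", "MA2", "VA1", "VA2", "VA3", "VA4")}
    profiles["rest"] = dict(_REST_PROFILE)
    profiles["fixation"] = dict(_REST_PROFILE)
    return profiles


def contrast_band_powers(band: str = "alpha",
                         factor: float = 3.0) -> dict[str, dict[str, float]]:
    """Profiles with one band's amplitude scaled by ``factor`` in the MA
    events only, leaving VA events at the null profile."""
    profiles = default_band_powers()
    for name in MA_EVENTS:
        profiles[name][band] = profiles[name][band] * factor
    return profiles


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic session generator.

    ``band_powers`` maps event name -> band name -> sinusoid amplitude
    in microvolts.  ``noise_exponent`` is the 1/f spectral slope of the
    Gaussian background and ``noise_scale`` its RMS amplitude.
    ``block_seconds`` is the span over which each sinusoid's frequency
    and phase stay fixed before being redrawn; it defaults to the 2-s
    analysis window so consecutive segment scores are independent draws.
    """

    rate: float = 125.0
    n_channels: int = 16
    band_powers: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_band_powers)
    noise_exponent: float = 1.0
    noise_scale: float = 5.0
    blink_rate: float = 12.0            # blinks per minute
    blink_amplitude: float = 100.0      # microvolts
    blink_duration: float = 0.3         # seconds
    blink_channel_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLINK_WEIGHTS))
    block_seconds: float = 2.0
    #: interior margin (Hz) kept between a drawn tone and its band edges,
    #: sized to the Hamming main-lobe half-width of a 2-s window so the
    #: windowed tone's energy stays inside the band
    band_edge_margin: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not 1 <= self.n_channels <= len(MONTAGE_16):
            raise ValueError(
                f"n_channels must be in [1, {len(MONTAGE_16)}]")
        if self.noise_scale < 0 or self.blink_amplitude < 0:
            raise ValueError("amplitudes and scales must be non-negative")
        for event, profile in self.band_powers.items():
            for band, amp in profile.items():
                if band not in BANDS or band == "raw":
                    raise ValueError(
                        f"unknown band {band!r} in profile for {event!r}")
                if amp < 0:
                    raise ValueError(
                        f"negative amplitude for {event!r}/{band!r}")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return MONTAGE_16[: self.n_channels]


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float,
                      scale: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent and RMS ``scale``."""
    if scale == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n)
    rms = shaped.std()
    return shaped * (scale / rms) if rms > 0 else shaped


def _band_interval(band_name: str, margin: float) -> tuple[float, float]:
    band = BANDS[band_name]
    lo, hi = band.f_lo + margin, band.f_hi - margin
    if lo >= hi:
        mid = 0.5 * (band.f_lo + band.f_hi)
        lo, hi = mid - 1e-3, mid + 1e-3
    return lo, hi


def _oscillatory_block(rng: np.random.Generator, t: np.ndarray,
                       profile: Mapping[str, float],
                       gains: Mapping[str, np.ndarray],
                       margin: float) -> np.ndarray:
    """One random-frequency, random-phase sinusoid per band, projected
    to the channels through that band's fixed spatial gain vector.

    Returns a (channels, len(t)) block.  Sharing each band's oscillation
    across channels (as volume conduction does in real EEG) keeps the
    latent source count below the channel count, so ICA can actually
    separate an added artifact source.
    """
    n_channels = len(next(iter(gains.values())))
    out = np.zeros((n_channels, t.size))
    for band_name, amplitude in sorted(profile.items()):
        lo, hi = _band_interval(band_name, margin)
        freq = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if amplitude > 0:
            wave = amplitude * np.sin(2.0 * np.pi * freq * t + phase)
            out += gains[band_name][:, None] * wave
    return out


def generate_session(config: SynthConfig,
                     schedule: EventSchedule) -> Recording:
    """Generate one day's recording spanning ``schedule``.

    Every event in the schedule must have an amplitude profile in
    ``config.band_powers`` (``fixation`` falls back to the ``rest``
    profile).  Samples outside any scheduled event are pure background
    noise.  The result is deterministic in ``config.seed``.
    """
    days = {e.day for e in schedule.events}
    if len(days) != 1:
        raise ValueError("generate_session expects a single-day schedule")
    day = days.pop()
    total_seconds = schedule.day_duration(day)
    n_samples = int(round(total_seconds * config.rate))
    if n_samples <= 0:
        raise ValueError("schedule spans no samples")

    for event in schedule.day_events(day):
        if event.name not in config.band_powers and event.name != "fixation":
            raise ValueError(f"no band-power profile for event {event.name!r}")

    rng = np.random.default_rng(config.seed)
    block = max(1, int(round(config.block_seconds * config.rate)))
    data = np.zeros((config.n_channels, n_samples))

    # fixed spatial gain vector per band for the whole session
    gains = {
        band: rng.uniform(0.6, 1.4, size=config.n_channels)
        for band in sorted(BANDS) if band != "raw"
    }

    for ch in range(config.n_channels):
        data[ch] = _one_over_f_noise(
            rng, n_samples, config.noise_exponent, config.noise_scale)

    for event in schedule.day_events(day):
        profile = config.band_powers.get(event.name)
        if profile is None and event.name == "fixation":
            profile = config.band_powers.get("rest", {})
        lo = int(round(event.onset * config.rate))
        hi = min(int(round((event.onset + event.duration) * config.rate)),
                 n_samples)
        for start in range(lo, hi, block):
            stop = min(start + block, hi)
            t = np.arange(stop - start) / config.rate
            data[:, start:stop] += _oscillatory_block(
                rng, t, profile, gains, config.band_edge_margin)

    return Recording(data, config.rate, config.channel_labels,
                     schedule.annotations(day))


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine pulse over ``n`` samples."""
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (k + 1) / (n + 1)))


def inject_blinks(recording: Recording, config: SynthConfig
                  ) -> tuple[Recording, list[float]]:
    """Add Poisson-process eye-blink transients; return ground truth.

    Blinks are raised-cosine pulses of ``config.blink_duration`` seconds
    and peak ``config.blink_amplitude`` microvolts, scaled per channel
    by ``config.blink_channel_weights`` (channels without a weight are
    untouched).  Returns the modified copy and the sorted onset times.
    """
    if config.blink_rate < 0:
        raise ValueError("blink_rate must be non-negative")
    out = recording.copy()
    if config.blink_rate == 0 or config.blink_amplitude == 0:
        return out, []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB11]))
    duration = recording.duration
    n_blinks = rng.poisson(config.blink_rate / 60.0 * duration)
    width = max(2, int(round(config.blink_duration * recording.rate)))
    onsets = np.sort(rng.uniform(0.0, max(duration - width / recording.rate,
                                          0.0), size=n_blinks))
    pulse = _raised_cosine(width) * config.blink_amplitude
    weights = np.array([
        config.blink_channel_weights.get(label, 0.0)
        for label in recording.channel_labels
    ])
    for onset in onsets:
        start = int(round(onset * recording.rate))
        stop = min(start + width, recording.n_samples)
        out.data[:, start:stop] += weights[:, None] * pulse[: stop - start]
    return out, [float(v) for v in onsets]
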