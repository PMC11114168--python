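"""Domain types and I/O shared by every stage of the pipeline.

The pipeline analyses 16-channel scalp EEG recorded during two kinds of
acupuncture stimulation at the Zusanli (ST36) acupoint: manual needling
(events ``MA1``, ``MA2``) and a VR-presented simulation of needling
(events ``VA1``-``VA4``), spread over two recording days.  This module
defines the recording container, the session event schedule, frequency
band definitions, subject metadata, and EDF/CSV round-trip I/O.
"""

from __future__ import annotations

import csv
import io
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MONTAGE_16",
    "FRONTAL_CHANNELS",
    "TREATMENT_EVENTS",
    "MA_EVENTS",
    "VA_EVENTS",
    "BANDS",
    "BandDefinition",
    "Recording",
    "Event",
    "EventSchedule",
    "SubjectMeta",
    "default_schedule",
    "read_recording",
    "write_recording",
]

#: Electrode labels of the 16-channel 10-20 montage, in cap order:
#: prefrontal, frontal, temporal, central, parietal, occipital.
MONTAGE_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8",
    "T3", "T4", "T5", "T6", "C3", "C4",
    "P3", "P4", "O1", "O2",
)

#: Channels over the prefrontal/frontal scalp, where ocular artifacts project.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "F7", "F8")

MA_EVENTS: tuple[str, ...] = ("MA1", "MA2")
VA_EVENTS: tuple[str, ...] = ("VA1", "VA2", "VA3", "VA4")
TREATMENT_EVENTS: tuple[str, ...] = MA_EVENTS + VA_EVENTS

#: Default sampling rate in Hz (16-channel OpenBCI daisy-chain rate).
DEFAULT_RATE: float = 125.0

#: Default duration of one treatment event, seconds.
TREATMENT_SECONDS: float = 300.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open ``[f_lo, f_hi)`` in Hz.

    The upper edge is treated as inclusive for bands that end at the
    50 Hz analysis ceiling (``raw`` and ``gamma``), so that the five
    canonical bands exactly partition the 1-50 Hz range.
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi <= 50.0):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi <= 50, "
                f"got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def closed_top(self) -> bool:
        return self.f_hi >= 50.0

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequencies inside the band."""
        freqs = np.asarray(freqs, dtype=float)
        if self.closed_top:
            return (freqs >= self.f_lo) & (freqs <= self.f_hi)
        return (freqs >= self.f_lo) & (freqs < self.f_hi)


#: Canonical EEG bands; ``raw`` is the full analysis range.
BANDS: dict[str, BandDefinition] = {
    "raw": BandDefinition("raw", 1.0, 50.0),
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 50.0),
}


@dataclass
class Recording:
    """A multi-channel EEG recording.

    Parameters
    ----------
    data
        Channels x samples array in microvolts.
    rate
        Sampling frequency in Hz.
    channel_labels
        Ordered 10-20 electrode names, one per row of ``data``.
    annotations
        ``(label, onset_seconds, duration_seconds)`` triples; onsets are
        seconds from recording start, intervals half-open.
    """

    data: np.ndarray
    rate: float
    channel_labels: Sequence[str]
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        total = self.duration
        for label, onset, dur in self.annotations:
            if onset < 0 or onset + dur > total + 1e-9:
                raise ValueError(
                    f"annotation {label!r} [{onset}, {onset + dur}) outside [0, {total})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def event_span(self, name: str) -> tuple[int, int]:
        """Half-open sample span of the first annotation named ``name``."""
        for label, onset, dur in self.annotations:
            if label == name:
                lo = int(round(onset * self.rate))
                hi = int(round((onset + dur) * self.rate))
                return lo, min(hi, self.n_samples)
        raise KeyError(f"event {name!r} not annotated in recording")

    def event_data(self, name: str) -> np.ndarray:
        lo, hi = self.event_span(name)
        return self.data[:, lo:hi]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.rate, list(self.channel_labels),
            list(self.annotations),
        )


@dataclass(frozen=True)
class Event:
    name: str
    day: int
    onset: float
    duration: float


@dataclass
class EventSchedule:
    """Ordered, non-overlapping session events for one or two days.

    Each treatment event (``MA1``, ``MA2``, ``VA1``-``VA4``) may appear
    at most once across the schedule; ``fixation`` and ``rest`` blocks
    may repeat.  Onsets are seconds from the start of that day's
    recording.
    """

    events: list[Event]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ev in self.events:
            if ev.day not in (1, 2):
                raise ValueError(f"invalid day {ev.day} for event {ev.name!r}")
            if ev.onset < 0 or ev.duration <= 0:
                raise ValueError(f"bad interval for event {ev.name!r}")
            if ev.name in TREATMENT_EVENTS:
                if ev.name in seen:
                    raise ValueError(f"treatment event {ev.name!r} repeated")
                seen.add(ev.name)
        for day in (1, 2):
            evs = [e for e in self.events if e.day == day]
            for a, b in zip(evs, evs[1:]):
                if b.onset < a.onset:
                    raise ValueError(f"day {day} events not ordered by onset")
                if b.onset < a.onset + a.duration - 1e-9:
                    raise ValueError(
                        f"day {day} events {a.name!r} and {b.name!r} overlap"
                    )

    def day_events(self, day: int) -> list[Event]:
        return [e for e in self.events if e.day == day]

    @property
    def treatment_events(self) -> list[Event]:
        return [e for e in self.events if e.name in TREATMENT_EVENTS]

    def day_duration(self, day: int) -> float:
        evs = self.day_events(day)
        return max((e.onset + e.duration for e in evs), default=0.0)

    def annotations(self, day: int) -> list[tuple[str, float, float]]:
        return [(e.name, e.onset, e.duration) for e in self.day_events(day)]


def default_schedule(day: int) -> EventSchedule:
    """The standard session layout for one recording day.

    Day 1: a 6-minute fixation block (1 min closed-eye + 5 min open-eye
    rest), then MA1/rest/MA2/rest, then (after an unrecorded
    intermission) VA1/rest/VA2/rest.  Day 2: fixation, then
    VA3/rest/VA4/rest.  Treatment events and rests are 300 s each; the
    two days together give 4,320 s (72 min) of recorded EEG.
    """
    if day not in (1, 2):
        raise ValueError(f"day must be 1 or 2, got {day!r}")
    names = (
        ["fixation", "MA1", "rest", "MA2", "rest",
         "VA1", "rest", "VA2", "rest"]
        if day == 1
        else ["fixation", "VA3", "rest", "VA4", "rest"]
    )
    events: list[Event] = []
    t = 0.0
    for name in names:
        dur = 360.0 if name == "fixation" else TREATMENT_SECONDS
        events.append(Event(name, day, t, dur))
        t += dur
    return EventSchedule(events)


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject demographics and screening measurements."""

    id: str
    sex: str
    age: int
    heart_rate: float
    body_temp: float
    vr_history: bool
    acu_history: bool

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


# ---------------------------------------------------------------------------
# Recording I/O: CSV (human-readable fixtures) and EDF+ (interchange)
# ---------------------------------------------------------------------------

def _annotation_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annotations.csv")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
        if fmt not in ("EDF", "CSV"):
            raise ValueError(f"unknown recording format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "EDF"
    if suffix == ".csv":
        return "CSV"
    raise ValueError(f"cannot infer recording format from {path.name!r}")


def write_recording(recording: Recording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as EDF+ or as CSV with an annotation sidecar.

    CSV stores samples as rows, channels as columns (header row of
    labels) and the sampling rate on a leading ``# rate:`` comment line;
    annotations go to ``<name>.csv.annotations.csv``.  EDF+ stores
    annotations on a standard annotations signal.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "CSV":
        _write_csv(recording, path)
    else:
        _write_edf(recording, path)


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_csv(path) if fmt == "CSV" else _read_edf(path)


def _write_csv(recording: Recording, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# rate: {float(recording.rate)!r}\n")
        writer = csv.writer(fh)
        writer.writerow(recording.channel_labels)
        for row in recording.data.T:
            writer.writerow([repr(float(v)) for v in row])
    with open(_annotation_sidecar(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "onset", "duration"])
        for label, onset, dur in recording.annotations:
            writer.writerow([label, repr(float(onset)), repr(float(dur))])


def _read_csv(path: Path) -> Recording:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# rate:"):
            raise ValueError(f"{path.name}: missing '# rate:' header line")
        rate = float(header.split(":", 1)[1])
        reader = csv.reader(fh)
        labels = next(reader, None)
        if not labels:
            raise ValueError(f"{path.name}: missing channel-label header row")
        rows = []
        for i, row in enumerate(reader):
            if len(row) != len(labels):
                raise ValueError(
                    f"{path.name}: row {i} has {len(row)} fields, "
                    f"expected {len(labels)}"
                )
            rows.append([float(v) for v in row])
    data = np.asarray(rows, dtype=float).T if rows else np.empty((len(labels), 0))
    annotations: list[tuple[str, float, float]] = []
    sidecar = _annotation_sidecar(path)
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            reader = csv.reader(fh)
            next(reader, None)
            for row in reader:
                annotations.append((row[0], float(row[1]), float(row[2])))
    return Recording(data, rate, labels, annotations)


def _write_edf(recording: Recording, path: Path) -> None:
    """Minimal EDF+C writer: 16-bit samples, 1-s data records, one
    annotations signal carrying the event schedule."""
    rate = recording.rate
    spr = rate
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    spr = int(round(spr))
    n_records = recording.n_samples / spr
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError(
            "EDF export needs a whole number of 1-s records; pad or trim "
            f"the {recording.n_samples}-sample recording first"
        )
    n_records = int(round(n_records))
    if n_records == 0:
        raise ValueError("cannot write an empty recording to EDF")

    n_sig = recording.n_channels + 1  # + annotations channel
    data = recording.data

    # Physical scaling per channel; flat channels get a token 1 uV span.
    phys_min = data.min(axis=1, initial=0.0)
    phys_max = data.max(axis=1, initial=0.0)
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 0.5, phys_min)
    phys_max = np.where(flat, phys_max + 0.5, phys_max)
    dig_min, dig_max = -32768, 32767

    # Timestamp TAL per record, plus every annotation in record 0.
    tals: list[bytes] = []
    for rec in range(n_records):
        tal = f"+{rec}\x14\x14\x00".encode("ascii")
        if rec == 0:
            for label, onset, dur in recording.annotations:
                tal += (
                    f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00".encode("utf-8")
                )
        tals.append(tal)
    annot_spr = max(8, (max(len(t) for t in tals) + 1) // 2)

    def pad(text: str, width: int) -> bytes:
        raw = text.encode("ascii")
        if len(raw) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return raw.ljust(width)

    hdr = io.BytesIO()
    hdr.write(pad("0", 8))
    hdr.write(pad("X X X X", 80))                   # patient id
    hdr.write(pad("Startdate X X X X", 80))         # recording id
    hdr.write(pad("01.01.00", 8))
    hdr.write(pad("00.00.00", 8))
    hdr.write(pad(str(256 * (n_sig + 1)), 8))
    hdr.write(pad("EDF+C", 44))
    hdr.write(pad(str(n_records), 8))
    hdr.write(pad("1", 8))                          # record duration, s
    hdr.write(pad(str(n_sig), 4))

    labels = list(recording.channel_labels) + ["EDF Annotations"]
    transducer = [""] * recording.n_channels + [""]
    dims = ["uV"] * recording.n_channels + [""]
    pmin = [f"{v:.6g}" for v in phys_min] + ["-1"]
    pmax = [f"{v:.6g}" for v in phys_max] + ["1"]
    dmin = [str(dig_min)] * recording.n_channels + [str(dig_min)]
    dmax = [str(dig_max)] * recording.n_channels + [str(dig_max)]
    prefilter = [""] * n_sig
    sprs = [str(spr)] * recording.n_channels + [str(annot_spr)]
    for values, width in (
        (labels, 16), (transducer, 80), (dims, 8), (pmin, 8), (pmax, 8),
        (dmin, 8), (dmax, 8), (prefilter, 80), (sprs, 8),
    ):
        for v in values:
            hdr.write(pad(v, width))
    hdr.write(b" " * (32 * n_sig))                  # reserved

    # Re-read the physical extrema exactly as formatted, so that the
    # writer and any standards-compliant reader agree on scaling.
    pmin_f = np.array([float(v) for v in pmin[:-1]])
    pmax_f = np.array([float(v) for v in pmax[:-1]])
    gain = (pmax_f - pmin_f) / (dig_max - dig_min)

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for rec in range(n_records):
            chunk = data[:, rec * spr:(rec + 1) * spr]
            digital = np.rint(
                (chunk - pmin_f[:, None]) / gain[:, None] + dig_min
            ).astype("<i2")
            fh.write(digital.tobytes())
            tal = tals[rec].ljust(2 * annot_spr, b"\x00")
            fh.write(tal)


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise ValueError(f"cannot parse EDF file {path.name}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    annotations = [
        (desc, float(onset), float(dur))
        for desc, onset, dur in zip(
            raw.annotations.description, raw.annotations.onset,
            raw.annotations.duration,
        )
    ]
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                     annotations)
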