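"""Reading, writing, and windowing of EEG recordings.

Two input layouts are supported: single-channel plain-text segments
(Bonn-style, one ASCII decimal per line, 173.61 Hz) and multi-channel EDF
recordings (CHB-MIT-style, typically 23 channels at 256 Hz).  Seizure
annotations come from a tab-separated sidecar file ("start_s<TAB>end_s" per
line), not from EDF+ records.

Amplitudes are kept in microvolts throughout.  Time coordinates are
0-based and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Signal",
    "SeizureAnnotation",
    "SegmentSet",
    "read_bonn_segment",
    "read_edf",
    "write_edf",
    "read_annotations",
    "segment_sliding",
    "expected_segment_points",
    "flatten_multichannel",
    "balance_classes",
    "save_segment_set",
    "load_segment_set",
]

BONN_RATE = 173.61  # Hz, sampling rate of the Bonn university EEG sets


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled multi-channel series.

    ``samples`` has shape ``(n_channels, n)`` in microvolts; ``rate`` is in
    Hz; ``channels`` holds one label per row.
    """

    samples: np.ndarray
    rate: float
    channels: tuple[str, ...] = ("ch1",)

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", arr)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if arr.ndim != 2:
            raise ValueError("samples must be a vector or a (channels, n) matrix")
        if arr.shape[0] != len(self.channels):
            raise ValueError(
                f"{arr.shape[0]} channel rows but {len(self.channels)} labels"
            )
        if arr.shape[1] < 2:
            raise ValueError("a signal needs at least 2 samples per channel")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n(self) -> int:
        """Sample count per channel."""
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n / self.rate

    def channel(self, index: int = 0) -> np.ndarray:
        """1-D view of one channel."""
        return self.samples[index]


@dataclass(frozen=True)
class SeizureAnnotation:
    """An expert-marked seizure interval, in seconds from recording start."""

    start_s: float
    end_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"need 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )


@dataclass
class SegmentSet:
    """Fixed-length labeled windows cut from one or more recordings."""

    segments: list[Signal]
    labels: list[str]
    window_s: float
    points_per_segment: int = 0

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise ValueError("labels must align with segments")
        if self.segments:
            counts = {s.n * s.n_channels for s in self.segments}
            if len(counts) > 1:
                raise ValueError(f"segments differ in length: {sorted(counts)}")
            self.points_per_segment = counts.pop()

    def __len__(self) -> int:
        return len(self.segments)


def read_bonn_segment(path: str | Path, rate: float = BONN_RATE) -> Signal:
    """Read a Bonn-style text segment: one amplitude (µV) per line."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not numeric: {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: empty segment file")
    return Signal(np.asarray(values, dtype=float), rate=rate, channels=(path.stem,))


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit standard header
# ---------------------------------------------------------------------------


def _edf_header_samples_per_record(path: Path) -> list[int]:
    """Parse per-channel samples-per-record straight from the EDF header.

    Used only to validate that all channels share one sampling rate before
    handing the file to the mne reader (which silently resamples mixed-rate
    layouts).
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            ns = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError):
            raise ValueError(f"{path}: malformed EDF header") from None
        if ns <= 0:
            raise ValueError(f"{path}: malformed EDF header (no channels)")
        var = fh.read(ns * 256)
        if len(var) < ns * 256:
            raise ValueError(f"{path}: truncated EDF channel header")
        off = ns * 216  # label..prefilter fields precede samples-per-record
        spr = []
        for ch in range(ns):
            raw = var[off + ch * 8 : off + (ch + 1) * 8]
            try:
                spr.append(int(raw.decode("ascii").strip()))
            except (UnicodeDecodeError, ValueError):
                raise ValueError(f"{path}: malformed EDF header") from None
    return spr


def read_edf(path: str | Path) -> Signal:
    """Read a multi-channel EDF recording into a µV :class:`Signal`.

    The sampling rate comes from the header and channel labels are kept in
    file order.  Files whose channels are sampled at different rates are
    rejected rather than resampled.
    """
    import mne

    path = Path(path)
    spr = _edf_header_samples_per_record(path)
    if len(set(spr)) > 1:
        raise ValueError(
            f"{path}: channels use different sampling rates {sorted(set(spr))}; "
            "mixed-rate EDF layouts are not supported"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise ValueError(f"{path}: not a readable EDF file ({exc})") from exc
    data = raw.get_data()  # volts for dimensioned channels
    orig_units = getattr(raw, "_orig_units", {}) or {}
    scale = np.ones(data.shape[0])
    for i, name in enumerate(raw.ch_names):
        unit = orig_units.get(name, "")
        # mne rescales uV-dimensioned signals to volts; undo to µV
        if unit in ("µV", "uV", "V", ""):
            scale[i] = 1e6 if unit in ("µV", "uV", "V") else 1.0
    # Channels mne left dimensionless are assumed already in µV.
    data = data * scale[:, None]
    return Signal(data, rate=float(raw.info["sfreq"]), channels=tuple(raw.ch_names))


def write_edf(signal: Signal, path: str | Path) -> None:
    """Write a :class:`Signal` as a minimal 16-bit EDF file.

    One-second data records; the rate must be a positive integer and the
    length a whole number of seconds.  Values are quantized to the 16-bit
    range spanned by each channel's physical min/max.
    """
    path = Path(path)
    rate = signal.rate
    if rate != int(rate) or rate <= 0:
        raise ValueError("EDF writer supports integer sampling rates only")
    spr = int(rate)
    if signal.n % spr != 0:
        raise ValueError("EDF writer needs a whole number of 1-s records")
    n_rec = signal.n // spr
    ns = signal.n_channels

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X", 80),  # patient id
            pad("X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration (s)
            pad(str(ns), 4),
        ]
    )
    phys_min = signal.samples.min(axis=1)
    phys_max = signal.samples.max(axis=1)
    # Avoid a zero span for constant channels
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def column(fmt, width):
        return b"".join(pad(fmt(c), width) for c in range(ns))

    header += column(lambda c: signal.channels[c], 16)
    header += column(lambda c: "", 80)  # transducer
    header += column(lambda c: "uV", 8)
    header += column(lambda c: f"{phys_min[c]:.6g}", 8)
    header += column(lambda c: f"{phys_max[c]:.6g}", 8)
    header += column(lambda c: str(dig_min), 8)
    header += column(lambda c: str(dig_max), 8)
    header += column(lambda c: "", 80)  # prefilter
    header += column(lambda c: str(spr), 8)
    header += column(lambda c: "", 32)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.rint((signal.samples - phys_min[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            block = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(block.tobytes())  # channel after channel within a record


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read a seizure sidecar: one "start_s<TAB>end_s" pair per line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'start<TAB>end'")
            out.append(SeizureAnnotation(float(parts[0]), float(parts[1])))
    return out


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def expected_segment_points(rate: float, duration: float, n_channels: int) -> int:
    """Total sampled values in one window: floor(rate·duration)·channels.

    Fractional counts are floored, e.g. 173.61 Hz × 23.6 s → 4097 points.
    """
    if rate <= 0 or duration <= 0 or n_channels < 1:
        raise ValueError("rate, duration and n_channels must be positive")
    # Tiny epsilon guards decimal rates whose product lands a hair under an
    # integer in binary floating point (e.g. 256 × 3).
    return int(np.floor(rate * duration + 1e-9)) * int(n_channels)


def _window_samples(seconds: float, rate: float, what: str) -> int:
    n = seconds * rate
    if n <= 0 or abs(n - round(n)) > 1e-6:
        raise ValueError(f"{what} of {seconds} s is not a whole number of samples at {rate} Hz")
    return int(round(n))


def segment_sliding(
    signal: Signal,
    annotations: list[SeizureAnnotation],
    window_s: float = 3.0,
    step_s: float = 1.0,
) -> SegmentSet:
    """Cut labeled sliding windows from a recording.

    A window is labeled ``seizure`` iff it lies entirely inside one
    annotated interval and ``non-seizure`` iff it is entirely outside all
    of them; windows straddling a boundary are discarded.
    """
    win = _window_samples(window_s, signal.rate, "window")
    step = _window_samples(step_s, signal.rate, "step")
    if win > signal.n:
        raise ValueError(
            f"window of {window_s} s exceeds the {signal.duration_s:.2f} s recording"
        )
    segments: list[Signal] = []
    labels: list[str] = []
    for start in range(0, signal.n - win + 1, step):
        t0 = start / signal.rate
        t1 = (start + win) / signal.rate
        inside = any(a.start_s <= t0 and t1 <= a.end_s for a in annotations)
        overlaps = any(t0 < a.end_s and a.start_s < t1 for a in annotations)
        if overlaps and not inside:
            continue  # straddles a seizure boundary
        segments.append(
            Signal(signal.samples[:, start : start + win], signal.rate, signal.channels)
        )
        labels.append("seizure" if inside else "non-seizure")
    return SegmentSet(segments, labels, window_s)


def flatten_multichannel(segment: Signal, order: str = "channel-major") -> Signal:
    """Concatenate channels into one single-channel series.

    ``channel-major`` (default) lays channels end to end; ``time-major``
    interleaves samples time point by time point.
    """
    if segment.n_channels == 1:
        return segment
    if order == "channel-major":
        flat = segment.samples.ravel(order="C")
    elif order == "time-major":
        flat = segment.samples.ravel(order="F")
    else:
        raise ValueError(f"unknown order {order!r}")
    return Signal(flat, rate=segment.rate, channels=("flat",))


def balance_classes(segset: SegmentSet, seed: int = 0) -> SegmentSet:
    """Downsample majority classes to the minority-class count (seeded)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(segset.labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.min()
    keep: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep.extend(sorted(idx))
    keep.sort()
    return SegmentSet(
        [segset.segments[i] for i in keep],
        [segset.labels[i] for i in keep],
        segset.window_s,
    )


# ---------------------------------------------------------------------------
# SegmentSet on disk: CSV manifest + one text file per segment
# ---------------------------------------------------------------------------


def save_segment_set(segset: SegmentSet, directory: str | Path) -> Path:
    """Write a CSV manifest plus per-segment text files; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "segments.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["segment_id", "label", "file", "rate_hz", "n_channels", "window_s"]
        )
        for i, (seg, label) in enumerate(zip(segset.segments, segset.labels)):
            name = f"segment_{i:05d}.txt"
            flat = seg.samples.ravel(order="C")
            np.savetxt(directory / name, flat, fmt="%.10g")
            writer.writerow([i, label, name, seg.rate, seg.n_channels, segset.window_s])
    return manifest


def load_segment_set(manifest: str | Path) -> SegmentSet:
    """Inverse of :func:`save_segment_set`."""
    manifest = Path(manifest)
    directory = manifest.parent
    segments: list[Signal] = []
    labels: list[str] = []
    window_s = 0.0
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            flat = np.loadtxt(directory / row["file"], ndmin=1)
            n_ch = int(row["n_channels"])
            samples = flat.reshape(n_ch, -1)
            channels = tuple(f"ch{c + 1}" for c in range(n_ch))
            segments.append(Signal(samples, float(row["rate_hz"]), channels))
            labels.append(row["label"])
            window_s = float(row["window_s"])
    return SegmentSet(segments, labels, window_s)
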