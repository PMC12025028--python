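"""Session I/O, preprocessing filters and sliding-window segmentation.

A recording session is a multichannel surface-EMG signal (4 forearm
electrodes by default) with labelled active intervals.  Preprocessing
follows the usual offline sEMG chain: a powerline notch, a Butterworth
band-pass, then segmentation into dense overlapping analysis windows
(250 ms window, 50 ms step by default, i.e. 80 % overlap).

All filters are applied forward-backward (zero phase) since the pipeline
is offline; time intervals are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .granular_labels import GestureLabel

__all__ = [
    "RecordingSession",
    "SignalWindow",
    "FilterSpec",
    "FormatError",
    "read_session",
    "write_session",
    "notch_filter",
    "bandpass_filter",
    "segment_windows",
    "window_samples",
    "save_windows",
    "load_windows",
]

logger = logging.getLogger(__name__)

SIGNAL_HEADER = ["time_s", "ch1", "ch2", "ch3", "ch4"]
ANNOTATION_HEADER = ["label", "start_s", "end_s"]


class FormatError(ValueError):
    """Raised when an on-disk session file violates the expected format."""


@dataclass
class RecordingSession:
    """Multichannel sEMG recording with labelled gesture intervals.

    signal is ``(n_channels, n_samples)`` in mV; annotations are
    ``(label, start_s, end_s)`` with non-overlapping half-open intervals
    inside the recording.
    """

    signal: np.ndarray
    sampling_rate: float
    annotations: list[tuple[GestureLabel, float, float]] = field(default_factory=list)
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration_s
        prev_end = -np.inf
        for label, start, end in sorted(self.annotations, key=lambda a: a[1]):
            if not 0.0 <= start < end:
                raise ValueError(f"bad interval [{start}, {end})")
            if end > dur + 1e-9:
                raise ValueError(
                    f"annotation [{start}, {end}) exceeds signal duration {dur:.6f} s"
                )
            if start < prev_end - 1e-12:
                raise ValueError("annotations overlap")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SignalWindow:
    """One fixed-length analysis window: ``samples`` is (channels, N) mV."""

    samples: np.ndarray
    label: GestureLabel
    start_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("window samples must be 2-D (channels x N)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing filter parameters.

    Defaults are standard sEMG choices: 50 Hz notch (Q = 30) against
    powerline interference and a 4th-order 20-450 Hz Butterworth
    band-pass covering the sEMG energy band.
    """

    notch_freq: float = 50.0
    notch_q: float = 30.0
    band_low: float = 20.0
    band_high: float = 450.0
    butterworth_order: int = 4

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.band_low < self.band_high < nyq:
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) must lie inside (0, {nyq})"
            )
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")
        if not 0 < self.notch_freq < nyq:
            raise ValueError(f"notch_freq must lie inside (0, {nyq})")


# ---------------------------------------------------------------------------
# CSV I/O


def write_session(session: RecordingSession, signal_path, annotation_path) -> None:
    """Write a session as a signal CSV (time_s,ch1..ch4) and an annotation
    CSV (label,start_s,end_s); labels are stored as fine ids."""
    t = np.arange(session.n_samples) / session.sampling_rate
    sig = pd.DataFrame({"time_s": t})
    for c in range(session.n_channels):
        sig[f"ch{c + 1}"] = session.signal[c]
    sig.to_csv(signal_path, index=False, float_format="%.6f")
    ann = pd.DataFrame(
        [
            {"label": label.fine_id, "start_s": start, "end_s": end}
            for label, start, end in session.annotations
        ],
        columns=ANNOTATION_HEADER,
    )
    ann.to_csv(annotation_path, index=False)


def read_session(signal_path, annotation_path, subject_id: str = "unknown") -> RecordingSession:
    """Read a session from its two CSVs, inferring the sampling rate from
    the median time step and validating annotations against duration."""
    signal_path, annotation_path = Path(signal_path), Path(annotation_path)
    try:
        sig = pd.read_csv(signal_path)
    except Exception as exc:  # ragged rows etc.
        raise FormatError(f"{signal_path}: {exc}") from exc
    missing = [c for c in SIGNAL_HEADER if c not in sig.columns]
    if missing:
        raise FormatError(f"{signal_path}: missing columns {missing}")
    if sig.isna().any().any():
        line = int(sig.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 1-based
        raise FormatError(f"{signal_path}: missing value near line {line}")
    t = sig["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{signal_path}: need at least 2 samples to infer rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise FormatError(f"{signal_path}: non-monotone time at line {line}")
    fs = 1.0 / float(np.median(dt))
    channels = [c for c in sig.columns if c.startswith("ch")]
    data = sig[channels].to_numpy(dtype=float).T

    try:
        ann = pd.read_csv(annotation_path)
    except Exception as exc:
        raise FormatError(f"{annotation_path}: {exc}") from exc
    missing = [c for c in ANNOTATION_HEADER if c not in ann.columns]
    if missing:
        raise FormatError(f"{annotation_path}: missing columns {missing}")
    annotations = []
    duration = data.shape[1] / fs
    for i, row in ann.iterrows():
        start, end = float(row["start_s"]), float(row["end_s"])
        if not 0 <= start < end or end > duration + 1e-9:
            raise FormatError(
                f"{annotation_path}: line {i + 2}: interval [{start}, {end}) "
                f"outside signal duration {duration:.6f} s"
            )
        annotations.append((GestureLabel.from_fine_id(int(row["label"])), start, end))
    return RecordingSession(data, fs, annotations, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Filters


def notch_filter(session: RecordingSession, spec: FilterSpec = FilterSpec()) -> RecordingSession:
    """Zero-phase IIR notch at ``spec.notch_freq`` applied per channel."""
    nyq = session.sampling_rate / 2.0
    if spec.notch_freq >= nyq:
        raise ValueError(f"notch_freq {spec.notch_freq} >= Nyquist {nyq}")
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=session.sampling_rate)
    filtered = sps.filtfilt(b, a, session.signal, axis=1)
    return replace(session, signal=filtered)


def bandpass_filter(session: RecordingSession, spec: FilterSpec = FilterSpec()) -> RecordingSession:
    """Zero-phase Butterworth band-pass applied per channel."""
    spec.validate(session.sampling_rate)
    sos = sps.butter(
        spec.butterworth_order,
        (spec.band_low, spec.band_high),
        btype="bandpass",
        fs=session.sampling_rate,
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, session.signal, axis=1)
    return replace(session, signal=filtered)


# ---------------------------------------------------------------------------
# Segmentation


def window_samples(sampling_rate: float, window_ms: float) -> int:
    """Window length in samples: floor(fs * window_ms / 1000).

    At 1925.9259 Hz and 250 ms this truncates to 481 samples.
    """
    return int(np.floor(sampling_rate * window_ms / 1000.0))


def segment_windows(
    session: RecordingSession, window_ms: float = 250.0, step_ms: float = 50.0
) -> list[SignalWindow]:
    """Cut each annotated interval into overlapping labelled windows.

    Window starts advance by the step within each interval; only windows
    fully contained in a single interval are emitted, so no window ever
    straddles an active/rest boundary or carries an ambiguous label.
    An interval shorter than one window yields no windows (warned, not an
    error).
    """
    if not window_ms > step_ms > 0:
        raise ValueError(f"need window_ms > step_ms > 0, got {window_ms}, {step_ms}")
    fs = session.sampling_rate
    n = window_samples(fs, window_ms)
    step = int(np.floor(fs * step_ms / 1000.0))
    if step < 1 or n < 2:
        raise ValueError("window/step too short for this sampling rate")
    windows: list[SignalWindow] = []
    for label, start_s, end_s in session.annotations:
        i0 = int(np.ceil(start_s * fs - 1e-9))
        i1 = min(int(np.floor(end_s * fs - 1e-9)) + 1, session.n_samples)
        length = i1 - i0
        if length < n:
            logger.warning(
                "interval [%.3f, %.3f) shorter than one window; skipped", start_s, end_s
            )
            continue
        for k in range((length - n) // step + 1):
            s = i0 + k * step
            windows.append(
                SignalWindow(session.signal[:, s : s + n].copy(), label, s / fs)
            )
    return windows


# ---------------------------------------------------------------------------
# Windowed-dataset container (HDF5 array + sidecar label CSV)


def save_windows(windows: list[SignalWindow], h5_path, sidecar_csv=None) -> None:
    """Persist windows as one (n_windows, channels, N) array plus a sidecar
    CSV of fine ids and start offsets."""
    if not windows:
        raise ValueError("no windows to save")
    h5_path = Path(h5_path)
    arr = np.stack([w.samples for w in windows])
    fine_ids = np.array([w.label.fine_id for w in windows], dtype=np.int64)
    starts = np.array([w.start_s for w in windows])
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("windows", data=arr)
        f.create_dataset("fine_id", data=fine_ids)
        f.create_dataset("start_s", data=starts)
    if sidecar_csv is None:
        sidecar_csv = h5_path.with_suffix(".labels.csv")
    pd.DataFrame(
        {"window_id": np.arange(len(windows)), "label": fine_ids, "start_s": starts}
    ).to_csv(sidecar_csv, index=False)


def load_windows(h5_path) -> list[SignalWindow]:
    with h5py.File(h5_path, "r") as f:
        arr = f["windows"][()]
        fine_ids = f["fine_id"][()]
        starts = f["start_s"][()]
    return [
        SignalWindow(arr[i], GestureLabel.from_fine_id(int(fine_ids[i])), float(starts[i]))
        for i in range(arr.shape[0])
    ]
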