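"""Handcrafted time-domain sEMG features.

Four classic features are computed per channel per window:

* ``RMS`` — root mean square, sqrt(1/N * sum x_i^2): signal amplitude.
* ``VAR`` — sum x_i^2 / (N - 1).  Note: this is the mean-power form
  (no mean subtraction), akin to simple square integral / mean power,
  not the statistical variance about the mean; the name is kept for
  continuity with the EMG feature literature.
* ``ZC``  — thresholded zero crossings: the number of adjacent sample
  pairs with -x_i * x_{i+1} > eps, where sgn(x) = 1 if x > eps else 0.
  The deadband eps suppresses noise-floor crossings.
* ``WL``  — waveform length, sum |x_{i+1} - x_i|: cumulative path
  length, sensitive to both amplitude and frequency.

A window of 4 channels yields a 16-dimensional feature vector in
channel-major order (ch1: RMS,VAR,ZC,WL, ch2: ..., ch4: WL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import SignalWindow

__all__ = [
    "FEATURE_NAMES",
    "FeatureParams",
    "FeatureVector",
    "FeatureScaler",
    "rms",
    "var_power",
    "zero_crossings",
    "waveform_length",
    "extract_features",
    "feature_matrix",
    "feature_frame",
    "fit_scaler",
    "apply_scaler",
]

FEATURE_NAMES = ("rms", "var", "zc", "wl")


@dataclass(frozen=True)
class FeatureParams:
    """zc_threshold is the deadband eps (mV) of the zero-crossing count."""

    zc_threshold: float = 0.01
    feature_order: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.zc_threshold < 0:
            raise ValueError("zc_threshold must be >= 0")
        if sorted(self.feature_order) != sorted(FEATURE_NAMES):
            raise ValueError(f"feature_order must permute {FEATURE_NAMES}")


@dataclass
class FeatureVector:
    """16 values (4 features x 4 channels), channel-major."""

    values: np.ndarray
    window_ref: SignalWindow | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature vector must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample vector")
    return x


def rms(x) -> float:
    x = _as_vector(x)
    if x.size < 1:
        raise ValueError("rms needs at least one sample")
    return float(np.sqrt(np.mean(np.square(x))))


def var_power(x) -> float:
    x = _as_vector(x)
    if x.size < 2:
        raise ValueError("var_power needs at least two samples")
    return float(np.sum(np.square(x)) / (x.size - 1))


def zero_crossings(x, eps: float = 0.0) -> int:
    x = _as_vector(x)
    if x.size < 2:
        raise ValueError("zero_crossings needs at least two samples")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    return int(np.count_nonzero(-x[:-1] * x[1:] > eps))


def waveform_length(x) -> float:
    x = _as_vector(x)
    if x.size < 2:
        raise ValueError("waveform_length needs at least two samples")
    return float(np.sum(np.abs(np.diff(x))))


_FEATURE_FUNCS = {
    "rms": lambda x, p: rms(x),
    "var": lambda x, p: var_power(x),
    "zc": lambda x, p: float(zero_crossings(x, p.zc_threshold)),
    "wl": lambda x, p: waveform_length(x),
}


def extract_features(window: SignalWindow, params: FeatureParams = FeatureParams()) -> FeatureVector:
    """Per-channel features concatenated channel-major in ``feature_order``."""
    vals = [
        _FEATURE_FUNCS[name](window.samples[c], params)
        for c in range(window.samples.shape[0])
        for name in params.feature_order
    ]
    return FeatureVector(np.array(vals), window_ref=window)


def feature_matrix(windows: list[SignalWindow], params: FeatureParams = FeatureParams()) -> np.ndarray:
    """Stack features for many windows into an (n_windows, 16) matrix."""
    return np.stack([extract_features(w, params).values for w in windows])


def feature_frame(windows: list[SignalWindow], params: FeatureParams = FeatureParams()) -> pd.DataFrame:
    """Exportable feature table: window_id, label (fine id), then
    ch{c}_{feature} columns in the frozen ordering."""
    mat = feature_matrix(windows, params)
    n_ch = windows[0].samples.shape[0]
    cols = [f"ch{c + 1}_{name}" for c in range(n_ch) for name in params.feature_order]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "label", [w.label.fine_id for w in windows])
    df.insert(0, "window_id", np.arange(len(windows)))
    return df


@dataclass
class FeatureScaler:
    """Per-dimension z-score parameters fitted on training data."""

    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive in every dimension")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.location) / self.scale


_SCALE_FLOOR = 1e-8


def fit_scaler(train) -> FeatureScaler:
    """Standardiser fitted on the training split only; near-constant
    dimensions get their scale clamped to a small floor so degenerate
    features cannot blow up downstream models."""
    if isinstance(train, np.ndarray):
        mat = train
    else:
        train = list(train)
        if not train:
            raise ValueError("empty training set")
        mat = np.stack([v.values if isinstance(v, FeatureVector) else v for v in train])
    if mat.size == 0:
        raise ValueError("empty training set")
    loc = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale = np.where(scale < _SCALE_FLOOR, _SCALE_FLOOR, scale)
    return FeatureScaler(loc, scale)


def apply_scaler(scaler: FeatureScaler, v):
    """Standardise a FeatureVector, raw vector or matrix of rows."""
    if isinstance(v, FeatureVector):
        return FeatureVector(scaler.transform(v.values), window_ref=v.window_ref)
    return scaler.transform(v)
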