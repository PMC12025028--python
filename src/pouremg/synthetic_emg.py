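"""Protocol-faithful synthetic surface-EMG generator.

The acquisition protocol being emulated: a seated subject holds a water
bottle and pours to the left, right or front at wrist angles of 22.5,
45, 67.5 or 90 degrees; each gesture is held for 5 s followed by 5 s of
rest, recorded by four electrodes around the thickest part of the
forearm at 1925.9259 Hz.  The hold (static grip) gesture is recorded
twice per repetition block, mirroring its two slots in the fine label
numbering (ids 5 and 10).

The signal model is deliberately simple — this generator exists so the
downstream pipeline is testable with known ground truth, not to imitate
motor-unit physiology:

* carrier: Gaussian white noise band-passed to the typical 20-450 Hz
  sEMG band, normalised to unit RMS per channel;
* activation: each active interval scales the carrier by a per-channel
  gain that depends on pouring direction (which electrodes sit over the
  recruited muscles) and multiplicatively on angle (steeper pours
  recruit harder), with 100 ms trapezoidal onset/offset ramps;
* additive 50 Hz powerline sinusoid and broadband baseline noise.

Direction determines *which* channel dominates, angle determines *how
much* — so classes are separable by construction while adjacent angles
remain the closest competitors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .granular_labels import ANGLES, Direction, GestureLabel
from .signal_io import RecordingSession

__all__ = [
    "ProtocolPlan",
    "SynthParams",
    "DEFAULT_SAMPLING_RATE",
    "make_protocol",
    "channel_activation_profile",
    "angle_scale",
    "synthesize_session",
]

DEFAULT_SAMPLING_RATE = 1925.9259

#: relative per-channel gains by direction; electrodes sit front/back/
#: left/right of the forearm so each pouring direction loads a distinct
#: dominant electrode.  Hold is a uniform low-amplitude grip.
_DIRECTION_PROFILES: dict[Direction, tuple[float, float, float, float]] = {
    Direction.FRONT: (1.00, 0.30, 0.25, 0.35),
    Direction.LEFT: (0.30, 0.25, 1.00, 0.40),
    Direction.RIGHT: (0.25, 0.35, 0.40, 1.00),
    Direction.HOLD: (0.15, 0.15, 0.15, 0.15),
}


def angle_scale(angle: float) -> float:
    """Monotone amplitude multiplier: linear from 0.4 at 22.5 deg to 1.0
    at 90 deg."""
    if angle not in ANGLES:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle!r}")
    return 0.4 + 0.6 * (angle - 22.5) / 67.5


def channel_activation_profile(direction: Direction | str, angle: float | None = None) -> np.ndarray:
    """Deterministic 4-vector of relative channel gains for a gesture.

    Distinct directions have distinct dominant (argmax) channels; for
    pouring gestures the whole profile scales monotonically with angle.
    """
    direction = Direction(direction)
    base = np.array(_DIRECTION_PROFILES[direction])
    if direction is Direction.HOLD:
        if angle is not None:
            raise ValueError("hold has no angle")
        return base
    if angle is None:
        raise ValueError(f"{direction.value} pouring requires an angle")
    return base * angle_scale(angle)


@dataclass
class ProtocolPlan:
    """Ordered trial list: (gesture, active seconds, rest seconds)."""

    trials: list[tuple[GestureLabel, float, float]]
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for label, active, rest in self.trials:
            if not isinstance(label, GestureLabel):
                raise ValueError(f"not a gesture label: {label!r}")
            if active <= 0 or rest < 0:
                raise ValueError("need active > 0 and rest >= 0")

    @property
    def total_duration_s(self) -> float:
        return float(sum(a + r for _, a, r in self.trials))


@dataclass
class SynthParams:
    """Knobs of the synthetic signal model (amplitudes in mV)."""

    amplitude: float = 1.0  # RMS of a fully recruited channel
    carrier_band: tuple[float, float] = (20.0, 450.0)
    powerline_freq: float = 50.0
    powerline_amplitude: float = 0.1  # 10% of max active RMS
    baseline_noise_sd: float = 0.03
    ramp_s: float = 0.1  # trapezoidal onset/offset ramp
    seed: int = 0

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        lo, hi = self.carrier_band
        if not 0 < lo < hi < nyq:
            raise ValueError(f"carrier_band {self.carrier_band} outside (0, {nyq})")
        if self.amplitude <= 0 or self.powerline_amplitude < 0 or self.baseline_noise_sd < 0:
            raise ValueError("amplitudes must be non-negative (carrier positive)")


def make_protocol(
    repetitions: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    active_s: float = 5.0,
    rest_s: float = 5.0,
    seed: int | None = None,
) -> ProtocolPlan:
    """Build the trial plan: per repetition, each of the 12 direction-angle
    gestures once plus the hold gesture twice (its two slots in the fine
    numbering), each trial ``active_s`` of gesture then ``rest_s`` of rest.

    With a seed the trial order is shuffled deterministically; without
    one the canonical block order is kept.
    """
    if repetitions < 1:
        raise ValueError(f"repetitions must be >= 1, got {repetitions}")
    gestures = [
        GestureLabel(d, a)
        for d in (Direction.LEFT, Direction.RIGHT, Direction.FRONT)
        for a in ANGLES
    ]
    trials: list[tuple[GestureLabel, float, float]] = []
    for _ in range(repetitions):
        block = gestures + [GestureLabel(Direction.HOLD), GestureLabel(Direction.HOLD)]
        trials.extend((g, float(active_s), float(rest_s)) for g in block)
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(trials))
        trials = [trials[i] for i in order]
    return ProtocolPlan(trials, sampling_rate)


def synthesize_session(
    plan: ProtocolPlan, params: SynthParams | None = None, subject_id: str = "synthetic"
) -> RecordingSession:
    """Render a plan into a 4-channel recording with exact annotations.

    The returned session's annotation intervals are the plan's active
    intervals; total sample count is ``round(fs * total duration)``.
    Identical (plan, params) including the seed give bit-identical
    signals.
    """
    params = params or SynthParams()
    fs = plan.sampling_rate
    params.validate(fs)
    n_ch = 4
    n_total = int(round(fs * plan.total_duration_s))
    rng = np.random.default_rng(params.seed)

    # unit-RMS band-limited carrier, one independent process per channel
    sos = sps.butter(4, params.carrier_band, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal((n_ch, n_total)), axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)

    # per-channel gain envelope over the whole timeline
    envelope = np.zeros((n_ch, n_total))
    annotations: list[tuple[GestureLabel, float, float]] = []
    ramp_n = max(int(round(params.ramp_s * fs)), 1)
    t0 = 0.0
    for label, active, rest in plan.trials:
        i0, i1 = int(round(t0 * fs)), min(int(round((t0 + active) * fs)), n_total)
        seg = i1 - i0
        gains = channel_activation_profile(label.direction, label.angle)
        shape = np.ones(seg)
        r = min(ramp_n, seg // 2)
        if r > 0:
            ramp = np.linspace(0.0, 1.0, r, endpoint=False)
            shape[:r] = ramp
            shape[seg - r :] = ramp[::-1]
        envelope[:, i0:i1] = gains[:, None] * shape[None, :]
        annotations.append((label, t0, t0 + active))
        t0 += active + rest

    t = np.arange(n_total) / fs
    powerline = params.powerline_amplitude * params.amplitude * np.sin(
        2 * np.pi * params.powerline_freq * t
    )
    baseline = params.baseline_noise_sd * params.amplitude * rng.standard_normal(
        (n_ch, n_total)
    )
    signal = params.amplitude * envelope * carrier + powerline[None, :] + baseline
    return RecordingSession(signal, fs, annotations, subject_id=subject_id)
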