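"""sEMG conditioning chain.

Raw surface EMG is high-pass filtered at 20 Hz (motion-artifact removal),
full-wave rectified, and low-pass filtered at 32 Hz to obtain the amplitude
envelope that tracks muscle contraction.  Both stages use fifth-order
Butterworth filters.  Envelope amplitudes are then standardized by a single
session-global scalar: the median of the pooled envelope samples over all
channels and all time points of the session.

Filtering is zero-phase (forward-backward) by default so that burst timing is
identical on both body sides; the single-pass response is available with
``zero_phase=False``.  Small negative overshoots that the low-pass stage can
introduce near sharp envelope transients are clipped to zero, keeping
downstream powers nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EmgSession, TrialSegment
from .errors import DegenerateSignalError, LengthError, ParameterError

__all__ = [
    "FilterSpec",
    "PreprocessConfig",
    "butterworth_filter",
    "rectify",
    "preprocess_trial",
    "standardize_session",
    "preprocess_session",
]


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage.

    kind: "highpass" or "lowpass"; cutoff in Hz; order >= 1.  With
    ``zero_phase`` the filter runs forward and backward: no phase distortion,
    attenuation doubled in dB (the -3 dB point of the single pass becomes
    -6 dB).
    """

    kind: str
    cutoff: float
    order: int = 5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ParameterError(f"filter kind must be highpass|lowpass, got {self.kind!r}")
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the conditioning chain (defaults = protocol values)."""

    hp_cutoff_hz: float = 20.0
    lp_cutoff_hz: float = 32.0
    filter_order: int = 5
    zero_phase: bool = True
    #: "pooled": one session-global median scalar (preserves between-muscle
    #: power ratios); "per_channel": each channel divided by its own median.
    standardization_mode: str = "pooled"
    #: envelope definition for downstream power extraction:
    #: "lowpass" = rectified + 32 Hz LP (default), "rectified" = no LP stage.
    envelope_stage: str = "lowpass"
    #: seconds excluded at each end of a trial during power integration.
    edge_trim_s: float = 1.0

    def __post_init__(self) -> None:
        if self.standardization_mode not in ("pooled", "per_channel"):
            raise ParameterError(f"bad standardization_mode {self.standardization_mode!r}")
        if self.envelope_stage not in ("lowpass", "rectified"):
            raise ParameterError(f"bad envelope_stage {self.envelope_stage!r}")


DEFAULT_CONFIG = PreprocessConfig()


def butterworth_filter(x: np.ndarray, sample_rate: float, spec: FilterSpec) -> np.ndarray:
    """Apply one Butterworth stage; output has the input's length."""
    x = np.asarray(x, dtype=float)
    nyquist = sample_rate / 2.0
    if not 0 < spec.cutoff < nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff:g} Hz not below Nyquist {nyquist:g} Hz"
        )
    if x.shape[-1] <= 3 * spec.order:
        raise LengthError(
            f"series of length {x.shape[-1]} too short for order-{spec.order} filter"
        )
    sos = signal.butter(spec.order, spec.cutoff, btype=spec.kind, fs=sample_rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def envelope_chain(
    samples: np.ndarray, sample_rate: float, config: PreprocessConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """HP -> rectify -> LP -> clip, along the last axis."""
    hp = FilterSpec("highpass", config.hp_cutoff_hz, config.filter_order, config.zero_phase)
    out = rectify(butterworth_filter(samples, sample_rate, hp))
    if config.envelope_stage == "lowpass":
        lp = FilterSpec("lowpass", config.lp_cutoff_hz, config.filter_order, config.zero_phase)
        out = butterworth_filter(out, sample_rate, lp)
    return np.clip(out, 0.0, None)


def preprocess_trial(
    segment: TrialSegment, config: PreprocessConfig = DEFAULT_CONFIG
) -> TrialSegment:
    """Run the conditioning chain on every channel of a trial.

    Returns a new segment with ``is_envelope=True``; channel count and length
    are unchanged.  Standardization is a separate, session-level step
    (:func:`standardize_session`) and is not applied here.
    """
    env = envelope_chain(segment.samples, segment.sample_rate, config)
    return segment.with_samples(env, is_envelope=True)


def standardize_session(
    envelopes: np.ndarray, mode: str = "pooled"
) -> tuple[np.ndarray, float | np.ndarray]:
    """Divide session envelopes by the session median amplitude.

    ``mode="pooled"`` (default): one scalar, the median of all samples pooled
    across channels and time — this preserves the between-muscle power ratios
    the coordination coefficients are built from.  ``mode="per_channel"``:
    each channel divided by its own median (sensitivity-analysis variant).
    Returns (standardized matrix, scale).
    """
    envelopes = np.asarray(envelopes, dtype=float)
    if mode == "pooled":
        scale: float | np.ndarray = float(np.median(envelopes))
        if scale <= 0:
            raise DegenerateSignalError("session median is zero; scale undefined")
        return envelopes / scale, scale
    if mode == "per_channel":
        scale = np.median(envelopes, axis=-1, keepdims=True)
        if np.any(scale <= 0):
            raise DegenerateSignalError("a channel median is zero; scale undefined")
        return envelopes / scale, scale.squeeze(-1)
    raise ParameterError(f"bad standardization mode {mode!r}")


def preprocess_session(
    session: EmgSession, config: PreprocessConfig = DEFAULT_CONFIG
) -> tuple[list[TrialSegment], float | np.ndarray]:
    """Full session pipeline: extract trials, condition each, standardize.

    The standardization scalar is the pooled median over the envelopes of all
    annotated trials of the session (the recorded material the indexes are
    computed from).  Returns (standardized trial segments, scale).
    """
    trials = [preprocess_trial(t, config) for t in session.extract_trials()]
    if not trials:
        raise DegenerateSignalError("session has no annotated trials")
    pooled = np.concatenate([t.samples for t in trials], axis=-1)
    _, scale = standardize_session(pooled, config.standardization_mode)
    if config.standardization_mode == "pooled":
        scaled = [t.with_samples(t.samples / scale) for t in trials]
    else:
        scaled = [t.with_samples(t.samples / np.asarray(scale)[:, None]) for t in trials]
    return scaled, scale
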