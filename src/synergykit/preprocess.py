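"""Raw sEMG to non-negative envelope matrices.

The synergy model D = C S + E factorizes *envelopes*: the low-frequency
amplitude profile of the rectified EMG interference pattern.  The chain
here is the standard synergy-literature pipeline — zero-phase Butterworth
band-pass, full-wave rectification, zero-phase Butterworth low-pass,
negatives clipped to zero — with every cutoff configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ArgumentError, DataError


@dataclass
class EnvelopeMatrix:
    """Non-negative preprocessed sEMG, channels x samples.

    ``values`` is the m x n matrix D of the synergy model: m channels
    (muscles) as rows, n time samples as columns.
    """

    values: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ArgumentError("EnvelopeMatrix requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise DataError("envelope contains non-finite values")
        if np.any(self.values < 0):
            raise DataError("envelope must be non-negative")
        m, n = self.values.shape
        if n <= m:
            raise DataError(
                f"expected channels x samples with n > m, got {m} x {n}"
            )
        if self.sampling_rate <= 0:
            raise ArgumentError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(m)]
        elif len(self.channel_names) != m:
            raise ArgumentError("channel_names length must equal channel count")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _butter_zero_phase(x, order, cutoff, fs, btype):
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def make_envelope(
    raw,
    sampling_rate: float,
    band: tuple[float, float] = (20.0, 450.0),
    env_cutoff: float = 4.0,
    order: int = 4,
    channel_names: list[str] | None = None,
) -> EnvelopeMatrix:
    """Band-pass, rectify and low-pass raw sEMG into an envelope matrix.

    Parameters
    ----------
    raw : array, channels x samples
        Raw sEMG.  The per-channel DC offset is removed by the band-pass.
    band : (low, high) in Hz
        Pass band of the 4th-order zero-phase Butterworth band-pass.
    env_cutoff : Hz
        Cutoff of the 4th-order zero-phase Butterworth low-pass applied
        after full-wave rectification.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.all(np.isfinite(raw)):
        raise DataError("raw sEMG contains non-finite values")
    low, high = band
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ArgumentError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    if not (0 < env_cutoff < nyq):
        raise ArgumentError("env_cutoff must lie inside the Nyquist band")
    # remove DC before rectification, then band-pass
    x = raw - raw.mean(axis=-1, keepdims=True)
    x = _butter_zero_phase(x, order, (low, high), sampling_rate, "bandpass")
    x = np.abs(x)
    x = _butter_zero_phase(x, order, env_cutoff, sampling_rate, "lowpass")
    env = np.clip(x, 0.0, None)
    return EnvelopeMatrix(env, sampling_rate, channel_names or [])


def concat_trials(envelopes: list[EnvelopeMatrix]) -> EnvelopeMatrix:
    """Concatenate envelope matrices along time, channels kept as rows."""
    if not envelopes:
        raise ArgumentError("need at least one envelope")
    first = envelopes[0]
    for e in envelopes[1:]:
        if e.m != first.m:
            raise ArgumentError(
                f"channel count mismatch: {e.m} vs {first.m}"
            )
        if e.sampling_rate != first.sampling_rate:
            raise ArgumentError("sampling rate mismatch")
    values = np.hstack([e.values for e in envelopes])
    return EnvelopeMatrix(values, first.sampling_rate, list(first.channel_names))


def normalize_channels(env: EnvelopeMatrix, mode: str = "max") -> EnvelopeMatrix:
    """Per-channel amplitude normalization.

    mode="max" rescales each channel so its maximum is 1; identically-zero
    channels are left untouched.  mode="none" is the identity.
    """
    if mode == "none":
        return EnvelopeMatrix(
            env.values.copy(), env.sampling_rate, list(env.channel_names)
        )
    if mode != "max":
        raise ArgumentError(f"unknown normalization mode: {mode!r}")
    peaks = env.values.max(axis=1, keepdims=True)
    scale = np.where(peaks > 0, peaks, 1.0)
    return EnvelopeMatrix(
        env.values / scale, env.sampling_rate, list(env.channel_names)
    )
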