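"""Elbow joint angle from a tri-axial accelerometer.

During slow flexion/extension the sensor is quasi-static: its output is
dominated by gravity, so the x-axis reading is Ax = g cos(alpha_g) with
alpha_g the angle between gravity and the sensor x-axis.  For the elbow
task the joint angle is the complement, theta = 90 deg - arccos(Ax / g).
Dynamic contamination is suppressed by a zero-phase low-pass rather than
sensor fusion; the gravity magnitude g is calibrated from a static
segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ArgumentError, CalibrationError, DataError, NotStaticError


@dataclass
class AccelTrace:
    """Tri-axial accelerometer samples (any consistent unit; calibration
    makes the angle formula unit-free)."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sampling_rate: float
    g_ref: float | None = None

    def __post_init__(self):
        self.ax = np.asarray(self.ax, dtype=float).ravel()
        self.ay = np.asarray(self.ay, dtype=float).ravel()
        self.az = np.asarray(self.az, dtype=float).ravel()
        if not (self.ax.size == self.ay.size == self.az.size):
            raise ArgumentError("axis lengths differ")
        for a in (self.ax, self.ay, self.az):
            if not np.all(np.isfinite(a)):
                raise DataError("accelerometer trace contains non-finite values")
        if self.sampling_rate <= 0:
            raise ArgumentError("sampling_rate must be positive")
        if self.g_ref is not None and self.g_ref <= 0:
            raise ArgumentError("g_ref must be positive")

    @property
    def n(self) -> int:
        return self.ax.size

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def slice(self, start: int, stop: int) -> "AccelTrace":
        return AccelTrace(
            self.ax[start:stop],
            self.ay[start:stop],
            self.az[start:stop],
            self.sampling_rate,
            self.g_ref,
        )


@dataclass
class AngleTrace:
    """Joint angle time series in degrees."""

    theta: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ArgumentError("sampling_rate must be positive")

    @property
    def n(self) -> int:
        return self.theta.size


def calibrate_gravity(
    static_segment: AccelTrace, max_rel_std: float = 0.05
) -> float:
    """Gravity magnitude from a resting segment.

    Returns the mean acceleration-vector magnitude over the segment.
    Requires at least 0.5 s of data; rejects segments whose magnitude
    fluctuates by more than ``max_rel_std`` of the mean (not static).
    """
    if static_segment.n < 0.5 * static_segment.sampling_rate:
        raise ArgumentError("static segment must cover at least 0.5 s")
    mag = static_segment.magnitude()
    g_ref = float(mag.mean())
    if g_ref <= 0:
        raise CalibrationError("zero gravity magnitude in static segment")
    if mag.std() > max_rel_std * g_ref:
        raise NotStaticError(
            f"segment magnitude std {mag.std():.4g} exceeds "
            f"{max_rel_std:.0%} of mean {g_ref:.4g}"
        )
    return g_ref


def angle_from_accel(trace: AccelTrace, cutoff: float = 2.0) -> AngleTrace:
    """Joint angle theta = 90 deg - arccos(Ax / g) per sample.

    Ax is zero-phase low-pass filtered at ``cutoff`` Hz first; the arccos
    argument is clamped to [-1, 1] so noise at the trajectory endpoints
    (|Ax| slightly above g) cannot produce NaN.  Set ``cutoff=None`` to
    skip filtering.
    """
    if trace.g_ref is None or trace.g_ref <= 0:
        raise CalibrationError("g_ref not set; run calibrate_gravity first")
    ax = trace.ax
    if cutoff is not None:
        if cutoff >= trace.sampling_rate / 2.0:
            raise ArgumentError("cutoff must be below Nyquist")
        sos = signal.butter(4, cutoff, fs=trace.sampling_rate, output="sos")
        ax = signal.sosfiltfilt(sos, ax)
    arg = np.clip(ax / trace.g_ref, -1.0, 1.0)
    theta = 90.0 - np.degrees(np.arccos(arg))
    return AngleTrace(theta, trace.sampling_rate)


def angle_error(theta: AngleTrace, theta_ref: AngleTrace) -> float:
    """Mean absolute error between two angle traces, in degrees."""
    if theta.n != theta_ref.n:
        raise ArgumentError(
            f"length mismatch: {theta.n} vs {theta_ref.n}"
        )
    return float(np.mean(np.abs(theta.theta - theta_ref.theta)))
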