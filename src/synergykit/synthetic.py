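"""Synthetic multi-day sEMG + accelerometer sessions with known synergies.

Emulates a cyclic 0-90 deg elbow flexion/extension task recorded over
several days: envelope-level EMG is composed from the generative synergy
model D = diag(day_gains) (C + day offset) S + E, and the accelerometer
x-axis is the gravity projection g sin(theta) of the true joint angle.
Ground truth (C, S, angle, per-day gains) is attached to every recording
so every downstream stage — pure-variable selection, factorization,
order selection, angle regression, cross-day stability — can be tested
without real data.

Activation time courses are raised-cosine bursts phase-locked to the
movement cycle, one burst per synergy per cycle, with per-cycle amplitude
and phase jitter.  Bursts cover a fraction of the cycle so every synergy
has rest intervals in every cycle; those single-synergy-active samples
are exactly the pure variables SIMPLISMA needs.

The generator works at envelope level (the signal the factorization
consumes); it does not simulate motor-unit interference patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError
from .kinematics import AccelTrace
from .preprocess import EnvelopeMatrix

#: default task geometry: 3 muscles, 2 synergies, 30 flexion cycles per
#: set, 200 envelope samples per 4-s cycle (50 Hz envelope rate)
DEFAULT_CHANNELS = 3
DEFAULT_SYNERGIES = 2
DEFAULT_CYCLES = 30
DEFAULT_SAMPLES_PER_CYCLE = 200
DEFAULT_SAMPLING_RATE = 50.0
DEFAULT_NOISE_SIGMA = 0.05


@dataclass
class GroundTruth:
    """Generating quantities for one subject.

    day_gains[d-1] are the per-channel multiplicative gains of day d
    (day 1 is the unit reference); day_c_offsets[d-1] the mild additive
    synergy-matrix perturbation of day d (zero on day 1).  Both model
    electrode displacement and signal drift across days.
    """

    C_true: np.ndarray          # m x r, non-negative
    S_true: np.ndarray          # r x n, non-negative
    angle_true: np.ndarray      # n, degrees
    day_gains: np.ndarray       # n_days x m, strictly positive
    day_c_offsets: np.ndarray   # n_days x m x r
    noise_sigma: float
    n_cycles: int = DEFAULT_CYCLES
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    g_ref: float = 1.0

    def __post_init__(self):
        if np.any(self.C_true < 0) or np.any(self.S_true < 0):
            raise ArgumentError("C_true and S_true must be non-negative")
        if np.any(self.day_gains <= 0):
            raise ArgumentError("day_gains must be strictly positive")

    @property
    def m(self) -> int:
        return self.C_true.shape[0]

    @property
    def r(self) -> int:
        return self.C_true.shape[1]

    @property
    def n_days(self) -> int:
        return self.day_gains.shape[0]

    def effective_c(self, day: int) -> np.ndarray:
        """Day-specific synergy matrix (C plus that day's drift offset)."""
        self._check_day(day)
        return np.clip(self.C_true + self.day_c_offsets[day - 1], 0.0, None)

    def _check_day(self, day: int):
        if not 1 <= day <= self.n_days:
            raise ArgumentError(
                f"day {day} outside protocol range 1..{self.n_days}"
            )


@dataclass
class Recording:
    subject: int
    day: int
    set_index: int
    emg: EnvelopeMatrix
    accel: AccelTrace
    group: str
    truth: GroundTruth


@dataclass
class SessionSet:
    """Recordings grouped by subject/day/set with a shared sampling rate."""

    recordings: list[Recording]
    sampling_rate: float
    group_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.recordings:
            m0 = self.recordings[0].emg.m
            for rec in self.recordings:
                if rec.emg.m != m0:
                    raise ArgumentError("recordings differ in channel count")
                if rec.emg.sampling_rate != self.sampling_rate:
                    raise ArgumentError("recordings differ in sampling rate")
        if not self.group_labels:
            self.group_labels = sorted({r.group for r in self.recordings})

    def select(self, subject=None, day=None, set_index=None, group=None):
        out = self.recordings
        if subject is not None:
            out = [r for r in out if r.subject == subject]
        if day is not None:
            out = [r for r in out if r.day == day]
        if set_index is not None:
            out = [r for r in out if r.set_index == set_index]
        if group is not None:
            out = [r for r in out if r.group == group]
        return out

    @property
    def subjects(self) -> list[int]:
        return sorted({r.subject for r in self.recordings})

    @property
    def days(self) -> list[int]:
        return sorted({r.day for r in self.recordings})


def cycle_angle_profile(n_cycles: int, samples_per_cycle: int) -> np.ndarray:
    """True joint angle (degrees) of the cyclic flexion/extension task.

    theta(phase) = 45 (1 - cos 2*pi*phase): 0 deg at cycle start, 90 deg
    at mid-cycle (full flexion), back to 0 deg at cycle end.
    """
    phase = np.arange(n_cycles * samples_per_cycle) / samples_per_cycle
    return 45.0 * (1.0 - np.cos(2.0 * np.pi * phase))


def make_activation_profiles(
    n_cycles: int,
    samples_per_cycle: int,
    r: int,
    seed: int,
    amp_jitter: float = 0.10,
    phase_jitter: float = 0.01,
) -> np.ndarray:
    """Raised-cosine burst activation time courses, r x (n_cycles * spc).

    Synergy k bursts once per cycle around phase (k + 1/2)/r — for the
    default r=2 this puts one synergy at peak flexion velocity and one at
    peak extension velocity.  Burst width is 0.8/r of the cycle, so each
    synergy is silent for most of every cycle (rest phases guarantee pure
    variables).  Per-cycle amplitude jitter (lognormal-like, sd
    ``amp_jitter``) and phase jitter (sd ``phase_jitter`` cycles) emulate
    trial-to-trial variability.
    """
    if r < 1 or n_cycles < 1:
        raise ArgumentError("r and n_cycles must be positive")
    if samples_per_cycle < 20:
        raise ArgumentError("samples_per_cycle must be at least 20")
    rng = np.random.default_rng(seed)
    n = n_cycles * samples_per_cycle
    phase = np.arange(n) / samples_per_cycle  # in cycles, 0..n_cycles
    width = 0.8 / r
    S = np.zeros((r, n))
    for k in range(r):
        center = (k + 0.5) / r
        for c in range(n_cycles):
            amp = float(np.exp(amp_jitter * rng.standard_normal()))
            jit = float(phase_jitter * rng.standard_normal())
            # distance to this cycle's (jittered) burst center, in cycles
            d = phase - (c + center + jit)
            mask = np.abs(d) < width / 2.0
            S[k, mask] += amp * 0.5 * (
                1.0 + np.cos(2.0 * np.pi * d[mask] / width)
            )
    return S


def _default_synergy_matrix(m: int, r: int, rng: np.random.Generator):
    """Structured non-negative synergy matrix: each synergy dominated by
    a distinct channel, with smaller shared loads elsewhere."""
    C = 0.15 + 0.25 * rng.random((m, r))
    for k in range(r):
        dominant = round(k * (m - 1) / max(r - 1, 1)) if r > 1 else m // 2
        C[dominant, k] = 1.0
    return C


def make_ground_truth(
    n_channels: int = DEFAULT_CHANNELS,
    r: int = DEFAULT_SYNERGIES,
    n_cycles: int = DEFAULT_CYCLES,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
    n_days: int = 5,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
    amplitude_scale: float = 1.0,
    day_gain_sigma: float = 0.10,
    day_c_sigma: float = 0.05,
) -> GroundTruth:
    """Draw one subject's generating model.

    ``amplitude_scale`` multiplies the whole synergy matrix (the
    high/low-amplitude group contrast); ``day_gain_sigma`` is the sd of
    the log per-channel day gains; ``day_c_sigma`` scales the additive
    day drift of C relative to its maximum entry.  Day 1 is always the
    unperturbed reference.
    """
    rng = np.random.default_rng(seed)
    C = amplitude_scale * _default_synergy_matrix(n_channels, r, rng)
    S = make_activation_profiles(
        n_cycles, samples_per_cycle, r, seed=int(rng.integers(2**31))
    )
    angle = cycle_angle_profile(n_cycles, samples_per_cycle)
    day_gains = np.ones((n_days, n_channels))
    day_c_offsets = np.zeros((n_days, n_channels, r))
    for d in range(1, n_days):
        day_gains[d] = np.exp(day_gain_sigma * rng.standard_normal(n_channels))
        day_c_offsets[d] = (
            day_c_sigma * C.max() * rng.standard_normal((n_channels, r))
        )
    return GroundTruth(
        C_true=C,
        S_true=S,
        angle_true=angle,
        day_gains=day_gains,
        day_c_offsets=day_c_offsets,
        noise_sigma=noise_sigma,
        n_cycles=n_cycles,
        samples_per_cycle=samples_per_cycle,
        sampling_rate=sampling_rate,
    )


def synthesize_session(
    truth: GroundTruth, day: int, seed: int
) -> tuple[EnvelopeMatrix, AccelTrace]:
    """One recording of the given day: noisy EMG envelopes + accelerometer.

    EMG: D = diag(day_gains) C_day S + E with E zero-mean Gaussian of
    per-channel sd noise_sigma * RMS(channel), clipped so D stays
    non-negative.  Accelerometer: Ax = g sin(theta), Az = g cos(theta),
    Ay = 0, each plus Gaussian noise of sd noise_sigma * g truncated at
    3 sd (so |Ax| <= g (1 + 3 noise_sigma)).  The returned trace carries
    the generating gravity reference in ``g_ref``.
    """
    truth._check_day(day)
    rng = np.random.default_rng(seed)
    gains = truth.day_gains[day - 1]
    D_clean = gains[:, None] * (truth.effective_c(day) @ truth.S_true)
    if truth.noise_sigma > 0:
        rms = np.sqrt(np.mean(D_clean**2, axis=1, keepdims=True))
        E = truth.noise_sigma * rms * rng.standard_normal(D_clean.shape)
        D = np.clip(D_clean + E, 0.0, None)
    else:
        D = D_clean
    emg = EnvelopeMatrix(D, truth.sampling_rate)

    g = truth.g_ref
    theta = np.radians(truth.angle_true)
    clean = np.stack([g * np.sin(theta), np.zeros_like(theta), g * np.cos(theta)])
    if truth.noise_sigma > 0:
        lim = 3.0 * truth.noise_sigma * g
        noise = np.clip(
            truth.noise_sigma * g * rng.standard_normal(clean.shape), -lim, lim
        )
        clean = clean + noise
    accel = AccelTrace(
        clean[0], clean[1], clean[2], truth.sampling_rate, g_ref=g
    )
    return emg, accel


def make_protocol(
    n_subjects: int = 12,
    n_days: int = 5,
    seed: int = 0,
    group_split: float = 0.0,
    amplitude_ratio: float = 1.5,
    **truth_kwargs,
) -> SessionSet:
    """Full multi-subject, multi-day acquisition protocol.

    Day 1 contributes two sets per subject (train + same-day test); each
    later day one set.  ``group_split`` is the fraction of subjects in
    the high-amplitude group (label "high", synergy matrix scaled by
    ``amplitude_ratio``); 0 puts everyone in a single "low" group.
    Every set gets freshly jittered activation profiles (trial-to-trial
    variability) on top of the subject's fixed synergy matrix.
    """
    if n_subjects < 1 or n_days < 1:
        raise ArgumentError("n_subjects and n_days must be positive")
    if not 0.0 <= group_split <= 1.0:
        raise ArgumentError("group_split must be a fraction in [0, 1]")
    n_high = round(n_subjects * group_split)
    root = np.random.SeedSequence(seed)
    recordings = []
    sampling_rate = truth_kwargs.get("sampling_rate", DEFAULT_SAMPLING_RATE)
    for subj, subj_ss in enumerate(root.spawn(n_subjects), start=1):
        group = "high" if subj <= n_high else "low"
        scale = amplitude_ratio if group == "high" else 1.0
        seeds = subj_ss.generate_state(2 * n_days + 4) % (2**31)
        truth = make_ground_truth(
            n_days=n_days,
            seed=int(seeds[0]),
            amplitude_scale=scale,
            **truth_kwargs,
        )
        si = 0
        for day in range(1, n_days + 1):
            for set_index in range(1, 3 if day == 1 else 2):
                si += 1
                set_truth = GroundTruth(
                    C_true=truth.C_true,
                    S_true=make_activation_profiles(
                        truth.n_cycles,
                        truth.samples_per_cycle,
                        truth.r,
                        seed=int(seeds[si]),
                    ),
                    angle_true=truth.angle_true,
                    day_gains=truth.day_gains,
                    day_c_offsets=truth.day_c_offsets,
                    noise_sigma=truth.noise_sigma,
                    n_cycles=truth.n_cycles,
                    samples_per_cycle=truth.samples_per_cycle,
                    sampling_rate=truth.sampling_rate,
                    g_ref=truth.g_ref,
                )
                emg, accel = synthesize_session(
                    set_truth, day, seed=int(seeds[si + n_days + 1])
                )
                recordings.append(
                    Recording(subj, day, set_index, emg, accel, group, set_truth)
                )
    return SessionSet(recordings, sampling_rate)
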