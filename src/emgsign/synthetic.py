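"""Synthetic data: exact bilinear instances and multi-user EMG cohorts.

Two generators with different jobs:

* :func:`generate_bilinear_instance` draws random factors and composes an
  exactly bilinear stacked matrix (optionally plus i.i.d. Gaussian noise) —
  the verification workload for the fitting and adaptation algebra.
* :func:`generate_emg_cohort` synthesizes raw multi-channel EMG-like trials
  for a cohort of subjects so every pipeline stage (file I/O, windowed
  features, selection, factorization, cross-validation) runs without any
  recordings. Each motion is an archetype of per-channel piecewise-linear
  amplitude envelopes (sequential sub-gestures) modulating band-limited
  Gaussian noise; each subject distorts all of their trials with fixed
  user confounds: per-channel gains, cross-channel mixing, and a circular
  electrode-rotation shift. These confound families are deliberately the
  user-linear kind of structure a bilinear user factor can absorb; the
  generator emulates burst texture and inter-subject variation, not
  motor-unit physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bilinear import StackedMatrix, compose
from .io import EmgTrial, default_vocabulary

__all__ = [
    "BilinearGenConfig",
    "EmgCohortConfig",
    "MotionArchetype",
    "generate_bilinear_instance",
    "generate_emg_cohort",
]


@dataclass(frozen=True)
class BilinearGenConfig:
    """Dimensions, factor scale and noise level of an exact bilinear instance."""

    I: int = 6
    J: int = 120
    C: int = 8
    U: int = 19
    M: int = 20
    N: int = 10
    factor_scale: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("I", "J", "C", "U", "M", "N"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def dims(self) -> tuple[int, int, int, int, int, int]:
        return (self.I, self.J, self.C, self.U, self.M, self.N)


def generate_bilinear_instance(
    config: BilinearGenConfig,
) -> tuple[StackedMatrix, np.ndarray, StackedMatrix, np.ndarray]:
    """Draw standard-normal factors, compose Y, add entrywise noise.

    Returns (Y, Z_true, W_true, X_true); deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    s = config.factor_scale
    Z = s * rng.standard_normal((config.I, config.U))
    W = StackedMatrix(s * rng.standard_normal((config.I * config.C, config.J)), config.C)
    X = s * rng.standard_normal((config.J, config.M * config.N))
    Y = compose(Z, W, X)
    if config.noise_sd > 0:
        Y = StackedMatrix(
            Y.data + config.noise_sd * rng.standard_normal(Y.shape), config.C
        )
    return Y, Z, W, X


@dataclass(frozen=True)
class MotionArchetype:
    """Per-motion generative parameters: envelope breakpoints and band edges.

    ``envelopes`` is (n_channels, n_segments): segment amplitudes of the
    piecewise-linear activation envelope, modelling sequential sub-gestures.
    ``bands`` is (n_channels, 2): per-channel band-pass edges in Hz.
    """

    envelopes: np.ndarray
    bands: np.ndarray


@dataclass(frozen=True)
class EmgCohortConfig:
    """Cohort layout, motion archetypes and user-confound strengths.

    Defaults follow the recording protocol the pipeline is built around: 3 s
    trials at 200 Hz on 8 channels, 20 motions, 10 repetitions per motion.
    Confound strengths (fixed a priori as "strong" inter-subject variation):
    per-channel gains are lognormal with sigma ``gain_log_sd``; a fraction
    ``mixing_strength`` of each channel is replaced by a random mixture of all
    channels; the channel index is circularly rotated by up to
    ``max_rotation`` positions (armband placement shift). Trials are jittered
    in envelope timing and amplitude.
    """

    n_subjects: int = 20
    n_motions: int = 20
    n_trials: int = 10
    n_channels: int = 8
    sampling_rate_hz: float = 200.0
    duration_s: float = 3.0
    band_hz: tuple[float, float] = (20.0, 95.0)
    min_segments: int = 2
    max_segments: int = 4
    gain_log_sd: float = 0.4
    mixing_strength: float = 0.35
    max_rotation: int = 2
    amplitude_jitter: float = 0.15
    timing_jitter: float = 0.10
    noise_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_motions < 1 or self.n_trials < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if not 0 <= self.mixing_strength < 1:
            raise ValueError("mixing_strength must lie in [0, 1)")
        if self.gain_log_sd < 0 or self.max_rotation < 0:
            raise ValueError("confound parameters must be non-negative")
        if not 0 < self.band_hz[0] < self.band_hz[1] < self.sampling_rate_hz / 2:
            raise ValueError("band_hz must lie strictly inside (0, Nyquist)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class SubjectConfound:
    """One subject's fixed signal distortion: gains, mixing matrix, rotation."""

    gains: np.ndarray  # (n_channels,), positive
    mixing: np.ndarray  # (n_channels, n_channels), rows sum to 1
    rotation: int


def _draw_archetypes(config: EmgCohortConfig, rng: np.random.Generator) -> list[MotionArchetype]:
    archetypes = []
    low, high = config.band_hz
    for _ in range(config.n_motions):
        n_seg = int(rng.integers(config.min_segments, config.max_segments + 1))
        env = rng.uniform(0.2, 1.5, size=(config.n_channels, n_seg))
        # Sparsify: each motion activates a subset of channels strongly.
        active = rng.random(config.n_channels) < 0.7
        env[~active] *= 0.15
        centers = rng.uniform(low + 10, high - 10, size=config.n_channels)
        widths = rng.uniform(15, 40, size=config.n_channels)
        bands = np.stack(
            [np.maximum(low, centers - widths / 2), np.minimum(high, centers + widths / 2)],
            axis=1,
        )
        archetypes.append(MotionArchetype(env, bands))
    return _check_distinct(archetypes)


def _check_distinct(archetypes: list[MotionArchetype]) -> list[MotionArchetype]:
    keys = {(a.envelopes.tobytes(), a.bands.tobytes()) for a in archetypes}
    if len(keys) != len(archetypes):
        raise ValueError("duplicate motion archetypes; motions must be distinguishable")
    return archetypes


def _draw_confound(config: EmgCohortConfig, rng: np.random.Generator) -> SubjectConfound:
    ch = config.n_channels
    gains = np.exp(rng.normal(0.0, config.gain_log_sd, size=ch))
    raw = np.abs(rng.normal(0.0, 1.0, size=(ch, ch)))
    raw /= raw.sum(axis=1, keepdims=True)
    mixing = (1 - config.mixing_strength) * np.eye(ch) + config.mixing_strength * raw
    rotation = int(rng.integers(0, config.max_rotation + 1)) if config.max_rotation else 0
    return SubjectConfound(gains=gains, mixing=mixing, rotation=rotation)


def _piecewise_envelope(
    amplitudes: np.ndarray, n_samples: int, timing_jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Piecewise-linear envelope through jittered segment breakpoints."""
    n_seg = amplitudes.size
    knots = np.linspace(0, 1, n_seg + 1)
    if timing_jitter > 0 and n_seg > 1:
        inner = knots[1:-1] + rng.uniform(-timing_jitter, timing_jitter, n_seg - 1) / n_seg
        knots = np.concatenate([[0.0], np.sort(np.clip(inner, 0.01, 0.99)), [1.0]])
    # Envelope value at each knot: ramp up from/down to a low resting level.
    levels = np.concatenate([[0.1 * amplitudes[0]], amplitudes, [0.1 * amplitudes[-1]]])
    knot_pos = np.concatenate([[0.0], (knots[:-1] + knots[1:]) / 2, [1.0]])
    t = np.linspace(0, 1, n_samples)
    return np.interp(t, knot_pos, levels)


def generate_emg_cohort(
    config: EmgCohortConfig,
) -> tuple[list[EmgTrial], dict[str, SubjectConfound]]:
    """Generate a full cohort of raw synthetic EMG trials.

    Per trial: band-limited Gaussian noise per channel, amplitude-modulated by
    the motion archetype's jittered envelope, then the subject's confound is
    applied (rotation, mixing, gains) and a small sensor noise floor added.
    Deterministic given the config seed. Returns the trials (subject-major,
    motion-major, trial-minor order) and each subject's ground-truth confound.
    """
    rng = np.random.default_rng(config.seed)
    vocab = default_vocabulary()
    if config.n_motions <= len(vocab):
        labels = list(vocab)[: config.n_motions]
    else:
        labels = [f"M{i + 1}" for i in range(config.n_motions)]
    archetypes = _draw_archetypes(config, rng)
    subjects = [f"S{u + 1:02d}" for u in range(config.n_subjects)]
    confounds = {s: _draw_confound(config, rng) for s in subjects}

    fs = config.sampling_rate_hz
    n = config.n_samples
    sos_cache: dict[tuple[float, float], np.ndarray] = {}

    def bandpass(x: np.ndarray, band: tuple[float, float]) -> np.ndarray:
        key = (round(band[0], 3), round(band[1], 3))
        if key not in sos_cache:
            sos_cache[key] = sps.butter(4, key, btype="bandpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos_cache[key], x)

    trials: list[EmgTrial] = []
    for subject in subjects:
        conf = confounds[subject]
        for m, label in enumerate(labels):
            arch = archetypes[m]
            for t_idx in range(config.n_trials):
                sig = np.empty((n, config.n_channels))
                for ch in range(config.n_channels):
                    carrier = bandpass(rng.standard_normal(n), tuple(arch.bands[ch]))
                    scale = 1.0 + rng.uniform(-config.amplitude_jitter, config.amplitude_jitter)
                    env = _piecewise_envelope(
                        scale * arch.envelopes[ch], n, config.timing_jitter, rng
                    )
                    sig[:, ch] = env * carrier
                # Subject confounds: electrode rotation, cross-channel mixing, gains.
                sig = np.roll(sig, conf.rotation, axis=1)
                sig = sig @ conf.mixing.T
                sig = sig * conf.gains
                sig += config.noise_floor * rng.standard_normal(sig.shape)
                trials.append(
                    EmgTrial(
                        subject_id=subject,
                        motion_label=label,
                        trial_index=t_idx,
                        samples=sig,
                        sampling_rate_hz=fs,
                    )
                )
    return trials, confounds
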