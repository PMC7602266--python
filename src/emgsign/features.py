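"""Windowed time- and frequency-domain features of multi-channel surface EMG.

Five time-domain statistics (MAV, STD, RMS, LOG, AAC) are computed directly on
each sliding window of the raw signal; five frequency-domain statistics (MNF,
MDF, MNP, PSR, PKF) are computed on a Welch power-spectral-density estimate of
the same window. All ten are evaluated per channel.

Conventions that matter:

* STD uses the population normalization (1/N), so rms**2 == std**2 + mean**2
  holds exactly.
* LOG is the exponentiated mean log-magnitude; zero samples are floored at a
  configurable small value because the logarithm is otherwise undefined on
  idle (exactly-zero) EMG samples.
* MNP here is the frequency-weighted form sum(f*P)/sum(f). This is unusual —
  the common definition of mean power is sum(P)/N, exposed separately as
  :func:`mean_power_conventional` — but it is the form this pipeline is
  defined with, so it is the one wired into the feature registry.
* MDF is the smallest bin frequency at which cumulative power reaches half the
  total, with no interpolation between bins.
* PKF ties break toward the lowest frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "FEATURE_NAMES",
    "TIME_DOMAIN_FEATURES",
    "FREQUENCY_DOMAIN_FEATURES",
    "FeatureConfig",
    "PsdEstimate",
    "FeatureSeries",
    "mav",
    "std",
    "rms",
    "log_detector",
    "aac",
    "welch_psd",
    "mnf",
    "mdf",
    "mnp",
    "mean_power_conventional",
    "psr",
    "pkf",
    "extract_features",
    "n_windows",
]

TIME_DOMAIN_FEATURES = ("MAV", "STD", "RMS", "LOG", "AAC")
FREQUENCY_DOMAIN_FEATURES = ("MNF", "MDF", "MNP", "PSR", "PKF")
FEATURE_NAMES = TIME_DOMAIN_FEATURES + FREQUENCY_DOMAIN_FEATURES


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing, Welch-PSD and feature-set parameters.

    window_samples defaults to 600 (one 3 s trial at 200 Hz -> one window per
    trial); stride defaults to a quarter window. Welch uses 128-sample Hann
    segments with 50% overlap, giving ~1.56 Hz resolution at 200 Hz. The PSR
    half-band ``psr_epsilon_hz`` and analysis band ``psr_band`` parameterize
    the peak-power ratio; the peak interval is clipped to the band.
    """

    window_samples: int = 600
    stride_samples: int | None = None
    welch_segment: int = 128
    welch_overlap_fraction: float = 0.5
    welch_window: str = "hann"
    psr_epsilon_hz: float = 10.0
    psr_band: tuple[float, float] | None = None  # None -> (0, Nyquist)
    log_floor: float = 1e-12
    feature_set: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if self.welch_segment > self.window_samples:
            raise ValueError("welch_segment cannot exceed window_samples")
        if not 0 <= self.welch_overlap_fraction < 1:
            raise ValueError("welch_overlap_fraction must lie in [0, 1)")
        if self.psr_epsilon_hz <= 0:
            raise ValueError("psr_epsilon_hz must be positive")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.stride_samples is not None and self.stride_samples < 1:
            raise ValueError("stride_samples must be >= 1")
        unknown = set(self.feature_set) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}; valid: {FEATURE_NAMES}")
        if len(set(self.feature_set)) != len(self.feature_set):
            raise ValueError("feature_set contains duplicates")

    @property
    def stride(self) -> int:
        return self.stride_samples if self.stride_samples is not None else max(
            1, self.window_samples // 4
        )

    def with_features(self, names: Sequence[str]) -> "FeatureConfig":
        return replace(self, feature_set=tuple(names))


@dataclass(frozen=True)
class PsdEstimate:
    """A one-sided power spectral density: ascending frequencies and powers."""

    frequencies: np.ndarray
    powers: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.powers, dtype=float)
        if f.ndim != 1 or p.ndim != 1 or f.shape != p.shape:
            raise ValueError("frequencies and powers must be 1-D of equal length")
        if f.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f[0] < 0:
            raise ValueError("frequencies must be non-negative")
        if np.any(p < 0) or not np.isfinite(p).all():
            raise ValueError("powers must be finite and non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "powers", p)

    @property
    def total_power(self) -> float:
        return float(self.powers.sum())


@dataclass(frozen=True)
class FeatureSeries:
    """Per-trial feature values, shaped (n_windows, n_channels, n_features)."""

    subject_id: str
    motion_label: str
    trial_index: int
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be (n_windows, n_channels, n_features)")
        if v.shape[0] < 1:
            raise ValueError("need at least one window")
        if v.shape[2] != len(self.feature_names):
            raise ValueError("last axis must align with feature_names")
        if not np.isfinite(v).all():
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    return x


def mav(x) -> float:
    """Mean absolute value, (1/N) * sum |x_i|."""
    return float(np.mean(np.abs(_as_vector(x))))


def std(x) -> float:
    """Population standard deviation, sqrt((1/N) * sum (x_i - mean)^2)."""
    return float(np.std(_as_vector(x)))


def rms(x) -> float:
    """Root mean square, sqrt((1/N) * sum x_i^2)."""
    return float(np.sqrt(np.mean(_as_vector(x) ** 2)))


def log_detector(x, log_floor: float = 1e-12) -> float:
    """Exponentiated mean log-magnitude (geometric mean of |x|), floored.

    Estimates muscle contraction force; magnitudes below ``log_floor`` are
    clipped so idle (zero) samples stay finite.
    """
    x = _as_vector(x)
    return float(np.exp(np.mean(np.log(np.maximum(np.abs(x), log_floor)))))


def aac(x) -> float:
    """Average amplitude change, mean |x_{i+1} - x_i| over N-1 steps."""
    x = _as_vector(x)
    if x.size < 2:
        raise ValueError("AAC needs at least two samples")
    return float(np.mean(np.abs(np.diff(x))))


def welch_psd(x, sampling_rate_hz: float, config: FeatureConfig | None = None) -> PsdEstimate:
    """Welch averaged-periodogram PSD of one window (density scaling).

    Overlapping Hann-tapered segments, mean-averaged, no detrending (the
    pipeline applies no filtering to the raw signal either). The density
    scaling makes integrated power approximately Parseval-consistent with the
    signal variance.
    """
    config = config or FeatureConfig()
    x = _as_vector(x)
    if x.size < config.welch_segment:
        raise ValueError(
            f"window of {x.size} samples is shorter than welch_segment={config.welch_segment}"
        )
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    nperseg = config.welch_segment
    f, p = sps.welch(
        x,
        fs=sampling_rate_hz,
        window=config.welch_window,
        nperseg=nperseg,
        noverlap=int(round(config.welch_overlap_fraction * nperseg)),
        detrend=False,
        scaling="density",
        average="mean",
    )
    return PsdEstimate(f, np.maximum(p, 0.0))


def _check_nonzero(psd: PsdEstimate) -> None:
    if psd.total_power <= 0:
        raise ValueError("undefined for an all-zero spectrum")


def mnf(psd: PsdEstimate) -> float:
    """Mean (spectral-centroid) frequency, sum(f*P)/sum(P), in Hz."""
    _check_nonzero(psd)
    return float(np.dot(psd.frequencies, psd.powers) / psd.powers.sum())


def mdf(psd: PsdEstimate) -> float:
    """Median frequency: smallest bin where cumulative power reaches half the total."""
    _check_nonzero(psd)
    cum = np.cumsum(psd.powers)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(psd.frequencies[idx])


def mnp(psd: PsdEstimate) -> float:
    """Frequency-weighted mean power, sum(f*P)/sum(f).

    Note this pipeline-specific form differs from the conventional mean power
    sum(P)/N (see :func:`mean_power_conventional`). It scales with the square
    of the signal amplitude, like a power should, but weights high-frequency
    bins more heavily.
    """
    f_sum = psd.frequencies.sum()
    if f_sum <= 0:
        raise ValueError("MNP undefined when all bin frequencies are zero")
    return float(np.dot(psd.frequencies, psd.powers) / f_sum)


def mean_power_conventional(psd: PsdEstimate) -> float:
    """The literature's mean power, sum(P)/N_bins."""
    return float(psd.powers.mean())


def pkf(psd: PsdEstimate) -> float:
    """Peak frequency: frequency of the maximum-power bin (ties -> lowest)."""
    return float(psd.frequencies[int(np.argmax(psd.powers))])


def psr(psd: PsdEstimate, config: FeatureConfig | None = None, nyquist_hz: float | None = None) -> float:
    """Power spectrum ratio: power within +-epsilon of the peak over band power.

    The peak frequency f0 is the global PKF; the numerator sums bins with
    f in [f0 - eps, f0 + eps] intersected with the band [f1, f2]; the
    denominator sums bins in the band. Lies in (0, 1] when the peak is inside
    the band.
    """
    config = config or FeatureConfig()
    if config.psr_band is not None:
        f1, f2 = config.psr_band
    else:
        f1, f2 = 0.0, nyquist_hz if nyquist_hz is not None else float(psd.frequencies[-1])
    if not f1 < f2:
        raise ValueError("psr_band must satisfy f1 < f2")
    f, p = psd.frequencies, psd.powers
    band = (f >= f1) & (f <= f2)
    denom = float(p[band].sum())
    if denom <= 0:
        raise ValueError("PSR undefined: zero power in the analysis band")
    f0 = pkf(psd)
    eps = config.psr_epsilon_hz
    peak = band & (f >= f0 - eps) & (f <= f0 + eps)
    return float(p[peak].sum()) / denom


def n_windows(n_samples: int, window: int, stride: int) -> int:
    """Number of half-open sliding windows [start, start + window)."""
    if n_samples < window:
        raise ValueError(f"trial of {n_samples} samples is shorter than one window ({window})")
    return (n_samples - window) // stride + 1


def _window_features(
    x: np.ndarray, names: Sequence[str], config: FeatureConfig, fs: float
) -> list[float]:
    need_psd = any(name in FREQUENCY_DOMAIN_FEATURES for name in names)
    psd = welch_psd(x, fs, config) if need_psd else None
    out = []
    for name in names:
        if name == "MAV":
            out.append(mav(x))
        elif name == "STD":
            out.append(std(x))
        elif name == "RMS":
            out.append(rms(x))
        elif name == "LOG":
            out.append(log_detector(x, config.log_floor))
        elif name == "AAC":
            out.append(aac(x))
        elif name == "MNF":
            out.append(mnf(psd) if psd.total_power > 0 else 0.0)
        elif name == "MDF":
            out.append(mdf(psd) if psd.total_power > 0 else 0.0)
        elif name == "MNP":
            out.append(mnp(psd))
        elif name == "PSR":
            out.append(psr(psd, config, nyquist_hz=fs / 2) if psd.total_power > 0 else 0.0)
        elif name == "PKF":
            out.append(pkf(psd))
        else:  # pragma: no cover - guarded by FeatureConfig validation
            raise ValueError(f"unknown feature {name}")
    return out


def extract_features(trial, config: FeatureConfig | None = None) -> FeatureSeries:
    """Sliding-window, per-channel feature extraction for one trial.

    Windows are half-open sample ranges [start, start + window) advanced by
    the configured stride; for each window and channel the configured features
    are computed in configured order. An all-zero window yields 0 for the
    ratio-type spectral features (MNF/MDF/PSR) rather than an error, since
    idle segments are legitimate data.
    """
    config = config or FeatureConfig()
    samples = np.asarray(trial.samples, dtype=float)
    t, n_ch = samples.shape
    nw = n_windows(t, config.window_samples, config.stride)
    names = config.feature_set
    values = np.empty((nw, n_ch, len(names)))
    fs = trial.sampling_rate_hz
    for w in range(nw):
        start = w * config.stride
        win = samples[start : start + config.window_samples]
        for ch in range(n_ch):
            values[w, ch] = _window_features(win[:, ch], names, config, fs)
    return FeatureSeries(
        subject_id=trial.subject_id,
        motion_label=trial.motion_label,
        trial_index=trial.trial_index,
        values=values,
        feature_names=tuple(names),
    )
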