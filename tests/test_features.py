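"""Feature definitions checked against naive loop oracles and their algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsign import features as ft


# ---------------------------------------------------------------------------
# Independent loop oracles (no numpy vectorization)
# ---------------------------------------------------------------------------

def oracle_mav(x):
    return sum(abs(v) for v in x) / len(x)


def oracle_std(x):
    mu = sum(x) / len(x)
    return math.sqrt(sum((v - mu) ** 2 for v in x) / len(x))


def oracle_rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def oracle_log(x, floor=1e-12):
    return math.exp(sum(math.log(max(abs(v), floor)) for v in x) / len(x))


def oracle_aac(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1)


def oracle_mnf(f, p):
    return sum(fi * pi for fi, pi in zip(f, p)) / sum(p)


def oracle_mdf(f, p):
    total = sum(p)
    cum = 0.0
    for fi, pi in zip(f, p):
        cum += pi
        if cum >= 0.5 * total:
            return fi
    return f[-1]


def oracle_mnp(f, p):
    return sum(fi * pi for fi, pi in zip(f, p)) / sum(f)


def oracle_pkf(f, p):
    best, best_f = -1.0, f[0]
    for fi, pi in zip(f, p):
        if pi > best:
            best, best_f = pi, fi
    return best_f


def oracle_psr(f, p, eps, f1, f2):
    f0 = oracle_pkf(f, p)
    num = sum(pi for fi, pi in zip(f, p) if f1 <= fi <= f2 and f0 - eps <= fi <= f0 + eps)
    den = sum(pi for fi, pi in zip(f, p) if f1 <= fi <= f2)
    return num / den


TIME_CASES = [
    (ft.mav, oracle_mav),
    (ft.std, oracle_std),
    (ft.rms, oracle_rms),
    (ft.log_detector, oracle_log),
    (ft.aac, oracle_aac),
]


@pytest.mark.parametrize("fn,oracle", TIME_CASES, ids=[c[0].__name__ for c in TIME_CASES])
def test_time_domain_features_match_loop_oracle(fn, oracle):
    rng = np.random.default_rng(0)
    for _ in range(100):
        x = rng.standard_normal(600)
        assert fn(x) == pytest.approx(oracle(list(x)), rel=1e-10)


def test_spectral_features_match_loop_oracle(rng):
    cfg = ft.FeatureConfig()
    for _ in range(100):
        x = rng.standard_normal(600)
        psd = ft.welch_psd(x, 200.0, cfg)
        f, p = list(psd.frequencies), list(psd.powers)
        assert ft.mnf(psd) == pytest.approx(oracle_mnf(f, p), rel=1e-10)
        assert ft.mdf(psd) == pytest.approx(oracle_mdf(f, p), rel=1e-10)
        assert ft.mnp(psd) == pytest.approx(oracle_mnp(f, p), rel=1e-10)
        assert ft.pkf(psd) == pytest.approx(oracle_pkf(f, p), rel=1e-10)
        assert ft.psr(psd, cfg, nyquist_hz=100.0) == pytest.approx(
            oracle_psr(f, p, cfg.psr_epsilon_hz, 0.0, 100.0), rel=1e-10
        )


def test_time_domain_small_examples():
    assert ft.mav([1, -1, 2, -2]) == pytest.approx(1.5)
    assert ft.mav([3.0] * 5) == pytest.approx(3.0)
    assert ft.std([1.0, -1.0]) == pytest.approx(1.0)
    assert ft.std([4.0] * 10) == 0.0
    assert ft.rms([3.0, 4.0]) == pytest.approx(math.sqrt(12.5))
    assert ft.rms([-2.0] * 7) == pytest.approx(2.0)
    assert ft.log_detector([5.0, -5.0, 5.0]) == pytest.approx(5.0)
    assert math.isfinite(ft.log_detector([0.0, 1.0, 2.0]))
    assert ft.aac([0.0, 1.0, 0.0, 1.0]) == pytest.approx(1.0)
    assert ft.aac([2.5] * 4) == 0.0


def test_empty_or_too_short_windows_raise():
    with pytest.raises(ValueError):
        ft.mav([])
    with pytest.raises(ValueError):
        ft.std([])
    with pytest.raises(ValueError):
        ft.aac([1.0])


def _psd(f, p):
    return ft.PsdEstimate(np.asarray(f, float), np.asarray(p, float))


def test_spectral_small_examples():
    single = _psd([0, 10, 20, 30], [0, 0, 5.0, 0])
    assert ft.mnf(single) == pytest.approx(20.0)
    assert ft.mdf(single) == pytest.approx(20.0)
    assert ft.pkf(single) == pytest.approx(20.0)
    assert ft.psr(single) == pytest.approx(1.0)
    assert ft.mnp(single) == pytest.approx(20.0 * 5.0 / 60.0)
    two = _psd([0, 10, 30], [0, 2.0, 2.0])
    assert ft.mnf(two) == pytest.approx(20.0)
    # Ties on the peak go to the lowest frequency.
    assert ft.pkf(two) == pytest.approx(10.0)
    # Uniform powers: cumulative reaches 50% at the middle bin.
    uniform = _psd(list(range(10)), [1.0] * 10)
    assert ft.mdf(uniform) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        ft.mnf(_psd([0, 1], [0, 0]))
    with pytest.raises(ValueError):
        ft.mdf(_psd([0, 1], [0, 0]))
    with pytest.raises(ValueError):
        ft.mnp(_psd([0.0], [1.0]))


def test_psr_uniform_psd_counts_bins_near_peak():
    # 64 uniform bins at 1 Hz spacing; eps=2 Hz spans 5 bins around the peak
    # (which ties to the lowest frequency, so the band is clipped at 0).
    psd = _psd(list(range(64)), [1.0] * 64)
    cfg = ft.FeatureConfig(psr_epsilon_hz=2.0)
    assert ft.psr(psd, cfg, nyquist_hz=63.0) == pytest.approx(3 / 64)
    shifted = _psd(list(range(64)), [1.0] * 30 + [1.5] + [1.0] * 33)
    assert ft.psr(shifted, cfg, nyquist_hz=63.0) == pytest.approx(5.5 / 64.5)


def test_rms_std_mean_identity_and_feature_ordering(rng):
    for _ in range(50):
        x = rng.standard_normal(200) * rng.uniform(0.1, 10)
        assert ft.rms(x) ** 2 == pytest.approx(ft.std(x) ** 2 + np.mean(x) ** 2, rel=1e-10)
        # AM-GM / Cauchy-Schwarz ordering (no flooring for continuous noise)
        assert ft.log_detector(x) <= ft.mav(x) + 1e-12
        assert ft.mav(x) <= ft.rms(x) + 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.01, 100.0, allow_nan=False, allow_infinity=False),
)
def test_amplitude_scaling_behaviour(seed, scale):
    """Amplitude features scale linearly, spectral locations are invariant,
    and the frequency-weighted power scales quadratically."""
    x = np.random.default_rng(seed).standard_normal(600)
    cfg = ft.FeatureConfig()
    psd1 = ft.welch_psd(x, 200.0, cfg)
    psd2 = ft.welch_psd(scale * x, 200.0, cfg)
    for fn in (ft.mav, ft.std, ft.rms, ft.aac):
        assert fn(scale * x) == pytest.approx(scale * fn(x), rel=1e-9)
    assert ft.log_detector(scale * x) == pytest.approx(scale * ft.log_detector(x), rel=1e-6)
    assert ft.mnf(psd2) == pytest.approx(ft.mnf(psd1), rel=1e-9)
    assert ft.mdf(psd2) == ft.mdf(psd1)
    assert ft.pkf(psd2) == ft.pkf(psd1)
    assert ft.psr(psd2, cfg, 100.0) == pytest.approx(ft.psr(psd1, cfg, 100.0), rel=1e-9)
    assert ft.mnp(psd2) == pytest.approx(scale**2 * ft.mnp(psd1), rel=1e-9)


def test_welch_sinusoid_peak_and_parseval(rng):
    t = np.arange(600) / 200.0
    sine = np.sin(2 * np.pi * 25.0 * t)
    psd = ft.welch_psd(sine, 200.0)
    df = psd.frequencies[1] - psd.frequencies[0]
    assert abs(ft.pkf(psd) - 25.0) <= df
    # White noise: integrated density approximates the variance.
    ratios = []
    for seed in range(5):
        x = np.random.default_rng(seed).standard_normal(600)
        psd = ft.welch_psd(x, 200.0)
        # one-sided density already doubles the interior bins
        total = np.trapezoid(psd.powers, psd.frequencies)
        ratios.append(total / np.var(x))
    assert abs(np.mean(ratios) - 1.0) < 0.1
    zero = ft.welch_psd(np.zeros(600), 200.0)
    assert np.all(zero.powers == 0)


def test_welch_requires_segment_within_window():
    with pytest.raises(ValueError):
        ft.welch_psd(np.zeros(64), 200.0, ft.FeatureConfig(window_samples=128))
    with pytest.raises(ValueError):
        ft.FeatureConfig(window_samples=100, welch_segment=128)


class _Trial:
    def __init__(self, samples, fs=200.0):
        self.subject_id = "S01"
        self.motion_label = "M1"
        self.trial_index = 0
        self.samples = samples
        self.sampling_rate_hz = fs


def test_extract_features_window_counts(rng):
    cfg = ft.FeatureConfig(window_samples=600)
    fs = ft.extract_features(_Trial(rng.standard_normal((600, 8))), cfg)
    assert fs.values.shape == (1, 8, 10)
    cfg2 = ft.FeatureConfig(window_samples=600, stride_samples=150)
    fs2 = ft.extract_features(_Trial(rng.standard_normal((900, 8))), cfg2)
    assert fs2.values.shape[0] == 3
    with pytest.raises(ValueError):
        ft.extract_features(_Trial(rng.standard_normal((300, 8))), cfg)


def test_extract_features_channel_permutation_equivariance(rng):
    x = rng.standard_normal((600, 4))
    cfg = ft.FeatureConfig()
    base = ft.extract_features(_Trial(x), cfg).values
    perm = [2, 0, 3, 1]
    permuted = ft.extract_features(_Trial(x[:, perm]), cfg).values
    np.testing.assert_allclose(permuted, base[:, perm, :], rtol=1e-12)
    assert np.isfinite(base).all()


def test_feature_config_validation():
    with pytest.raises(ValueError):
        ft.FeatureConfig(feature_set=("RMS", "BOGUS"))
    with pytest.raises(ValueError):
        ft.FeatureConfig(window_samples=1)
    cfg = ft.FeatureConfig(feature_set=("RMS", "MDF"))
    assert cfg.with_features(("RMS",)).feature_set == ("RMS",)


def test_mean_power_conventional_differs_from_weighted_form():
    psd = _psd([0, 10, 20], [3.0, 0.0, 0.0])
    assert ft.mean_power_conventional(psd) == pytest.approx(1.0)
    assert ft.mnp(psd) == pytest.approx(0.0)
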