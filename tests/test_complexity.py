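"""Analytic signal, sample entropy (vs brute force), and the CMCI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmci.complexity import (
    SeConfig,
    analytic_signal,
    compute_cmci,
    imf_entropies,
    sample_entropy,
    sample_entropy_counts,
    total_complexity,
)

from conftest import make_time


def naive_counts(x, m, r):
    """Independent O(N^2) double-loop template-counting oracle."""
    x = np.asarray(x, float)
    nt = len(x) - m  # template count, shared by lengths m and m + 1
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


class TestAnalyticSignal:
    def test_pure_tone_has_unit_amplitude(self):
        t = make_time(3000)
        a = analytic_signal(np.cos(2 * np.pi * 2.0 * t))
        interior = slice(100, -100)
        assert np.max(np.abs(a.amplitude[interior] - 1.0)) < 0.01

    def test_pure_tone_instantaneous_frequency(self):
        t = make_time(3000)
        a = analytic_signal(np.cos(2 * np.pi * 2.0 * t))
        freq = a.instantaneous_frequency(sample_rate=100.0)
        interior = slice(100, -100)
        assert np.max(np.abs(freq[interior] - 2.0)) < 0.02

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(512)
        a = analytic_signal(x)
        scale = np.max(np.abs(x))
        assert np.max(np.abs(a.reconstruct() - x)) / scale < 1e-9

    def test_zero_input_convention(self):
        a = analytic_signal(np.zeros(64))
        assert not np.any(a.amplitude) and not np.any(a.phase)

    def test_phase_wrapped_to_half_open_interval(self):
        rng = np.random.default_rng(3)
        a = analytic_signal(rng.standard_normal(256))
        assert np.all(a.phase > -np.pi) and np.all(a.phase <= np.pi)


class TestSampleEntropy:
    def test_constant_series_is_maximally_regular(self):
        assert sample_entropy(np.full(50, 3.2)) == 0.0

    def test_alternating_series_matches_oracle(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        r = 0.2 * np.std(x)
        a, b = naive_counts(x, 2, r)
        assert sample_entropy_counts(x, 2, r) == (a, b)
        assert sample_entropy(x, 2, 0.2) == pytest.approx(-math.log(a / b))

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_match_bruteforce_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        x = rng.standard_normal(n)
        if seed % 3 == 0:
            x = np.round(x, 1)  # force ties/boundary cases
        r = 0.2 * np.std(x)
        assert sample_entropy_counts(x, 2, r) == naive_counts(x, 2, r)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000),
           st.floats(0.25, 4.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(150)
        se = sample_entropy(x)
        assert sample_entropy(a * x + b) == pytest.approx(se, abs=1e-12)

    def test_noise_more_entropic_than_tone(self):
        t = make_time(1000)
        tone = np.sin(2 * np.pi * 1.0 * t)
        se_tone = sample_entropy(tone)
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            wins += sample_entropy(rng.uniform(-1, 1, 1000)) > se_tone
        assert wins == 5

    def test_nan_when_no_matches(self):
        # strictly convex growth: no two templates within r at length m+1
        x = np.array([2.0**k for k in range(12)])
        se = sample_entropy(x, m=2, r_factor=0.001)
        assert math.isnan(se)


class TestImfEntropies:
    def test_constant_amplitude_tone_has_low_amplitude_entropy(self):
        t = make_time(3000)
        a = analytic_signal(np.cos(2 * np.pi * 2.0 * t))
        se_a, _ = imf_entropies(a)
        assert se_a < 0.05

    def test_amplitude_modulation_raises_amplitude_entropy(self):
        t = make_time(2000)
        carrier = np.cos(2 * np.pi * 5.0 * t)
        base = imf_entropies(analytic_signal(carrier))[0]
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            am = (1 + 0.5 * rng.standard_normal(t.size)) * carrier
            wins += imf_entropies(analytic_signal(am))[0] > base
        assert wins == 5

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        a = analytic_signal(rng.standard_normal(120))
        se_a, se_p = imf_entropies(a)
        for series, got in ((a.amplitude, se_a), (a.phase, se_p)):
            r = 0.2 * np.std(series)
            na, nb = naive_counts(series, 2, r)
            assert got == pytest.approx(-math.log(na / nb))


class TestTotalComplexity:
    def test_equal_weights_average(self):
        assert total_complexity(0.3, 0.5) == pytest.approx(0.4)

    def test_degenerate_weighting(self):
        assert total_complexity(0.3, 0.5, (1.0, 0.0)) == 0.3

    def test_zero_entropies(self):
        assert total_complexity(0.0, 0.0) == 0.0

    def test_undefined_propagates(self):
        assert math.isnan(total_complexity(float("nan"), 0.5))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            total_complexity(0.1, 0.2, (0.7, 0.7))


class TestCmci:
    def test_cmci_is_mean_of_total_complexities(self):
        rng = np.random.default_rng(4)
        res = compute_cmci(rng.standard_normal(1000), sample_rate=100)
        assert res.defined
        assert res.cmci == pytest.approx(np.mean(res.total_complexity),
                                         abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        t = make_time(2000)
        x = np.sin(2 * np.pi * 0.4 * t) + 0.3 * rng.standard_normal(2000)
        base = compute_cmci(x, sample_rate=100).cmci
        for a in (0.5, 2.0, 10.0):
            assert abs(compute_cmci(a * x, sample_rate=100).cmci - base) < 1e-6

    def test_noise_raises_complexity(self):
        t = make_time(2000)
        clean = np.sin(2 * np.pi * 0.4 * t) + 0.7 * np.sin(2 * np.pi * 2.1 * t)
        rng = np.random.default_rng(8)
        noise = rng.standard_normal(t.size)
        noise *= np.std(clean) / np.std(noise)  # SNR 0 dB
        assert (compute_cmci(clean, sample_rate=100).cmci
                < compute_cmci(clean + noise, sample_rate=100).cmci)

    def test_degenerate_input_gives_diagnostic(self):
        res = compute_cmci(np.linspace(0, 1, 200))
        assert not res.defined
        assert "no IMFs" in res.diagnostic

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        r1 = compute_cmci(x, sample_rate=100)
        r2 = compute_cmci(x, sample_rate=100)
        assert r1.cmci == r2.cmci
        assert r1.total_complexity == r2.total_complexity

    def test_phase_mode_ifreq_is_available(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(800)
        res = compute_cmci(x, se_config=SeConfig(phase_mode="ifreq"),
                           sample_rate=100)
        assert res.defined
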