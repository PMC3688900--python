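"""Filtering, spectra, periodicity, correlation and FDR against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from specseg.freq import (
    fdr_adjust,
    highpass,
    n_bins,
    periodicity_test,
    phase_difference,
    spearman_spt,
    spectrum,
)

N = 306
DT = 8.0
FS = 0.125


def cosine(k, phase_deg=0.0, amp=1.0, n=N):
    t = np.arange(n)
    return amp * np.cos(2 * np.pi * k * t / n + np.deg2rad(phase_deg))


class TestHighpass:
    def test_dc_rejected(self):
        out = highpass(np.full(N, 5.0))
        assert np.abs(out).max() < 1e-6

    def test_fundamental_preserved(self):
        x = cosine(36)
        out = highpass(x)
        amp = spectrum(out, DT).amplitude_at(36)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_passband_gain_above_twice_cutoff(self):
        # 0.0148 Hz ~ 2x cutoff: gain within 1 percent
        x = cosine(40)
        out = highpass(x)
        assert spectrum(out, DT).amplitude_at(40) == pytest.approx(1.0, rel=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(cosine(36), cutoff_hz=0.0625)


class TestSpectrum:
    def test_pure_tone_peak_and_zero_phase(self):
        res = spectrum(cosine(36), DT)
        assert res.peak_bin == 36
        assert res.peak_hz == pytest.approx(36 / (N * DT))
        assert res.amplitude_at(36) == pytest.approx(1.0)
        assert res.phase_at(36) == pytest.approx(0.0, abs=1e-9)

    def test_phase_of_shifted_cosine(self):
        res = spectrum(cosine(36, phase_deg=-56.5), DT)
        assert res.phase_at(36) == pytest.approx(-56.5, abs=1e-9)

    @pytest.mark.parametrize("phase", [-170.0, -56.5, 0.0, 40.1, 127.8])
    def test_noiseless_phase_recovery_below_one_degree(self, phase):
        res = spectrum(cosine(36, phase_deg=phase, amp=0.07), DT)
        assert abs(res.phase_at(36) - phase) < 1.0

    def test_parseval(self, rng):
        x = rng.standard_normal(N)
        coef = np.fft.rfft(x)
        power = np.abs(coef) ** 2
        total = (2 * power.sum() - power[0] - (power[-1] if N % 2 == 0 else 0)) / N
        assert total == pytest.approx(np.sum(x**2), rel=1e-10)

    def test_nyquist_amplitude_not_doubled(self):
        x = cosine(N // 2, amp=0.5)
        assert spectrum(x, DT).amplitude_at(N // 2) == pytest.approx(0.5)


class TestPeriodicity:
    def test_strong_cosine_reaches_minimal_p(self):
        p = periodicity_test(cosine(36), 36 / (N * DT), DT, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_white_noise_p_uniform(self):
        rng = np.random.default_rng(0)
        f = 36 / (N * DT)
        ps = [
            periodicity_test(rng.standard_normal(N), f, DT, n_perm=199, seed=s)
            for s in range(120)
        ]
        stat = stats.kstest(ps, "uniform")
        assert stat.pvalue > 0.005

    def test_off_grid_frequency_rejected(self):
        with pytest.raises(ValueError):
            periodicity_test(cosine(36), 0.0150, DT)

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            periodicity_test(cosine(36), 36 / (N * DT), DT, n_perm=50)


class TestNBins:
    def test_reference_band_gives_135(self):
        assert n_bins(0.0074, 0.0625, 306, 0.125) == 135

    def test_full_half_spectrum(self):
        assert n_bins(0.0, 0.0625, 306, 0.125) == 153

    @settings(max_examples=30, derandomize=True)
    @given(
        cut_bin=st.integers(1, 50),
        n_fft=st.sampled_from([128, 256, 306, 512]),
    )
    def test_matches_grid_enumeration(self, cut_bin, n_fft):
        """Count equals the number of grid bins in the open-closed band."""
        fs = 0.125
        # cutoff strictly between grid bins, away from the rounding midpoint
        cutoff = (cut_bin + 0.3) / (n_fft / fs)
        nyq = fs / 2
        grid = np.fft.rfftfreq(n_fft, 1 / fs)
        enumerated = int(np.sum((grid > cutoff) & (grid <= nyq)))
        assert n_bins(cutoff, nyq, n_fft, fs) == enumerated


class TestSpearman:
    def test_identical_series(self, rng):
        x = rng.standard_normal(34)
        r, _ = spearman_spt(x, x)
        assert r == pytest.approx(1.0)

    def test_reversed_ranks(self, rng):
        x = np.sort(rng.standard_normal(34))
        r, _ = spearman_spt(x, x[::-1])
        assert r == pytest.approx(-1.0)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 40))
    def test_matches_rank_difference_formula(self, seed, n):
        """Tie-free input: r equals 1 - 6*sum(d^2)/(n(n^2-1))."""
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
        r, _ = spearman_spt(x, y)
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            r, p = spearman_spt(np.ones(34), np.arange(34.0))
        assert np.isnan(r) and p == 1.0


def bh_stepup_oracle(p):
    """O(n^2) literal Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.array(
        [
            min(1.0, min(sorted_p[j] * n / (j + 1) for j in range(i, n)))
            for i in range(n)
        ]
    )
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestFDR:
    def test_single_p_unchanged(self):
        adj, _ = fdr_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_all_equal_p_unchanged(self):
        adj, _ = fdr_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 25))
    def test_matches_brute_force_stepup(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=n)
        adj, sig = fdr_adjust(p, q=0.05)
        assert np.allclose(adj, bh_stepup_oracle(p), atol=1e-12)
        assert np.array_equal(sig, adj < 0.05)

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=30))
        adj, _ = fdr_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestPhaseDifference:
    @pytest.mark.parametrize(
        "ic, spt, expected",
        [(-56.5, -69.3, 12.8), (127.8, -69.3, 197.1), (40.0, 40.0, 0.0)],
    )
    def test_published_pairs(self, ic, spt, expected):
        assert phase_difference(ic, spt) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(
        ic=st.floats(-179.99, 180.0),
        ref=st.floats(-179.99, 180.0),
    )
    def test_wrapped_into_circle(self, ic, ref):
        d = phase_difference(ic, ref)
        assert 0.0 <= d < 360.0
        assert np.isclose(np.cos(np.deg2rad(d)), np.cos(np.deg2rad(ic - ref)))
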