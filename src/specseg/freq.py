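"""Frequency-domain analysis of component time courses.

Implements the measurement side of the classification pipeline: zero-phase
Butterworth high-pass filtering, one-sided amplitude/phase spectra on the
session FFT grid, a rank-based permutation test for periodicity at a given
frequency, the tested-bin count, Spearman correlation against the stimulus
reference, Benjamini-Hochberg FDR adjustment, and the phase-difference
convention used in the component tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpectrumResult",
    "highpass",
    "spectrum",
    "periodicity_test",
    "n_bins",
    "spearman_spt",
    "fdr_adjust",
    "phase_difference",
]

#: lower cutoff of the high-pass filter, 1/(2 x 68 s) rounded to 4 decimals
DEFAULT_CUTOFF_HZ = 0.0074
#: Butterworth order (applied forward-backward, so effective order doubles)
FILTER_ORDER = 5


def highpass(
    tc: np.ndarray,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    sampling_hz: float = 0.125,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the last axis.

    Forward-backward application (``filtfilt``) removes the phase response;
    the DC component is rejected and the passband gain is within 1% above
    twice the cutoff.
    """
    nyq = sampling_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = signal.butter(order, cutoff_hz, btype="highpass", fs=sampling_hz)
    return signal.filtfilt(b, a, np.asarray(tc, dtype=float), axis=-1)


@dataclass
class SpectrumResult:
    """One-sided amplitude/phase spectrum of a component time course.

    ``amplitude`` is in unit-amplitude convention: a cosine of amplitude
    ``a`` at an interior grid frequency measures ``a`` (the DC and Nyquist
    bins carry no conjugate pair and are scaled accordingly).  ``peak_hz``
    is the frequency of maximal amplitude strictly above ``cutoff_hz``.
    """

    frequencies: np.ndarray
    amplitude: np.ndarray
    phase_deg: np.ndarray
    peak_hz: float
    peak_bin: int
    p_periodicity: float | None = None
    p_bonf: float | None = None

    def amplitude_at(self, k: int) -> float:
        return float(self.amplitude[k])

    def phase_at(self, k: int) -> float:
        return float(self.phase_deg[k])


def spectrum(
    tc: np.ndarray,
    acq_interval: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> SpectrumResult:
    """Amplitude and phase on the N-point one-sided FFT grid.

    Parseval's identity holds: ``sum(x**2)`` equals the scaled sum of
    squared spectral magnitudes.
    """
    x = np.asarray(tc, dtype=float)
    if x.size < 2:
        raise ValueError("time course must have at least 2 samples")
    n = x.size
    coef = np.fft.rfft(x)
    amp = 2.0 * np.abs(coef) / n
    amp[0] = np.abs(coef[0]) / n
    if n % 2 == 0:
        amp[-1] = np.abs(coef[-1]) / n
    phase = np.angle(coef, deg=True)
    freqs = np.fft.rfftfreq(n, acq_interval)
    band = freqs > cutoff_hz
    if not band.any():
        raise ValueError("no frequency bins above the cutoff")
    idx = np.flatnonzero(band)
    peak_bin = int(idx[np.argmax(amp[idx])])
    return SpectrumResult(
        frequencies=freqs,
        amplitude=amp,
        phase_deg=phase,
        peak_hz=float(freqs[peak_bin]),
        peak_bin=peak_bin,
    )


def periodicity_test(
    tc: np.ndarray,
    f: float,
    acq_interval: float,
    n_perm: int = 999,
    seed: int = 0,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> float:
    """Permutation p-value for a periodic component at frequency ``f``.

    The statistic is a Fisher-g-type ratio computed on the rank-transformed
    series: spectral power at the tested bin divided by the total power in
    the tested band (above the high-pass cutoff, up to Nyquist).  The rank
    transform provides robustness to heavy tails and outliers; the null is
    formed by random permutations of the ranks, which preserve the marginal
    distribution while destroying all serial structure, giving exact
    finite-sample control.  The smallest attainable p is 1/(n_perm+1).
    """
    x = np.asarray(tc, dtype=float)
    n = x.size
    freqs = np.fft.rfftfreq(n, acq_interval)
    k = int(round(f * n * acq_interval))
    # accept grid frequencies up to printing precision (5 decimals)
    if k >= freqs.size or not np.isclose(freqs[k], f, atol=0.5e-5):
        raise ValueError(f"frequency {f} Hz does not lie on the FFT grid")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    band = np.flatnonzero(freqs > cutoff_hz)

    def g_stat(series: np.ndarray) -> float:
        power = np.abs(np.fft.rfft(series)) ** 2
        total = power[band].sum()
        return power[k] / total if total > 0 else 0.0

    ranks = stats.rankdata(x)
    ranks = (ranks - ranks.mean()) / ranks.std()
    observed = g_stat(ranks)
    rng = np.random.default_rng(seed)
    # permutation spectra in one batched FFT
    perms = np.array([rng.permutation(ranks) for _ in range(n_perm)])
    power = np.abs(np.fft.rfft(perms, axis=-1)) ** 2
    g_null = power[:, k] / power[:, band].sum(axis=-1)
    exceed = int(np.sum(g_null >= observed))
    return (1 + exceed) / (n_perm + 1)


def n_bins(
    cutoff_hz: float, nyquist_hz: float, n_fft: int, sampling_hz: float
) -> int:
    """Number of tested frequency bins between the cutoff and Nyquist.

    Computed as the tested frequency range times the number of FFT points
    divided by the sampling rate; for (0.0074, 0.0625, 306, 0.125) this is
    135.
    """
    if nyquist_hz <= cutoff_hz:
        raise ValueError("Nyquist frequency must exceed the cutoff")
    return int(round((nyquist_hz - cutoff_hz) * n_fft / sampling_hz))


def spearman_spt(tc_run_avg: np.ndarray, spt_run: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of a run-averaged time course with the SPT.

    Returns ``(r, p)``; a constant input has undefined rank correlation and
    yields ``(nan, 1.0)`` with a warning.
    """
    x = np.asarray(tc_run_avg, dtype=float)
    y = np.asarray(spt_run, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: Spearman correlation undefined")
        return float("nan"), 1.0
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, significant)`` where ``adjusted`` are monotone
    BH-adjusted p-values and ``significant`` the mask at level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def phase_difference(ic_phase_deg: float, spt_phase_deg: float) -> float:
    """Component phase minus SPT phase, wrapped into [0, 360) degrees.

    A component in phase with the stimulus reports ~0; an anti-phase
    (deactivated) component reports ~180.
    """
    d = float((ic_phase_deg - spt_phase_deg) % 360.0)
    # float modulo can return exactly 360.0 for tiny negative inputs
    return 0.0 if d >= 360.0 else d
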