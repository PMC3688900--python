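"""Reference emulation of the auditory sparse-sampling study conditions.

The original subject data are not deposited, so the group-level component
table cannot be recomputed from recordings.  What CAN be recomputed is the
behaviour of the classifier under the study conditions: this module plants
the 16 grey-matter component time courses with the published per-component
stimulus-bin frequency, spectral amplitude, phase offset from the stimulus
reference, and Spearman correlation, runs the full frequency-domain
classification, and counts the labels.

Generator model per component (subject-averaged session time course):

* a cosine at the component's stimulus-grid bin with the published
  amplitude, phased relative to the generated SPT reference by the
  published phase difference (absolute spectral phase depends on the HRF
  convention and is not recoverable; phase differences are);
* a run-periodic multi-tone background on the in-band run-harmonic bins
  (random phases; stimulus bins, the component's own bin and the Nyquist
  bin excluded), orthogonalised to the SPT run average within its own
  frequency subspace, with its scale solved by bisection so the measured
  run-averaged Spearman r equals the published value.  The scale is capped
  so the largest background bin stays below 0.8x the planted amplitude,
  keeping the published spectral-peak location (a categorical study
  condition) intact.

The run-periodic background reflects the study's own observation that
component behaviour repeats systematically from run to run: it survives
run-averaging exactly as the published averaged-time-course SDs require,
which white or 1/f noise cannot do without burying the listed peaks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_components
from .design import AcquisitionDesign, SPTWaveform, build_spt
from .freq import DEFAULT_CUTOFF_HZ

__all__ = [
    "ReferenceComponent",
    "GM_COMPONENTS",
    "reference_design",
    "generate_reference_timecourses",
    "classify_reference_set",
    "label_counts",
    "modal_label_counts",
]


@dataclass(frozen=True)
class ReferenceComponent:
    """Published per-component parameters of the grey-matter set."""

    ic_id: str
    label: str
    r_spt: float | None
    f_hz: float
    ampl: float
    phase_diff_deg: float | None


#: The 16 grey-matter components: stimulus-bin frequency, spectral
#: amplitude at that bin, phase difference from the stimulus reference, and
#: run-averaged Spearman correlation with it.  Unrelated components have no
#: published amplitude/phase; they are planted at their off-stimulus bins
#: with a mid-range amplitude and random phase.
GM_COMPONENTS: tuple[ReferenceComponent, ...] = (
    ReferenceComponent("21", "stimulus-activated", 0.79, 0.01471, 0.145, 12.8),
    ReferenceComponent("32", "stimulus-activated", 0.82, 0.01471, 0.076, 29.1),
    ReferenceComponent("4", "stimulus-activated", 0.42, 0.01471, 0.028, 62.9),
    ReferenceComponent("15", "stimulus-deactivated", -0.87, 0.01471, 0.070, 197.1),
    ReferenceComponent("33", "stimulus-deactivated", -0.78, 0.01471, 0.062, 198.7),
    ReferenceComponent("37", "stimulus-deactivated", -0.70, 0.01471, 0.064, 158.1),
    ReferenceComponent("28", "stimulus-deactivated", -0.58, 0.01471, 0.048, 210.2),
    ReferenceComponent("22", "stimulus-deactivated", -0.54, 0.01471, 0.046, 145.7),
    ReferenceComponent("18", "stimulus-deactivated", -0.49, 0.01471, 0.045, 162.1),
    ReferenceComponent("10", "stimulus-deactivated", -0.47, 0.01471, 0.037, 158.7),
    ReferenceComponent("27", "stimulus-deactivated", -0.45, 0.01471, 0.054, 155.8),
    ReferenceComponent("31", "stimulus-deactivated", -0.45, 0.01471, 0.061, 149.1),
    ReferenceComponent("38", "stimulus-neutral", -0.07, 0.02941, 0.040, 139.7),
    ReferenceComponent("26", "stimulus-neutral", -0.08, 0.01471, 0.075, 109.5),
    ReferenceComponent("19", "stimulus-unrelated", None, 0.03309, 0.080, None),
    ReferenceComponent("25", "stimulus-unrelated", None, 0.04044, 0.080, None),
)

#: headroom between the largest background bin and the planted amplitude
PEAK_HEADROOM = 0.8


def reference_design(seed: int = 0) -> AcquisitionDesign:
    """The study's acquisition design with a seeded jitter draw."""
    return AcquisitionDesign.jittered(seed)


def _run_harmonic_bins(design: AcquisitionDesign, cutoff_hz: float) -> list[int]:
    """In-band session bins of run-periodic content (excluding Nyquist)."""
    n = design.total_volumes
    step = design.n_runs
    bins = []
    for k in range(step, n // 2, step):
        if k / (n * design.acq_interval) > cutoff_hz:
            bins.append(k)
    return bins


def _unit_background(
    rng: np.random.Generator,
    design: AcquisitionDesign,
    spt_run: np.ndarray,
    exclude: set[int],
    cutoff_hz: float,
) -> np.ndarray:
    """Unit-SD run-periodic background, orthogonal to the SPT run average.

    Random-phase tones on the in-band run-harmonic bins (minus the excluded
    session bins), built as one run template and tiled; the projection of
    the SPT run average onto the background's own bins is removed, so the
    background correlates exactly zero (linearly) with the reference
    without touching the excluded bins.
    """
    m = design.volumes_per_run
    run_bins = [
        k // design.n_runs
        for k in _run_harmonic_bins(design, cutoff_hz)
        if k not in exclude
    ]
    coef = np.zeros(m // 2 + 1, dtype=complex)
    for rb in run_bins:
        coef[rb] = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi))
    bg = np.fft.irfft(coef, m)
    spt_coef = np.fft.rfft(spt_run)
    proj = np.zeros_like(coef)
    for rb in run_bins:
        proj[rb] = spt_coef[rb]
    spt_in_span = np.fft.irfft(proj, m)
    denom = spt_in_span @ spt_in_span
    if denom > 1e-12:
        bg = bg - (bg @ spt_in_span) / denom * spt_in_span
    bg = bg - bg.mean()
    bg = bg / bg.std()
    return np.tile(bg, design.n_runs)


def _max_bin_amplitude(x: np.ndarray) -> float:
    n = x.size
    amp = 2.0 * np.abs(np.fft.rfft(x)) / n
    amp[0] = 0.0
    if n % 2 == 0:
        amp[-1] *= 0.5
    return float(amp.max())


def _calibrate_scale(
    sig: np.ndarray,
    bg: np.ndarray,
    spt_run: np.ndarray,
    design: AcquisitionDesign,
    target_r: float,
    cap: float,
    iters: int = 40,
) -> float:
    """Bisect the background scale so |Spearman r| matches |target_r|."""

    def measured(scale: float) -> float:
        tc = sig + scale * bg
        run_avg = tc.reshape(design.n_runs, design.volumes_per_run).mean(axis=0)
        return abs(stats.spearmanr(run_avg, spt_run)[0])

    target = abs(target_r)
    if measured(0.0) <= target:
        return 0.0
    if measured(cap) >= target:
        return cap
    lo, hi = 0.0, cap
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if measured(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_reference_timecourses(
    seed: int,
    design: AcquisitionDesign | None = None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    components: tuple[ReferenceComponent, ...] = GM_COMPONENTS,
) -> tuple[dict[str, np.ndarray], SPTWaveform, AcquisitionDesign]:
    """Planted time courses for the grey-matter component set.

    Returns ``(timecourses, spt, design)``; the SPT is built from the same
    jittered design, and every planted phase is anchored to the measured
    SPT phase at the component's bin.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = AcquisitionDesign.jittered(int(rng.integers(2**31)))
    spt = build_spt(design)
    spt_run = spt.run_average()
    n = design.total_volumes
    t = np.arange(n)
    out: dict[str, np.ndarray] = {}
    for comp in components:
        k = int(round(comp.f_hz * n * design.acq_interval))
        if comp.phase_diff_deg is not None:
            phase = np.deg2rad(spt.phase_at_bin(k) + comp.phase_diff_deg)
        else:
            phase = rng.uniform(0.0, 2.0 * np.pi)
        sig = comp.ampl * np.cos(2.0 * np.pi * k * t / n + phase)
        exclude = {design.fundamental_bin, design.harmonic2_bin, k}
        bg = _unit_background(rng, design, spt_run, exclude, cutoff_hz)
        cap = PEAK_HEADROOM * comp.ampl / _max_bin_amplitude(bg)
        if comp.r_spt is None:
            scale = min(comp.ampl, cap)
        else:
            scale = _calibrate_scale(sig, bg, spt_run, design, comp.r_spt, cap)
        out[comp.ic_id] = sig + scale * bg
    return out, spt, design


def classify_reference_set(
    seed: int,
    q_level: float = 0.05,
    n_perm: int = 199,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> pd.DataFrame:
    """Generate the reference set for one seed and classify it."""
    tcs, spt, design = generate_reference_timecourses(seed, cutoff_hz=cutoff_hz)
    gm = {ic: True for ic in tcs}
    return classify_components(
        tcs, gm, design, spt, q_level=q_level, cutoff_hz=cutoff_hz,
        n_perm=n_perm, seed=seed,
    )


def label_counts(seeds, q_level: float = 0.05, n_perm: int = 199) -> pd.DataFrame:
    """Per-seed label counts of the reference classification."""
    rows = []
    for s in seeds:
        table = classify_reference_set(int(s), q_level=q_level, n_perm=n_perm)
        counts = Counter(table["label"])
        rows.append(
            {
                "seed": int(s),
                "stimulus-activated": counts.get("stimulus-activated", 0),
                "stimulus-deactivated": counts.get("stimulus-deactivated", 0),
                "stimulus-neutral": counts.get("stimulus-neutral", 0),
                "stimulus-unrelated": counts.get("stimulus-unrelated", 0),
            }
        )
    return pd.DataFrame(rows).set_index("seed")


def modal_label_counts(counts: pd.DataFrame) -> dict[str, int]:
    """Most frequent per-label count across seeds."""
    return {
        col: int(counts[col].mode().iloc[0])
        for col in counts.columns
    }
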