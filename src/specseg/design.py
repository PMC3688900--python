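"""Sparse-acquisition block paradigm and the stimulus-timing reference waveform.

The experiment modelled here is a sparse-sampling block design: single
volumes are acquired every ``acq_interval`` seconds (long enough that
scanner noise does not overlap stimulus presentation), while the stimulus
alternates between fixed-length on-blocks and jittered off-blocks.  The
stimulus presentation timing (SPT) waveform is the on/off boxcar convolved
with a canonical hemodynamic response function (HRF) and subsampled at the
acquisition times; its spectral anchors (fundamental stimulus frequency and
second harmonic on the FFT grid of the session) drive all downstream
frequency-domain classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats

__all__ = [
    "AcquisitionDesign",
    "HRFParams",
    "SPTWaveform",
    "build_boxcar",
    "build_spt",
    "double_gamma_hrf",
    "fundamental_frequency",
    "second_harmonic_frequency",
    "phase_to_seconds",
    "load_design",
    "save_design",
    "save_spt",
]

#: fine time grid for boxcar construction and HRF convolution (seconds).
FINE_DT = 0.1


@dataclass(frozen=True)
class AcquisitionDesign:
    """Timing of one sparse-sampling session.

    Parameters follow the study design this package emulates: 9 runs of 34
    acquisitions at 8 s intervals (306 volumes), stimulus on for 32 s and
    off for 30-36 s, four on/off cycles per run, with the stimulus onset of
    each run delayed by 0, 4 or 6 s relative to the first acquisition.

    ``off_durations[r][c]`` is the off-block after cycle ``c`` of run ``r``.
    Use :meth:`jittered` for a seeded random draw of the off-durations, or
    the default constructor for a strictly periodic design.
    """

    n_runs: int = 9
    volumes_per_run: int = 34
    acq_interval: float = 8.0
    on_duration: float = 32.0
    cycles_per_run: int = 4
    onset_delays: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    off_durations: tuple[tuple[float, ...], ...] = field(default=None)  # type: ignore[assignment]

    #: admissible off-block durations (seconds)
    OFF_RANGE = (30.0, 36.0)
    OFF_CHOICES = (30.0, 32.0, 34.0, 36.0)
    DELAY_CYCLE = (0.0, 4.0, 6.0)

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.volumes_per_run < 1:
            raise ValueError("n_runs and volumes_per_run must be positive")
        if self.acq_interval <= 0:
            raise ValueError("acq_interval must be positive")
        if self.on_duration < 0:
            raise ValueError("on_duration must be non-negative")
        if self.onset_delays is None:
            delays = tuple(
                self.DELAY_CYCLE[r % len(self.DELAY_CYCLE)] for r in range(self.n_runs)
            )
            object.__setattr__(self, "onset_delays", delays)
        if self.off_durations is None:
            offs = tuple(
                tuple(34.0 for _ in range(self.cycles_per_run))
                for _ in range(self.n_runs)
            )
            object.__setattr__(self, "off_durations", offs)
        if len(self.onset_delays) != self.n_runs:
            raise ValueError("need one onset delay per run")
        if len(self.off_durations) != self.n_runs or any(
            len(run) != self.cycles_per_run for run in self.off_durations
        ):
            raise ValueError("need one off-duration per cycle per run")
        lo, hi = self.OFF_RANGE
        for run in self.off_durations:
            for off in run:
                if not lo <= off <= hi:
                    raise ValueError(f"off duration {off} outside [{lo}, {hi}] s")

    @classmethod
    def jittered(cls, seed: int, **kwargs) -> "AcquisitionDesign":
        """Design with off-durations drawn uniformly from {30, 32, 34, 36} s."""
        proto = cls(**kwargs)
        rng = np.random.default_rng(seed)
        offs = tuple(
            tuple(rng.choice(cls.OFF_CHOICES) for _ in range(proto.cycles_per_run))
            for _ in range(proto.n_runs)
        )
        return replace(proto, off_durations=offs)

    # -- derived quantities -------------------------------------------------
    @property
    def total_volumes(self) -> int:
        return self.n_runs * self.volumes_per_run

    @property
    def run_duration(self) -> float:
        """Run length in seconds (volumes x acquisition interval)."""
        return self.volumes_per_run * self.acq_interval

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.acq_interval

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.acq_interval

    def frequency_grid(self, n_fft: int | None = None) -> np.ndarray:
        """One-sided FFT frequency grid of the concatenated session."""
        n = self.total_volumes if n_fft is None else n_fft
        return np.fft.rfftfreq(n, self.acq_interval)

    @property
    def fundamental_bin(self) -> int:
        """FFT bin of the stimulus cycling rate on the full-session grid."""
        return int(round(self.cycles_per_run * self.n_runs))

    @property
    def harmonic2_bin(self) -> int:
        return 2 * self.fundamental_bin


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF (SPM convention).

    ``peak_delay`` / ``undershoot_delay`` are the gamma shape parameters at
    unit scale, i.e. the response peaks near 5 s and the undershoot near
    15 s; ``ratio`` scales the undershoot relative to the peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    ratio: float = 6.0
    duration: float = 32.0


def double_gamma_hrf(params: HRFParams | None = None, dt: float = FINE_DT) -> np.ndarray:
    """Sampled canonical HRF on a ``dt`` grid, normalised to unit peak."""
    p = params or HRFParams()
    t = np.arange(0.0, p.duration, dt)
    h = _stats.gamma.pdf(t, p.peak_delay) - _stats.gamma.pdf(t, p.undershoot_delay) / p.ratio
    return h / h.max()


def build_boxcar(
    design: AcquisitionDesign, run_index: int, dt: float = FINE_DT
) -> np.ndarray:
    """Fine-grained on/off indicator for one run.

    The indicator is 1 during each on-block and 0 otherwise; the first
    on-block starts at the run's onset delay, and off-blocks (including any
    dead time at the end of the run) are 0.
    """
    if not 0 <= run_index < design.n_runs:
        raise IndexError(f"run_index {run_index} out of range [0, {design.n_runs})")
    if not np.isclose(round(design.acq_interval / dt) * dt, design.acq_interval):
        raise ValueError("fine resolution dt must divide the acquisition interval")
    n = int(round(design.run_duration / dt))
    box = np.zeros(n)
    t = design.onset_delays[run_index]
    for off in design.off_durations[run_index]:
        i0 = int(round(t / dt))
        i1 = int(round((t + design.on_duration) / dt))
        if i0 < n:
            box[i0 : min(i1, n)] = 1.0
        t += design.on_duration + off
    return box


@dataclass(frozen=True)
class SPTWaveform:
    """Stimulus presentation timing reference, sampled at acquisition times.

    ``samples`` is the HRF-convolved boxcar subsampled at the acquisition
    interval, z-scored per run and concatenated across runs.  ``phase_deg``
    is the FFT phase of ``samples`` at the fundamental bin, in the
    cosine convention ``x(t) = A cos(2 pi f t + phase)``.
    """

    samples: np.ndarray
    fundamental_hz: float
    harmonic2_hz: float
    phase_deg: float
    acq_interval: float
    n_runs: int

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def volumes_per_run(self) -> int:
        return self.n // self.n_runs

    @property
    def fundamental_bin(self) -> int:
        return int(round(self.fundamental_hz * self.n * self.acq_interval))

    @property
    def harmonic2_bin(self) -> int:
        return int(round(self.harmonic2_hz * self.n * self.acq_interval))

    def run_average(self) -> np.ndarray:
        """Average over runs (one run's worth of samples)."""
        return self.samples.reshape(self.n_runs, -1).mean(axis=0)

    def phase_at_bin(self, k: int) -> float:
        """FFT phase (degrees, in (-180, 180]) of the reference at bin ``k``."""
        coef = np.fft.rfft(self.samples)[k]
        return float(np.angle(coef, deg=True))


def build_spt(
    design: AcquisitionDesign,
    hrf_params: HRFParams | None = None,
    dt: float = FINE_DT,
) -> SPTWaveform:
    """Build the SPT reference: per-run boxcar * HRF, subsampled at 8 s.

    Each run's boxcar is convolved with the canonical HRF on the fine grid,
    sampled at the acquisition times, z-scored within the run, and the runs
    are concatenated.
    """
    h = double_gamma_hrf(hrf_params, dt)
    step = int(round(design.acq_interval / dt))
    runs = []
    for r in range(design.n_runs):
        box = build_boxcar(design, r, dt)
        conv = np.convolve(box, h)[: box.size]
        samp = conv[::step][: design.volumes_per_run]
        sd = samp.std()
        if sd > 0:
            samp = (samp - samp.mean()) / sd
        runs.append(samp)
    samples = np.concatenate(runs)
    f1 = fundamental_frequency(design)
    f2 = second_harmonic_frequency(design)
    k1 = design.fundamental_bin
    phase = float(np.angle(np.fft.rfft(samples)[k1], deg=True))
    return SPTWaveform(
        samples=samples,
        fundamental_hz=f1,
        harmonic2_hz=f2,
        phase_deg=phase,
        acq_interval=design.acq_interval,
        n_runs=design.n_runs,
    )


def fundamental_frequency(design: AcquisitionDesign, n_fft: int | None = None) -> float:
    """Stimulus cycling rate on the session FFT grid, rounded to 5 decimals.

    The returned value is ``k / (n_fft * acq_interval)`` for the integer bin
    ``k`` nearest ``cycles_per_run / run_duration``; for the reference
    design (306 volumes, 8 s, 4 cycles per 272 s run) this is 0.01471 Hz.
    """
    if design.cycles_per_run < 1:
        raise ValueError("design has no stimulus cycles")
    n = design.total_volumes if n_fft is None else n_fft
    if n != design.total_volumes:
        raise ValueError("n_fft must equal the total number of volumes")
    target = design.cycles_per_run / design.run_duration
    k = int(round(target * n * design.acq_interval))
    return round(k / (n * design.acq_interval), 5)


def second_harmonic_frequency(design: AcquisitionDesign) -> float:
    """Grid frequency of twice the stimulus cycling rate (5 decimals)."""
    n = design.total_volumes
    return round(design.harmonic2_bin / (n * design.acq_interval), 5)


def phase_to_seconds(phase_deg: float, cycle_duration: float) -> float:
    """Convert a phase lag in degrees to seconds of one stimulus cycle."""
    return phase_deg / 360.0 * cycle_duration


# -- flat config / TSV I/O --------------------------------------------------

def save_design(design: AcquisitionDesign, path) -> None:
    """Write the design as a flat ``key = value`` config file."""
    lines = [
        f"n_runs = {design.n_runs}",
        f"volumes_per_run = {design.volumes_per_run}",
        f"acq_interval = {design.acq_interval}",
        f"on_duration = {design.on_duration}",
        f"cycles_per_run = {design.cycles_per_run}",
        "onset_delays = " + ",".join(str(d) for d in design.onset_delays),
        "off_durations = "
        + ";".join(",".join(str(o) for o in run) for run in design.off_durations),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_design(path) -> AcquisitionDesign:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    return AcquisitionDesign(
        n_runs=int(kv["n_runs"]),
        volumes_per_run=int(kv["volumes_per_run"]),
        acq_interval=float(kv["acq_interval"]),
        on_duration=float(kv["on_duration"]),
        cycles_per_run=int(kv["cycles_per_run"]),
        onset_delays=tuple(float(x) for x in kv["onset_delays"].split(",")),
        off_durations=tuple(
            tuple(float(x) for x in run.split(","))
            for run in kv["off_durations"].split(";")
        ),
    )


def save_spt(spt: SPTWaveform, path) -> None:
    """Export the SPT as a two-column TSV (time_s, amplitude)."""
    t = np.arange(spt.n) * spt.acq_interval
    with open(path, "w") as fh:
        fh.write("time_s\tamplitude\n")
        for ti, xi in zip(t, spt.samples):
            fh.write(f"{ti:.1f}\t{xi:.10g}\n")
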