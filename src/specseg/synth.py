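"""Synthetic fMRI-like datasets with planted spatiotemporal components.

The generator emulates the statistical structure the analysis assumes after
preprocessing: 4-D volumes that are a sum of spatial-map x time-course
outer products plus voxelwise noise, per-subject motion traces (with traces
coupled to planted motion components), binary grey-matter and CSF masks,
and a ground-truth table.  MR physics, registration and smoothing are out
of scope; volumes are generated directly in "preprocessed" space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AcquisitionDesign

__all__ = [
    "SptLocked",
    "Harmonic2",
    "OffFrequency",
    "MotionCoupled",
    "CsfArtifact",
    "WhiteNoise",
    "PlantedComponent",
    "SyntheticDataset",
    "make_timecourse",
    "gaussian_blob_map",
    "one_over_f_noise",
    "synthesize",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """Unknown or inconsistent temporal specification."""


# -- temporal specifications -------------------------------------------------

@dataclass(frozen=True)
class SptLocked:
    """Cosine at the stimulus fundamental bin."""

    phase_deg: float
    amplitude: float
    kind = "spt_locked"


@dataclass(frozen=True)
class Harmonic2:
    """Cosine at the second-harmonic bin."""

    phase_deg: float
    amplitude: float
    kind = "harmonic2"


@dataclass(frozen=True)
class OffFrequency:
    """Cosine at an arbitrary off-stimulus grid frequency."""

    freq_hz: float
    amplitude: float = 0.08
    phase_deg: float | None = None  # None: random phase
    kind = "off_frequency"


@dataclass(frozen=True)
class MotionCoupled:
    """Series coupled into one of the six motion-parameter traces."""

    param_index: int
    amplitude: float = 1.0
    kind = "motion_coupled"


@dataclass(frozen=True)
class CsfArtifact:
    """Slow oscillatory artifact confined to the CSF mask."""

    amplitude: float = 1.0
    freq_hz: float = 0.02859
    kind = "csf_artifact"


@dataclass(frozen=True)
class WhiteNoise:
    kind = "white_noise"


TemporalSpec = SptLocked | Harmonic2 | OffFrequency | MotionCoupled | CsfArtifact | WhiteNoise


def _planted_bin(spec: TemporalSpec, design: AcquisitionDesign) -> int | None:
    n = design.total_volumes
    if isinstance(spec, SptLocked):
        return design.fundamental_bin
    if isinstance(spec, Harmonic2):
        return design.harmonic2_bin
    if isinstance(spec, (OffFrequency, CsfArtifact)):
        k = int(round(spec.freq_hz * n * design.acq_interval))
        if k in (design.fundamental_bin, design.harmonic2_bin):
            raise ConfigurationError(
                "off-frequency component coincides with a stimulus bin"
            )
        return k
    return None


def make_timecourse(
    spec: TemporalSpec,
    design: AcquisitionDesign,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Session-length time course realising a temporal specification.

    Periodic specs are ``amplitude * cos(2 pi f t + phase)`` on the
    acquisition grid plus white Gaussian noise of ``noise_sd``; the planted
    amplitude and phase at the spec's bin are preserved exactly at
    ``noise_sd = 0`` so they can be recovered to machine precision.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.total_volumes
    t = np.arange(n)
    if isinstance(spec, (SptLocked, Harmonic2, OffFrequency, CsfArtifact)):
        k = _planted_bin(spec, design)
        phase = getattr(spec, "phase_deg", None)
        if phase is None:
            phase = rng.uniform(-180.0, 180.0)
        x = spec.amplitude * np.cos(2 * np.pi * k * t / n + np.deg2rad(phase))
    elif isinstance(spec, MotionCoupled):
        if not 0 <= spec.param_index < 6:
            raise ConfigurationError("motion parameter index must be in 0..5")
        # lightly smoothed white series: near-orthogonal across components
        # (so ICA can separate several of them) while still trace-like
        smooth = np.convolve(rng.standard_normal(n), np.ones(3) / 3.0, mode="same")
        x = spec.amplitude * (smooth - smooth.mean()) / smooth.std()
    elif isinstance(spec, WhiteNoise):
        x = rng.standard_normal(n)
    else:
        raise ConfigurationError(f"unknown temporal spec {spec!r}")
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return x


# -- spatial maps ------------------------------------------------------------

def gaussian_blob_map(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    sigma: float,
    z_thresh: float = 1.0,
) -> np.ndarray:
    """Z-scored Gaussian blob thresholded at ``z_thresh`` (non-negative).

    Matches the z-scored map convention of ICA reporting: the blob is
    z-scored over the volume and values below the threshold are zeroed.
    """
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    blob = np.exp(-d2 / (2.0 * sigma**2))
    z = (blob - blob.mean()) / blob.std()
    z[z < z_thresh] = 0.0
    return z


def one_over_f_noise(
    n: int, sd: float, rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent amplitude envelope, SD ``sd``."""
    white = rng.standard_normal(n)
    coef = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0)
    with np.errstate(divide="ignore"):
        env = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    shaped = np.fft.irfft(coef * env, n)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


# -- dataset assembly --------------------------------------------------------

@dataclass
class PlantedComponent:
    """A ground-truth source: spatial map, temporal spec, true class."""

    name: str
    spatial_map: np.ndarray
    temporal_spec: TemporalSpec
    label_truth: str

    def __post_init__(self) -> None:
        if np.any(self.spatial_map < 0):
            raise ValueError("spatial maps are non-negative after thresholding")
        amp = getattr(self.temporal_spec, "amplitude", None)
        if amp is not None and amp < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class SyntheticDataset:
    """Per-subject 4-D volumes with masks, motion traces, and ground truth."""

    design: AcquisitionDesign
    volumes: list[np.ndarray]  # per subject, (x, y, z, t)
    motion: list[np.ndarray]  # per subject, (t, 6)
    csf_mask: np.ndarray
    gm_mask: np.ndarray
    truth: list[PlantedComponent]
    timecourses: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape[:3]


def synthesize(
    design: AcquisitionDesign,
    components: list[PlantedComponent],
    subject_count: int = 19,
    noise_sd: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 16, 10),
    csf_mask: np.ndarray | None = None,
    gm_mask: np.ndarray | None = None,
    timecourse_noise_sd: float = 0.0,
) -> SyntheticDataset:
    """Assemble per-subject volumes as sum of map (x) time-course + noise.

    All subjects share the planted spatial maps and time courses (the group
    ICA model); voxelwise Gaussian noise of ``noise_sd`` is drawn fresh per
    subject.  Motion traces are smooth random walks; for each
    ``MotionCoupled`` component its time course is added into the indicated
    motion parameter so temporal correlation ranking can find it.
    ``CsfArtifact`` maps must be supported inside the CSF mask.
    """
    if subject_count < 1:
        raise ValueError("subject_count must be >= 1")
    rng = np.random.default_rng(seed)
    n = design.total_volumes
    if csf_mask is None:
        csf_mask = np.zeros(shape, dtype=bool)
        csf_mask[: max(1, shape[0] // 8), :, :] = True
    if gm_mask is None:
        gm_mask = ~csf_mask
    csf_mask = np.asarray(csf_mask, dtype=bool)
    gm_mask = np.asarray(gm_mask, dtype=bool)

    tcs: dict[str, np.ndarray] = {}
    for comp in components:
        if comp.spatial_map.shape != shape:
            raise ValueError(
                f"component {comp.name}: map shape {comp.spatial_map.shape} "
                f"does not match volume shape {shape}"
            )
        if isinstance(comp.temporal_spec, CsfArtifact):
            if np.any(comp.spatial_map[~csf_mask] > 0):
                raise ValueError(
                    f"CSF artifact {comp.name} extends outside the CSF mask"
                )
        tcs[comp.name] = make_timecourse(
            comp.temporal_spec, design, timecourse_noise_sd, rng
        )

    volumes, motion = [], []
    for _ in range(subject_count):
        vol = np.zeros(shape + (n,))
        for comp in components:
            vol += comp.spatial_map[..., None] * tcs[comp.name][None, None, None, :]
        if noise_sd > 0:
            vol += noise_sd * rng.standard_normal(vol.shape)
        volumes.append(vol)
        traces = np.empty((n, 6))
        for j in range(6):
            walk = np.cumsum(rng.standard_normal(n))
            traces[:, j] = 0.3 * (walk - walk.mean()) / walk.std()
        mc = [c for c in components if isinstance(c.temporal_spec, MotionCoupled)]
        if mc:
            # head-motion parameters are strongly inter-correlated in real
            # realignment traces: every coupled component drives its own
            # trace at full weight and all other traces at a moderate one
            zs = {}
            for comp in mc:
                tc = tcs[comp.name]
                zs[comp.name] = (tc - tc.mean()) / tc.std()
            total = np.sum(list(zs.values()), axis=0)
            traces += 0.45 * total[:, None]
            for comp in mc:
                traces[:, comp.temporal_spec.param_index] += 0.55 * zs[comp.name]
        motion.append(traces * 0.05)  # mm-scale realignment traces

    return SyntheticDataset(
        design=design,
        volumes=volumes,
        motion=motion,
        csf_mask=csf_mask,
        gm_mask=gm_mask,
        truth=list(components),
        timecourses=tcs,
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write NIfTI volumes/masks, SPM-style motion files, and a truth TSV."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([1.56, 1.56, 5.0, 1.0])
    for i, (vol, mot) in enumerate(zip(ds.volumes, ds.motion), start=1):
        nib.save(
            nib.Nifti1Image(vol.astype(np.float32), affine),
            out / f"sub-{i:02d}_bold.nii",
        )
        np.savetxt(out / f"sub-{i:02d}_motion.txt", mot, fmt="%.6f")
    nib.save(
        nib.Nifti1Image(ds.csf_mask.astype(np.uint8), affine), out / "csf_mask.nii"
    )
    nib.save(nib.Nifti1Image(ds.gm_mask.astype(np.uint8), affine), out / "gm_mask.nii")
    rows = []
    for comp in ds.truth:
        spec = comp.temporal_spec
        rows.append(
            {
                "component_id": comp.name,
                "class": comp.label_truth,
                "kind": spec.kind,
                "f_hz": getattr(spec, "freq_hz", np.nan),
                "amplitude": getattr(spec, "amplitude", np.nan),
                "phase_deg": getattr(spec, "phase_deg", np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
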