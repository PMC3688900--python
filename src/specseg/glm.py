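"""Conventional regression arm: voxelwise GLM on the stimulus regressor.

Each subject's data are regressed on the HRF-convolved stimulus timing
waveform with per-run baseline, linear and parabolic drift nuisances; the
stimulus betas go into a group one-sample t-test, thresholded either by
BH-FDR or at an uncorrected p, and split into activation / deactivation
masks for comparison with the ICA classification maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .design import AcquisitionDesign, SPTWaveform
from .freq import fdr_adjust

__all__ = ["GlmResult", "fit_subject_glm", "group_map", "compare_maps", "dice"]


def _drift_regressors(design: AcquisitionDesign) -> np.ndarray:
    """Per-run baseline, linear and parabolic columns (runs concatenated)."""
    m = design.volumes_per_run
    t = np.linspace(-1.0, 1.0, m)
    cols = []
    for r in range(design.n_runs):
        for poly in (np.ones(m), t, t**2):
            col = np.zeros(design.total_volumes)
            col[r * m : (r + 1) * m] = poly
            cols.append(col)
    return np.column_stack(cols)


def build_design_matrix(spt: SPTWaveform, design: AcquisitionDesign) -> np.ndarray:
    """Stimulus regressor followed by the per-run drift nuisances."""
    s = spt.samples
    s = (s - s.mean()) / s.std()
    x = np.column_stack([s, _drift_regressors(design)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via the QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(x)[1]))
        bad = np.flatnonzero(r_diag < 1e-10 * r_diag.max())
        names = ["spt"] + [
            f"run{r + 1}_{p}"
            for r in range(design.n_runs)
            for p in ("baseline", "linear", "parabolic")
        ]
        raise ValueError(
            "rank-deficient design matrix; collinear columns: "
            + ", ".join(names[i] for i in bad)
        )
    return x


def fit_subject_glm(
    data: np.ndarray, spt: SPTWaveform, design: AcquisitionDesign
) -> np.ndarray:
    """OLS per voxel; returns the stimulus-beta (contrast) image.

    ``data`` is (time x voxels) or 4-D (x, y, z, t); the returned contrast
    has the spatial shape of the input.
    """
    data = np.asarray(data, dtype=float)
    four_d = data.ndim == 4
    mat = data.reshape(-1, data.shape[-1]).T if four_d else data
    x = build_design_matrix(spt, design)
    if x.shape[0] != mat.shape[0]:
        raise ValueError("data length does not match the design")
    beta, *_ = np.linalg.lstsq(x, mat, rcond=None)
    contrast = beta[0]
    return contrast.reshape(data.shape[:3]) if four_d else contrast


@dataclass
class GlmResult:
    """Group-level stimulus effect with thresholded sign masks."""

    group_t: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    threshold_spec: tuple[str, float, str]

    def __post_init__(self) -> None:
        assert not np.any(self.pos_mask & self.neg_mask)


def group_map(
    contrasts: np.ndarray, q: float = 0.05, correction: str = "fdr"
) -> GlmResult:
    """One-sample t-test over subject contrasts, thresholded and signed.

    ``correction`` is ``"fdr"`` (BH at level ``q``) or ``"uncorrected"``
    (plain p < q, the map-comparison convention at p < 0.001).
    """
    c = np.asarray(contrasts, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("group map needs at least 2 subjects")
    t, p = _stats.ttest_1samp(c, 0.0, axis=0)
    t = np.nan_to_num(t)
    p = np.nan_to_num(p, nan=1.0)
    if correction == "fdr":
        _, sig = fdr_adjust(p.ravel(), q)
        sig = sig.reshape(p.shape)
    elif correction == "uncorrected":
        sig = p < q
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return GlmResult(
        group_t=t,
        pos_mask=sig & (t > 0),
        neg_mask=sig & (t < 0),
        threshold_spec=("t", q, correction),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.sum(a & b) / denom


def compare_maps(
    glm: GlmResult, ica_union: dict[str, np.ndarray]
) -> dict[str, dict[str, float]]:
    """Per-class overlap of ICA union masks with the signed GLM masks.

    ``ica_union`` maps a class label to a binary mask; activation-like
    classes are compared with the positive GLM mask and deactivation-like
    with the negative.  Reports Dice, GLM-only and ICA-only voxel counts.
    """
    report: dict[str, dict[str, float]] = {}
    for label, mask in ica_union.items():
        mask = np.asarray(mask, dtype=bool)
        glm_mask = glm.neg_mask if "deactiv" in label else glm.pos_mask
        if mask.shape != glm_mask.shape:
            raise ValueError(f"mask grid mismatch for class {label!r}")
        report[label] = {
            "dice": dice(mask, glm_mask),
            "glm_only": int(np.sum(glm_mask & ~mask)),
            "ica_only": int(np.sum(mask & ~glm_mask)),
            "both": int(np.sum(mask & glm_mask)),
        }
    return report
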