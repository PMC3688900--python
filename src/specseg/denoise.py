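"""Artifact-component selection and removal (the two-pass denoising scheme).

Per-subject ICA components are ranked by temporal correlation with the six
head-motion parameters and by spatial correlation with the CSF mask; the
four most correlated components per artifact parameter are pooled, the
pooled list deduplicated, and the selected components regressed out of the
voxel data before group ICA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NoiseSelection", "rank_artifact_components", "remove_components"]

TOP_PER_PARAMETER = 4


@dataclass
class NoiseSelection:
    """Top-ranked artifact components per parameter and their union."""

    per_parameter_top: dict[str, list[int]]
    correlations: dict[str, list[float]]
    selected: list[int]

    @property
    def removed_count(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for param, ids in self.per_parameter_top.items():
            for rank, (cid, corr) in enumerate(
                zip(ids, self.correlations[param]), start=1
            ):
                rows.append(
                    {
                        "parameter": param,
                        "rank": rank,
                        "component_id": cid,
                        "correlation": corr,
                    }
                )
        return pd.DataFrame(rows)


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def rank_artifact_components(
    timecourses: np.ndarray,
    maps: np.ndarray,
    motion: np.ndarray,
    csf_mask: np.ndarray,
) -> NoiseSelection:
    """Rank components against the 6 motion traces and the CSF mask.

    ``timecourses`` is (time x components), ``maps`` (components x voxels),
    ``motion`` (time x 6); for CSF the |z| map is correlated with the
    binarised mask.  Exactly four components are returned per parameter
    regardless of correlation magnitude; the union is deduplicated in
    first-seen order.
    """
    tcs = np.asarray(timecourses, dtype=float)
    maps = np.asarray(maps, dtype=float)
    motion = np.asarray(motion, dtype=float)
    k = tcs.shape[1]
    if k < TOP_PER_PARAMETER:
        raise ValueError(f"need at least {TOP_PER_PARAMETER} components, got {k}")
    if motion.shape[0] != tcs.shape[0]:
        raise ValueError("motion traces must match the time-course length")
    if motion.shape[1] != 6:
        raise ValueError("expected 6 motion parameters")
    csf = np.asarray(csf_mask, dtype=float).reshape(-1)
    if maps.shape[1] != csf.size:
        raise ValueError("CSF mask does not match the map voxel dimension")

    per_top: dict[str, list[int]] = {}
    per_corr: dict[str, list[float]] = {}
    names = [f"motion{j + 1}" for j in range(6)] + ["csf"]
    for j, name in enumerate(names):
        if name == "csf":
            vals = np.array(
                [_abs_pearson(np.abs(_z(m)), csf) for m in maps]
            )
        else:
            vals = np.array([_abs_pearson(tcs[:, c], motion[:, j]) for c in range(k)])
        order = np.argsort(vals)[::-1][:TOP_PER_PARAMETER]
        per_top[name] = [int(c) for c in order]
        per_corr[name] = [float(vals[c]) for c in order]

    selected: list[int] = []
    for name in names:
        for cid in per_top[name]:
            if cid not in selected:
                selected.append(cid)
    return NoiseSelection(per_parameter_top=per_top, correlations=per_corr, selected=selected)


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def remove_components(
    data: np.ndarray,
    timecourses: np.ndarray,
    selection: NoiseSelection | list[int],
) -> np.ndarray:
    """Regress the selected component time courses out of every voxel.

    Ordinary least squares of the selected time courses (plus intercept)
    per voxel; the fitted contribution is subtracted.  An empty selection
    returns the input unchanged.  ``data`` is (time x voxels) or a 4-D
    (x, y, z, t) volume.
    """
    ids = selection.selected if isinstance(selection, NoiseSelection) else list(selection)
    data = np.asarray(data, dtype=float)
    if not ids:
        return data.copy()
    tcs = np.asarray(timecourses, dtype=float)
    if max(ids) >= tcs.shape[1] or min(ids) < 0:
        raise ValueError("selection contains invalid component ids")
    four_d = data.ndim == 4
    if four_d:
        shape = data.shape
        mat = data.reshape(-1, shape[-1]).T  # (time, voxels)
    else:
        mat = data
    x = np.column_stack([np.ones(mat.shape[0]), tcs[:, ids]])
    beta, *_ = np.linalg.lstsq(x, mat, rcond=None)
    clean = mat - x[:, 1:] @ beta[1:]
    if four_d:
        return clean.T.reshape(shape)
    return clean
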