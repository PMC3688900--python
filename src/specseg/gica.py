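"""Group spatial ICA: PCA reduction, temporal concatenation, Infomax,
back-reconstruction, and group statistical maps.

The decomposition follows the temporal-concatenation scheme standard for
multi-subject spatial ICA: each subject's (time x voxel) matrix is reduced
to ``k1`` principal components in time, the reduced matrices are stacked,
reduced again to the model order, and unmixed with Infomax (natural
gradient, logistic nonlinearity, favouring super-Gaussian spatial
sources).  Per-subject maps and time courses are recovered by projecting
the group mixing matrix back through the stored reduction operators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as _stats

from .freq import fdr_adjust

__all__ = [
    "Reduction",
    "reduce",
    "infomax",
    "group_ica",
    "ComponentSet",
    "group_tmap",
    "save_component_set",
]


@dataclass
class Reduction:
    """Top-k principal subspace of a (time x voxel) data matrix.

    ``basis`` (time x k) holds the orthonormal temporal principal
    directions; ``reduced`` (k x voxels) the projected data.  The stored
    basis is what back-reconstruction uses to return from reduced space to
    full time courses.
    """

    basis: np.ndarray
    reduced: np.ndarray
    eigenvalues: np.ndarray
    row_means: np.ndarray

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    @property
    def explained_variance(self) -> float:
        return float(self.eigenvalues[: self.k].sum())

    def reconstruct(self) -> np.ndarray:
        """Data approximation from the retained subspace (time x voxels)."""
        return self.basis @ self.reduced + self.row_means


def reduce(data: np.ndarray, k: int) -> Reduction:
    """Reduce a (time x voxel) matrix to its top-k principal subspace.

    Rows (time points) are mean-centred per voxel before the SVD; the
    eigenvalues are of the temporal covariance, so their top-k sum is the
    variance explained by the retained subspace.
    """
    data = np.asarray(data, dtype=float)
    if k < 1 or k > min(data.shape):
        raise ValueError(
            f"k={k} must be in [1, {min(data.shape)}] for shape {data.shape}"
        )
    means = data.mean(axis=0, keepdims=True)
    centred = data - means
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    basis = u[:, :k]
    reduced = (s[:k, None] * vt[:k])
    eig = s**2 / max(1, data.shape[0] - 1)
    return Reduction(basis=basis, reduced=reduced, eigenvalues=eig, row_means=means)


def infomax(
    data: np.ndarray,
    lr: float = 0.001,
    max_iter: int = 512,
    block: int | None = None,
    tol: float = 1e-7,
    anneal: float = 0.98,
    seed: int = 0,
) -> tuple[np.ndarray, bool]:
    """Infomax unmixing of a whitened (k x samples) matrix.

    Natural-gradient ascent of the information-transfer objective with a
    logistic nonlinearity; the learning rate is annealed whenever an update
    overshoots.  Returns ``(W, converged)``; ``W @ data`` are the sources.
    """
    z = np.asarray(data, dtype=float)
    k, n = z.shape
    if block is None:
        block = int(min(n, max(32, np.floor(np.sqrt(n / 3.0)))))
    rng = np.random.default_rng(seed)
    w = np.eye(k)
    eye = np.eye(k)
    converged = False
    for _ in range(max_iter):
        perm = rng.permutation(n)
        w_old = w.copy()
        blew_up = False
        for start in range(0, n - block + 1, block):
            u = w @ z[:, perm[start : start + block]]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = eye + (1.0 - 2.0 * y) @ u.T / block
            w = w + lr * grad @ w
            if not np.all(np.isfinite(w)) or np.abs(w).max() > 1e8:
                blew_up = True
                break
        if blew_up:
            w = w_old
            lr *= 0.5
            continue
        delta = np.abs(w - w_old).max()
        lr *= anneal
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Infomax did not converge within max_iter; partial result")
    return w, converged


@dataclass
class ComponentSet:
    """Group ICA result with back-reconstructed per-subject sets.

    ``group_maps`` are the z-scored aggregate source maps (order x voxels);
    ``subject_maps`` (subjects x order x voxels); ``subject_timecourses``
    (subjects x time x order), z-scored per component so every individual
    time course has SD 1.
    """

    group_maps: np.ndarray
    subject_maps: np.ndarray
    subject_timecourses: np.ndarray
    order: int
    converged: bool
    seed: int
    spatial_shape: tuple[int, ...] | None = None
    group_t: np.ndarray | None = None
    group_t_mask: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.subject_maps.shape[0]

    def mean_timecourses(self) -> np.ndarray:
        """Subject-averaged component time courses (time x order)."""
        return self.subject_timecourses.mean(axis=0)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=1, keepdims=True)) / sd


def group_ica(
    subject_matrices: list[np.ndarray],
    order: int,
    seed: int = 0,
    k1: int | None = None,
    lr: float = 0.001,
    max_iter: int = 512,
) -> ComponentSet:
    """Temporal-concatenation group spatial ICA with back-reconstruction.

    ``subject_matrices`` are (time x voxel) arrays sharing the voxel
    dimension.  Sign indeterminacy is fixed by making every group map's
    skewness non-negative; component order is by variance of the group
    aggregate mixing.
    """
    if not subject_matrices:
        raise ValueError("no subjects")
    v = subject_matrices[0].shape[1]
    if any(m.shape[1] != v for m in subject_matrices):
        raise ValueError("all subjects must share the voxel dimension")
    k1 = k1 or order
    reductions = [reduce(m, k1) for m in subject_matrices]
    stacked = np.vstack([r.reduced for r in reductions])  # (S*k1, voxels)

    # second reduction + whitening of the concatenated data
    centred = stacked - stacked.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if order > s.size:
        raise ValueError(f"order {order} exceeds concatenated rank {s.size}")
    g = u[:, :order]  # (S*k1, order)
    z = np.sqrt(v) * vt[:order]  # whitened spatial data (order, voxels)
    scale = s[:order] / np.sqrt(v)

    w, converged = infomax(z, lr=lr, max_iter=max_iter, seed=seed)
    sources = w @ z  # (order, voxels) spatial maps
    # total unmixing from concatenated reduced space: sources = U_tot @ stacked
    u_tot = w @ np.diag(1.0 / scale) @ g.T
    a_tot = np.linalg.pinv(u_tot)  # (S*k1, order) aggregate mixing

    # sign convention: non-negative skewness of each group map
    skew = _stats.skew(sources, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    a_tot = a_tot * flip[None, :]

    # order components by aggregate mixing variance (descending)
    strength = (a_tot**2).sum(axis=0)
    idx = np.argsort(strength)[::-1]
    sources = sources[idx]
    a_tot = a_tot[:, idx]

    n_sub = len(subject_matrices)
    subject_maps = np.empty((n_sub, order, v))
    t_len = subject_matrices[0].shape[0]
    subject_tcs = np.empty((n_sub, t_len, order))
    for i, red in enumerate(reductions):
        a_i = a_tot[i * k1 : (i + 1) * k1]  # (k1, order)
        subject_maps[i] = np.linalg.pinv(a_i) @ red.reduced
        tc = red.basis @ a_i  # (time, order)
        subject_tcs[i] = _zscore_rows(tc.T).T

    return ComponentSet(
        group_maps=_zscore_rows(sources),
        subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
        order=order,
        converged=converged,
        seed=seed,
    )


def group_tmap(
    subject_maps: np.ndarray, q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise one-sample t-test across subjects with BH-FDR threshold.

    ``subject_maps`` is (subjects, ..., voxels); the test is per voxel per
    component, the FDR threshold is applied within each component map.
    Returns ``(t, mask)``.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("group t-map needs at least 2 subjects")
    t, p = _stats.ttest_1samp(maps, 0.0, axis=0)
    t = np.nan_to_num(t)
    p = np.nan_to_num(p, nan=1.0)
    if p.ndim == 1:
        _, mask = fdr_adjust(p, q)
    else:
        mask = np.empty_like(p, dtype=bool)
        for c in range(p.shape[0]):
            _, mask[c] = fdr_adjust(p[c].ravel(), q)
            mask[c] = mask[c].reshape(p[c].shape)
    return t, mask


def save_component_set(cs: ComponentSet, out_dir, affine=None) -> None:
    """Write z-maps and t-maps as NIfTI, time courses as TSV, manifest JSON."""
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cs.spatial_shape is None:
        raise ValueError("component set has no spatial shape for NIfTI export")
    aff = affine if affine is not None else np.eye(4)
    shape = tuple(cs.spatial_shape)
    zvol = np.stack([m.reshape(shape) for m in cs.group_maps], axis=-1)
    nib.save(nib.Nifti1Image(zvol.astype(np.float32), aff), out / "group_zmaps.nii")
    if cs.group_t is not None:
        tvol = np.stack([m.reshape(shape) for m in cs.group_t], axis=-1)
        nib.save(nib.Nifti1Image(tvol.astype(np.float32), aff), out / "group_tmaps.nii")
    mean_tc = cs.mean_timecourses()
    pd.DataFrame(
        mean_tc, columns=[f"ic{i + 1:02d}" for i in range(cs.order)]
    ).to_csv(out / "timecourses.tsv", sep="\t", index=False)
    manifest = {
        "order": cs.order,
        "seed": cs.seed,
        "converged": bool(cs.converged),
        "n_subjects": cs.n_subjects,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
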