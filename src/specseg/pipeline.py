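"""Orchestration: simulate -> subject ICA + denoise -> group ICA ->
classification -> GLM comparison, with a single fan-out seed and a flat
config file.

Every stage writes its outputs under the run directory and the final
report bundles the classification table, per-label counts and the
ICA-vs-GLM overlap.  One global seed is expanded into per-stage seeds by a
fixed derivation so a run is reproducible end to end.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import denoise as _denoise
from . import glm as _glm
from .classify import classify_components, infer_gm_labels
from .design import AcquisitionDesign, build_spt, save_design, save_spt
from .gica import ComponentSet, group_ica, group_tmap, save_component_set
from .synth import (
    CsfArtifact,
    Harmonic2,
    MotionCoupled,
    OffFrequency,
    PlantedComponent,
    SptLocked,
    SyntheticDataset,
    gaussian_blob_map,
    synthesize,
    write_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]

_STAGES = ("simulate", "subject_ica", "denoise", "group_ica", "classify", "glm")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (flat file, one section per module)."""

    seed: int = 0
    subjects: int = 19
    shape: tuple[int, int, int] = (16, 16, 10)
    noise_sd: float = 0.5
    order: int = 40
    subject_order: int = 40
    q_group: float = 0.01
    q_corr: float = 0.05
    p_bonf: float = 0.05
    p_compare: float = 0.001
    n_perm: int = 199
    max_iter: int = 256

    def __post_init__(self) -> None:
        for name in ("q_group", "q_corr", "p_bonf", "p_compare"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def save_config(cfg: RunConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["run"] = {"seed": str(cfg.seed)}
    cp["synth"] = {
        "subjects": str(cfg.subjects),
        "shape": ",".join(map(str, cfg.shape)),
        "noise_sd": str(cfg.noise_sd),
    }
    cp["ica"] = {
        "order": str(cfg.order),
        "subject_order": str(cfg.subject_order),
        "max_iter": str(cfg.max_iter),
        "q_group": str(cfg.q_group),
    }
    cp["classify"] = {
        "q_corr": str(cfg.q_corr),
        "p_bonf": str(cfg.p_bonf),
        "n_perm": str(cfg.n_perm),
    }
    cp["glm"] = {"p_compare": str(cfg.p_compare)}
    with open(path, "w") as fh:
        cp.write(fh)


def load_config(path) -> RunConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(path)
    return RunConfig(
        seed=cp.getint("run", "seed", fallback=0),
        subjects=cp.getint("synth", "subjects", fallback=19),
        shape=tuple(
            int(x) for x in cp.get("synth", "shape", fallback="16,16,10").split(",")
        ),
        noise_sd=cp.getfloat("synth", "noise_sd", fallback=0.5),
        order=cp.getint("ica", "order", fallback=40),
        subject_order=cp.getint("ica", "subject_order", fallback=40),
        max_iter=cp.getint("ica", "max_iter", fallback=256),
        q_group=cp.getfloat("ica", "q_group", fallback=0.01),
        q_corr=cp.getfloat("classify", "q_corr", fallback=0.05),
        p_bonf=cp.getfloat("classify", "p_bonf", fallback=0.05),
        n_perm=cp.getint("classify", "n_perm", fallback=199),
        p_compare=cp.getfloat("glm", "p_compare", fallback=0.001),
    )


def default_components(
    design: AcquisitionDesign,
    shape: tuple[int, int, int],
    spt_phase_deg: float,
    spt_phase2_deg: float,
) -> tuple[list[PlantedComponent], np.ndarray, np.ndarray]:
    """Desk-scale planted source set covering every classification label.

    Four grey-matter sources (a stimulus-locked in-phase source, a
    stimulus-locked source 135 degrees off — far enough from anti-phase
    that the two time courses are not collinear, which would make them
    unseparable, yet still significantly negatively correlated — a
    second-harmonic neutral source, and a run-periodic off-frequency one)
    plus a realistic artifact population: twelve motion-coupled components
    (two per realignment trace; real head-motion parameters are strongly
    inter-correlated, so every coupled component loads on every trace) and
    four CSF components tiling the CSF slab at distinct off-stimulus
    frequencies.  With several genuinely coupled components per artifact
    parameter the top-4 rankings fill with true artifacts and the
    grey-matter sources survive the removal pass, as in the original
    two-pass scheme.  Spatial supports sit on a near-disjoint grid so the
    maps are spatially independent.  Returns the components plus the CSF
    and GM masks.
    """
    csf = np.zeros(shape, dtype=bool)
    csf[: max(1, shape[0] // 8)] = True
    gm = ~csf
    nx, ny, nz = shape

    def blob(center, sigma=1.0):
        return gaussian_blob_map(shape, center, sigma)

    xs = [nx * f for f in (0.25, 0.47, 0.69, 0.88)]
    ys = [ny * f for f in (0.125, 0.375, 0.625, 0.875)]
    centers = [
        (x, y, nz * (0.5 if (i + j) % 2 else 0.3))
        for i, x in enumerate(xs)
        for j, y in enumerate(ys)
    ]
    gm_specs = [
        ("activated", SptLocked(spt_phase_deg + 15.0, 1.0), "stimulus-activated"),
        ("deactivated", SptLocked(spt_phase_deg + 135.0, 1.0), "stimulus-deactivated"),
        ("neutral", Harmonic2(spt_phase2_deg + 140.0, 1.0), "stimulus-neutral"),
        ("unrelated", OffFrequency(0.03309, 1.0), "stimulus-unrelated"),
    ] + [
        (f"motion{j + 1}", MotionCoupled(j % 6, 1.0), "noise") for j in range(12)
    ]
    comps = [
        PlantedComponent(name, blob(c) * gm, spec, label)
        for (name, spec, label), c in zip(gm_specs, centers)
    ]
    for j, f in enumerate((0.01961, 0.02083, 0.02859, 0.04330)):
        comps.append(
            PlantedComponent(
                f"csf{j + 1}",
                blob((0.0, ny * (0.125 + 0.25 * j), nz * 0.5), sigma=1.8) * csf,
                CsfArtifact(amplitude=1.5, freq_hz=f),
                "noise",
            )
        )
    return comps, csf, gm


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Run every stage and return the report dictionary.

    Any stage failure is re-raised with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg)}
    state: dict = {}
    for stage in _STAGES:
        try:
            _STAGE_FUNCS[stage](cfg, out, state, report)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    report["outputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out.glob("*"))
        if p.is_file()
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    seed = cfg.stage_seed("simulate")
    design = AcquisitionDesign.jittered(seed)
    spt = build_spt(design)
    comps, csf, gm = default_components(
        design,
        cfg.shape,
        spt.phase_deg,
        spt.phase_at_bin(design.harmonic2_bin),
    )
    ds = synthesize(
        design,
        comps,
        subject_count=cfg.subjects,
        noise_sd=cfg.noise_sd,
        seed=seed,
        shape=cfg.shape,
        csf_mask=csf,
        gm_mask=gm,
        # independent temporal noise keeps same-bin sources non-collinear
        timecourse_noise_sd=0.6,
    )
    write_dataset(ds, out / "data")
    save_design(design, out / "design.cfg")
    save_spt(spt, out / "spt.tsv")
    state.update(design=design, spt=spt, dataset=ds)
    report["simulate"] = {"seed": seed, "subjects": cfg.subjects, "components": len(comps)}


def _stage_subject_ica(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    ds: SyntheticDataset = state["dataset"]
    seed = cfg.stage_seed("subject_ica")
    order = min(cfg.subject_order, ds.design.total_volumes - 1)
    results = []
    for i, vol in enumerate(ds.volumes):
        mat = vol.reshape(-1, vol.shape[-1]).T  # (time, voxels)
        cs = group_ica([mat], order=order, seed=seed + i, max_iter=cfg.max_iter)
        results.append(cs)
    state["subject_ica"] = results
    report["subject_ica"] = {"order": order, "seed": seed}


def _stage_denoise(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    ds: SyntheticDataset = state["dataset"]
    removed = []
    denoised = []
    for i, (vol, cs) in enumerate(zip(ds.volumes, state["subject_ica"])):
        sel = _denoise.rank_artifact_components(
            cs.subject_timecourses[0],
            cs.subject_maps[0],
            ds.motion[i],
            ds.csf_mask,
        )
        clean = _denoise.remove_components(vol, cs.subject_timecourses[0], sel)
        denoised.append(clean)
        removed.append(sel.removed_count)
        if i == 0:
            sel.to_frame().to_csv(out / "noise_selection_sub01.tsv", sep="\t", index=False)
    state["denoised"] = denoised
    report["denoise"] = {"removed_per_subject": removed}


def _stage_group_ica(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    ds: SyntheticDataset = state["dataset"]
    seed = cfg.stage_seed("group_ica")
    mats = [v.reshape(-1, v.shape[-1]).T for v in state["denoised"]]
    order = min(cfg.order, min(m.shape[0] for m in mats) - 1)
    cs = group_ica(mats, order=order, seed=seed, max_iter=cfg.max_iter)
    cs.spatial_shape = ds.shape
    t, mask = group_tmap(cs.subject_maps, q=cfg.q_group)
    cs.group_t, cs.group_t_mask = t, mask
    save_component_set(cs, out / "gica")
    state["components"] = cs
    report["group_ica"] = {"order": order, "seed": seed, "converged": cs.converged}


def _stage_classify(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    ds: SyntheticDataset = state["dataset"]
    cs: ComponentSet = state["components"]
    design, spt = state["design"], state["spt"]
    gm_flags = infer_gm_labels(cs.group_maps, ds.gm_mask, ds.csf_mask)
    mean_tc = cs.mean_timecourses()
    tcs = {f"ic{i + 1:02d}": mean_tc[:, i] for i in range(cs.order)}
    gm = {f"ic{i + 1:02d}": bool(gm_flags[i]) for i in range(cs.order)}
    table = classify_components(
        tcs, gm, design, spt,
        q_level=cfg.q_corr, n_perm=cfg.n_perm, seed=cfg.stage_seed("classify"),
    )
    table.to_csv(out / "classification.tsv", sep="\t", index=False)
    table[table["gm"] == 0].to_csv(out / "non_gm_components.tsv", sep="\t", index=False)
    state["classification"] = table
    counts = table["label"].value_counts().to_dict()
    report["classify"] = {"counts": counts, "rows": int(len(table))}


def _stage_glm(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    ds: SyntheticDataset = state["dataset"]
    cs: ComponentSet = state["components"]
    design, spt = state["design"], state["spt"]
    contrasts = np.stack(
        [_glm.fit_subject_glm(v, spt, design).ravel() for v in state["denoised"]]
    )
    result = _glm.group_map(contrasts, q=cfg.p_compare, correction="uncorrected")
    table = state["classification"]
    union: dict[str, np.ndarray] = {}
    for label in ("stimulus-activated", "stimulus-deactivated"):
        ids = table.index[table["label"] == label].to_numpy()
        mask = np.zeros(cs.group_maps.shape[1], dtype=bool)
        for i in ids:
            mask |= np.abs(cs.group_maps[i]) > 2.0
        union[label] = mask
    overlap = _glm.compare_maps(result, union)
    report["glm"] = {
        "threshold": result.threshold_spec,
        "pos_voxels": int(result.pos_mask.sum()),
        "neg_voxels": int(result.neg_mask.sum()),
        "overlap": overlap,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "subject_ica": _stage_subject_ica,
    "denoise": _stage_denoise,
    "group_ica": _stage_group_ica,
    "classify": _stage_classify,
    "glm": _stage_glm,
}
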