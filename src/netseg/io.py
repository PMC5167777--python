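"""Reading and writing the on-disk formats: NIfTI-1 volumes, anchor
JSON, 6-column motion text, YAML configs, and sweep reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import SubjectData, VolumeGrid
from .fixtures import CohortSimConfig, TemplateSet
from .groupica import Decomposition
from .preprocess import PreprocessConfig

__all__ = [
    "save_volume", "load_volume",
    "write_templates", "read_templates",
    "write_cohort", "read_cohort",
    "write_motion", "read_motion",
    "write_decomposition",
    "load_preprocess_config", "load_cohort_config",
]


def save_volume(path, data: np.ndarray, grid: VolumeGrid) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             grid.affine()), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _grid_from_img(img) -> tuple:
    dims = tuple(int(d) for d in img.shape[:3])
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return dims, vox


def write_templates(directory, templates: TemplateSet) -> None:
    """Masks as NIfTI-1, anchors as ``anchors.json``, brain mask alongside."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    grid = templates.grid
    save_volume(d / "brain_mask.nii", grid.brain_mask.astype(np.float32), grid)
    for label, mask in templates.masks.items():
        save_volume(d / f"{label}.nii", mask.astype(np.float32), grid)
    with open(d / "anchors.json", "w") as fh:
        json.dump({k: [list(map(int, a)) for a in v]
                   for k, v in templates.anchors.items()}, fh, indent=2)
    with open(d / "grid.json", "w") as fh:
        json.dump({"dims": list(grid.dims),
                   "voxel_size_mm": list(grid.voxel_size_mm)}, fh)


def read_templates(directory) -> TemplateSet:
    d = Path(directory)
    mask_img = nib.load(str(d / "brain_mask.nii"))
    dims, vox = _grid_from_img(mask_img)
    grid = VolumeGrid(dims=dims, voxel_size_mm=vox,
                      brain_mask=np.asarray(mask_img.get_fdata()) > 0.5)
    with open(d / "anchors.json") as fh:
        anchors = {k: [tuple(a) for a in v] for k, v in json.load(fh).items()}
    masks = {label: load_volume(d / f"{label}.nii") > 0.5 for label in anchors}
    return TemplateSet(grid=grid, masks=masks, anchors=anchors)


def write_motion(path, table: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(table, dtype=float), fmt="%.8f")


def read_motion(path) -> np.ndarray:
    table = np.loadtxt(str(path))
    if table.ndim != 2 or table.shape[1] != 6:
        raise ValueError(f"motion table at {path} is not (T, 6)")
    return table


def write_cohort(directory, subjects, truth=None) -> None:
    """Per-subject 4D NIfTI files plus a JSON manifest (and ground truth)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    grid = subjects[0].grid
    manifest = {"tr_s": subjects[0].tr_s, "subjects": []}
    for s in subjects:
        fname = f"{s.subject_id or 'sub'}.nii"
        save_volume(d / fname, s.series, grid)
        entry = {"file": fname, "subject_id": s.subject_id}
        if s.motion is not None:
            mname = fname.replace(".nii", "_motion.txt")
            write_motion(d / mname, s.motion)
            entry["motion"] = mname
        manifest["subjects"].append(entry)
    save_volume(d / "brain_mask.nii", grid.brain_mask.astype(np.float32), grid)
    if truth is not None:
        manifest["ground_truth"] = {
            "source_labels": truth.source_labels,
            "jitters": truth.jitters.tolist(),
        }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_cohort(directory) -> list:
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    mask_img = nib.load(str(d / "brain_mask.nii"))
    dims, vox = _grid_from_img(mask_img)
    grid = VolumeGrid(dims=dims, voxel_size_mm=vox,
                      brain_mask=np.asarray(mask_img.get_fdata()) > 0.5)
    subjects = []
    for entry in manifest["subjects"]:
        series = load_volume(d / entry["file"])
        motion = read_motion(d / entry["motion"]) if "motion" in entry else None
        subjects.append(SubjectData(grid=grid, series=series,
                                    tr_s=float(manifest["tr_s"]),
                                    motion=motion,
                                    subject_id=entry.get("subject_id", "")))
    return subjects


def write_decomposition(directory, decomp: Decomposition) -> None:
    """Group maps as per-component NIfTI, subject maps as 4D stacks,
    time courses as CSV (components x time), diagnostics as JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    grid = decomp.grid
    for k in range(decomp.n_components):
        save_volume(d / f"group_ic{k:03d}.nii", decomp.group_volume(k), grid)
    for s in range(decomp.subject_maps.shape[0]):
        stack = np.stack([grid.embed(m) for m in decomp.subject_maps[s]], axis=-1)
        save_volume(d / f"subject{s:02d}_maps.nii", stack, grid)
        np.savetxt(d / f"subject{s:02d}_timecourses.csv",
                   decomp.subject_timecourses[s], delimiter=",")
    diag = dict(decomp.diagnostics)
    diag.update({"algorithm": decomp.algorithm,
                 "model_order": decomp.model_order,
                 "n_components": decomp.n_components})
    if decomp.reproducibility is not None:
        diag["reproducibility"] = decomp.reproducibility.tolist()
    with open(d / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2, default=str)


def load_preprocess_config(path) -> PreprocessConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "band_hz" in raw:
        raw["band_hz"] = tuple(raw["band_hz"])
    return PreprocessConfig(**raw)


def load_cohort_config(path) -> CohortSimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "tc_band_hz" in raw:
        raw["tc_band_hz"] = tuple(raw["tc_band_hz"])
    return CohortSimConfig(**raw)
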