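"""Readers and writers for the on-disk formats (CSV, YAML, NIfTI).

Subjects are aligned strictly by id, never by row order.  Voxel indices
are 0-based internally; millimeter coordinates appear only at report
boundaries, always via the image affine.  Mask semantics: nonzero means
analyze.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bootstrap import CI_METHODS, BootstrapSettings
from .engine import MAP_FIELDS, AnalysisConfig, StatMapSet, VoxelDataset
from .exceptions import AlignmentError, ConfigError, InsufficientDataError

logger = logging.getLogger(__name__)

AFFINE_ATOL = 1e-4


def read_subject_table(path) -> pd.DataFrame:
    """Read and validate the subject covariate CSV.

    Requires columns subject_id, group (coded 0=young / 1=old) and
    performance; extra covariate columns pass through untouched.
    """
    tab = pd.read_csv(path)
    required = {"subject_id", "group", "performance"}
    missing = required - set(tab.columns)
    if missing:
        raise ConfigError(f"subject table missing columns: {sorted(missing)}")
    tab["subject_id"] = tab["subject_id"].astype(str)
    if tab["subject_id"].duplicated().any():
        dups = sorted(tab.loc[tab["subject_id"].duplicated(), "subject_id"])
        raise AlignmentError(f"duplicate subject ids: {dups}")
    if not tab["group"].isin((0, 1)).all():
        raise ConfigError(
            "group must be coded 0 (young) / 1 (old); remap other codings "
            "before analysis")
    if not np.isfinite(tab["performance"].to_numpy(dtype=float)).all():
        raise ConfigError("performance must be finite for every analysis row")
    return tab


def read_image_list(path) -> pd.DataFrame:
    """Read the subject-to-image mapping CSV (columns subject_id, path)."""
    tab = pd.read_csv(path)
    if not {"subject_id", "path"} <= set(tab.columns):
        raise ConfigError("image list needs columns subject_id, path")
    tab["subject_id"] = tab["subject_id"].astype(str)
    return tab


def read_contrast_images(image_table: pd.DataFrame, mask_path,
                         subject_order) -> VoxelDataset:
    """Load per-subject contrast images into a VoxelDataset.

    Every image must match the mask's shape and affine (affine entries
    to within 1e-4).  Voxels that are NaN in any subject are removed
    from the mask with a logged count.  Rows follow ``subject_order``.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.get_fdata()) != 0
    affine = mask_img.affine
    by_id = dict(zip(image_table["subject_id"], image_table["path"]))
    ids = [str(s) for s in subject_order]
    missing = sorted(set(ids) - set(by_id))
    if missing:
        raise AlignmentError(f"no image listed for subjects: {missing}")

    problems = []
    rows = []
    for sid in ids:
        p = Path(by_id[sid])
        if not p.exists():
            problems.append(f"{sid}: file not found: {p}")
            continue
        img = nib.load(str(p))
        if img.shape != mask_img.shape:
            problems.append(f"{sid}: shape {img.shape} != mask {mask_img.shape}")
            continue
        if not np.allclose(img.affine, affine, atol=AFFINE_ATOL):
            problems.append(f"{sid}: affine differs from mask beyond {AFFINE_ATOL}")
            continue
        rows.append(np.asarray(img.get_fdata())[mask])
    if problems:
        raise InsufficientDataError(
            "contrast images failed validation:\n  " + "\n  ".join(problems))

    data = np.vstack(rows)
    nan_cols = np.isnan(data).any(axis=0)
    if nan_cols.any():
        logger.info("removing %d voxels with NaN in at least one subject",
                    int(nan_cols.sum()))
        keep3d = mask.copy()
        keep3d[mask] = ~nan_cols
        mask = keep3d
        data = data[:, ~nan_cols]
    return VoxelDataset(data=data, mask=mask, affine=affine,
                        subject_ids=tuple(ids))


def write_contrast_images(dataset: VoxelDataset, out_dir) -> pd.DataFrame:
    """Write one NIfTI per subject plus the mask; returns the image list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(dataset.mask.astype(np.int16), dataset.affine),
             str(out / "mask.nii.gz"))
    records = []
    for i, sid in enumerate(dataset.subject_ids):
        vol = np.zeros(dataset.mask.shape, dtype=np.float64)
        vol[dataset.mask] = dataset.data[i]
        p = out / f"{sid}_contrast.nii.gz"
        nib.save(nib.Nifti1Image(vol, dataset.affine), str(p))
        records.append({"subject_id": sid, "path": str(p)})
    return pd.DataFrame(records)


def write_stat_maps(maps: StatMapSet, out_dir) -> dict[str, Path]:
    """One NIfTI per statistic map; out-of-mask voxels are 0.

    The input affine propagates verbatim to every output header; the
    model_label map is written as an integer volume.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in maps.maps:
        vol = maps.volume(name, fill=0.0)
        if name == "model_label":
            img = nib.Nifti1Image(np.nan_to_num(vol).astype(np.int16),
                                  maps.affine)
        else:
            img = nib.Nifti1Image(vol, maps.affine)
        path = out / f"{name}.nii.gz"
        nib.save(img, str(path))
        written[name] = path
    nib.save(nib.Nifti1Image(maps.mask.astype(np.int16), maps.affine),
             str(out / "analysis_mask.nii.gz"))
    written["analysis_mask"] = out / "analysis_mask.nii.gz"
    return written


def read_stat_maps(map_dir) -> StatMapSet:
    """Rebuild a StatMapSet from a directory written by write_stat_maps."""
    d = Path(map_dir)
    mask_img = nib.load(str(d / "analysis_mask.nii.gz"))
    mask = np.asarray(mask_img.get_fdata()) != 0
    maps = {}
    for name in MAP_FIELDS:
        p = d / f"{name}.nii.gz"
        if p.exists():
            maps[name] = np.asarray(nib.load(str(p)).get_fdata())[mask]
    if not maps:
        raise InsufficientDataError(f"no statistic maps found under {d}")
    return StatMapSet(mask=mask, affine=mask_img.affine, maps=maps)


_CONFIG_KEYS = {"height_alpha", "extent_threshold", "connectivity",
                "rounding", "bootstrap"}
_BOOTSTRAP_KEYS = {"n_resamples", "alpha", "ci_method", "seed"}


def validate_config(raw: dict | None) -> AnalysisConfig:
    """Build an AnalysisConfig from a parsed mapping; unknown keys rejected."""
    raw = dict(raw or {})
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; allowed: {sorted(_CONFIG_KEYS)}")
    boot_raw = dict(raw.pop("bootstrap", {}) or {})
    unknown = set(boot_raw) - _BOOTSTRAP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown bootstrap keys {sorted(unknown)}; allowed: {sorted(_BOOTSTRAP_KEYS)}")
    try:
        bootstrap = BootstrapSettings(**boot_raw)
    except ValueError as err:
        raise ConfigError(
            f"invalid bootstrap settings ({err}); n_resamples >= 100, "
            f"0 < alpha < 1, ci_method in {CI_METHODS}") from err
    try:
        return AnalysisConfig(bootstrap=bootstrap, **raw)
    except (ValueError, TypeError) as err:
        raise ConfigError(str(err)) from err


def read_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def serialize_config(config: AnalysisConfig) -> str:
    d = {
        "height_alpha": config.height_alpha,
        "extent_threshold": config.extent_threshold,
        "connectivity": config.connectivity,
        "rounding": config.rounding,
        "bootstrap": {
            "n_resamples": config.bootstrap.n_resamples,
            "alpha": config.bootstrap.alpha,
            "ci_method": config.bootstrap.ci_method,
            "seed": config.bootstrap.seed,
        },
    }
    return yaml.safe_dump(d, sort_keys=False)


def with_seed(config: AnalysisConfig, seed: int) -> AnalysisConfig:
    """Copy of the config with the bootstrap seed replaced."""
    return replace(config, bootstrap=replace(config.bootstrap, seed=seed))
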