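"""Voxel-wise sweep of the path models over an in-mask data matrix.

Every in-mask voxel gets the same treatment: fit the mediator equation
(B on group), fit the moderated outcome equation (C on B, group and
their interaction), arbitrate — if the interaction is not significant at
the height threshold the model degenerates to simple mediation and is
refit without the interaction — then bootstrap the conditional indirect
effects of the selected model using a single resample plan shared by all
voxels.  Within-group one-sample t statistics of the contrast ("dual >
single" simple effects) are computed alongside.

The original-data fits are vectorised across voxels (the design shares
its group column; only the brain column differs per voxel), and the
bootstrap refits are vectorised across resamples within each voxel.
Voxels are independent work units: any processing order yields identical
maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import (
    BootstrapSettings,
    ResamplePlan,
    bc_interval,
    indirect_draws,
    make_resample_plan,
    percentile_interval,
)
from .exceptions import AlignmentError, ConfigError, InsufficientDataError
from .paths import OLD, YOUNG, OutcomeFit

logger = logging.getLogger(__name__)

MODEL_DEGENERATE = 0
MODEL_MODERATED = 1
MODEL_SIMPLE = 2

#: flat per-voxel statistic maps carried by a StatMapSet
MAP_FIELDS = (
    "a", "a_t", "a_p",
    "b", "b_t", "b_p",
    "c_prime", "c_prime_t", "c_prime_p",
    "v", "v_t", "v_p",
    "ind_young", "ind_old",
    "ci_young_lower", "ci_young_upper",
    "ci_old_lower", "ci_old_upper",
    "dual_young_t", "dual_old_t",
    "model_label", "n_dropped",
)


@dataclass(frozen=True)
class VoxelDataset:
    """Subjects-by-voxels contrast matrix plus its spatial bookkeeping."""

    data: np.ndarray            # (n_subjects, n_voxels)
    mask: np.ndarray            # 3-D boolean
    affine: np.ndarray          # 4x4 voxel-index -> mm
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        if self.data.shape[1] != int(np.count_nonzero(self.mask)):
            raise InsufficientDataError(
                "data columns must match the in-mask voxel count")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ConfigError("affine must be invertible")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_index_map(self) -> np.ndarray:
        """(n_voxels, 3) array of 0-based (i, j, k) per data column."""
        return np.argwhere(self.mask)


@dataclass
class StatMapSet:
    """Per-voxel result maps over the analysis mask."""

    mask: np.ndarray
    affine: np.ndarray
    maps: dict[str, np.ndarray] = field(default_factory=dict)

    def volume(self, name: str, fill: float = 0.0) -> np.ndarray:
        """Embed a flat map into the 3-D mask geometry."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.maps[name]
        return vol

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and bootstrap settings for a whole-brain run."""

    height_alpha: float = 0.05
    extent_threshold: int = 50
    connectivity: int = 18
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    rounding: int = 3

    def __post_init__(self):
        if not 0.0 < self.height_alpha < 1.0:
            raise ConfigError("height_alpha must be in (0, 1)")
        if self.extent_threshold < 1:
            raise ConfigError("extent_threshold must be at least 1")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")


def arbitrate_model(moderated_fit: OutcomeFit, height_alpha: float) -> Literal["moderated", "simple", "degenerate"]:
    """Keep the interaction only when it is significant (strict p < alpha)."""
    if moderated_fit.kind != "moderated":
        raise ValueError("arbitration requires a moderated fit")
    if moderated_fit.degenerate:
        return "degenerate"
    if moderated_fit.v.p_value < height_alpha:
        return "moderated"
    return "simple"


# ---------------------------------------------------------------------------
# batched original-data fits


def _batch_outcome(A: np.ndarray, data: np.ndarray, C: np.ndarray,
                   moderated: bool) -> dict[str, np.ndarray]:
    """Fit the outcome equation at every voxel at once.

    Assembles per-voxel normal equations from column sums (the group and
    performance vectors are shared; only B differs per voxel) and solves
    them as a batch.  Returns estimate/se/t/p arrays for b, c' (and v),
    plus r_squared and a validity flag.
    """
    n, V = data.shape
    old = A == OLD
    n_o = int(old.sum())
    B = data
    Sb = B.sum(axis=0)
    Sbb = np.einsum("ij,ij->j", B, B)
    Sab = B[old].sum(axis=0)
    Sabb = np.einsum("ij,ij->j", B[old], B[old])
    Sc = float(C.sum())
    Scc = float(C @ C)
    Sac = float(C[old].sum())
    Sbc = B.T @ C
    Sabc = B[old].T @ C[old]

    if moderated:
        p = 4
        XtX = np.empty((V, 4, 4))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = Sb
        XtX[:, 0, 2] = XtX[:, 2, 0] = n_o
        XtX[:, 0, 3] = XtX[:, 3, 0] = Sab
        XtX[:, 1, 1] = Sbb
        XtX[:, 1, 2] = XtX[:, 2, 1] = Sab
        XtX[:, 1, 3] = XtX[:, 3, 1] = Sabb
        XtX[:, 2, 2] = n_o
        XtX[:, 2, 3] = XtX[:, 3, 2] = Sab
        XtX[:, 3, 3] = Sabb
        Xty = np.stack([np.full(V, Sc), Sbc, np.full(V, Sac), Sabc], axis=1)
    else:
        p = 3
        XtX = np.empty((V, 3, 3))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = Sb
        XtX[:, 0, 2] = XtX[:, 2, 0] = n_o
        XtX[:, 1, 1] = Sbb
        XtX[:, 1, 2] = XtX[:, 2, 1] = Sab
        XtX[:, 2, 2] = n_o
        Xty = np.stack([np.full(V, Sc), Sbc, np.full(V, Sac)], axis=1)

    diag = np.einsum("vii->vi", XtX)
    scale = np.prod(np.maximum(np.abs(diag), 1e-300), axis=1)
    det = np.linalg.det(XtX)
    good = np.abs(det) > 1e-12 * scale

    beta = np.full((V, p), np.nan)
    se = np.full((V, p), np.nan)
    rss = np.full(V, np.nan)
    if good.any():
        beta[good] = np.linalg.solve(XtX[good], Xty[good][..., None])[..., 0]
        rss_g = Scc - np.einsum("vi,vi->v", beta[good], Xty[good])
        rss[good] = np.clip(rss_g, 0.0, None)
        dof = n - p
        sigma2 = rss[good] / dof
        inv = np.linalg.inv(XtX[good])
        se[good] = np.sqrt(np.clip(
            np.einsum("vii->vi", inv) * sigma2[:, None], 0.0, None))

    dof = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t = np.where(se > 0, t, 0.0)
    pval = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), 1.0)
    tss = float(np.sum((C - C.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.zeros(V)

    out = {
        "b": beta[:, 1], "b_se": se[:, 1], "b_t": t[:, 1], "b_p": pval[:, 1],
        "c_prime": beta[:, 2], "c_prime_se": se[:, 2],
        "c_prime_t": t[:, 2], "c_prime_p": pval[:, 2],
        "r_squared": r2, "good": good, "dof": np.full(V, dof),
    }
    if moderated:
        out.update({"v": beta[:, 3], "v_se": se[:, 3],
                    "v_t": t[:, 3], "v_p": pval[:, 3]})
    return out


def _batch_mediator(A: np.ndarray, data: np.ndarray) -> dict[str, np.ndarray]:
    """Fit B = b0 + a*A at every voxel: a is the old-young mean difference."""
    n, V = data.shape
    young, old = A == YOUNG, A == OLD
    n_y, n_o = int(young.sum()), int(old.sum())
    mean_y = data[young].mean(axis=0)
    mean_o = data[old].mean(axis=0)
    a = mean_o - mean_y
    resid = data.copy()
    resid[young] -= mean_y
    resid[old] -= mean_o
    dof = n - 2
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 * (1.0 / n_y + 1.0 / n_o))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, a / se, 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), np.where(a == 0, 1.0, 0.0))
    return {"a": a, "a_se": se, "a_t": t, "a_p": p}


def _group_one_sample_t(data: np.ndarray) -> np.ndarray:
    """One-sample t of the contrast against 0, per voxel."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def align_covariates(covariates: pd.DataFrame, subject_ids) -> pd.DataFrame:
    """Reorder the covariate table to match the dataset's subject order.

    Alignment is strictly by subject id; row order in either input never
    matters.  Raises :class:`AlignmentError` listing offenders.
    """
    tab = covariates.set_index(covariates["subject_id"].astype(str))
    ids = [str(s) for s in subject_ids]
    if tab.index.has_duplicates:
        dups = sorted(tab.index[tab.index.duplicated()].unique())
        raise AlignmentError(f"duplicate subject ids: {dups}")
    missing = sorted(set(ids) - set(tab.index))
    extra = sorted(set(tab.index) - set(ids))
    if missing or extra:
        raise AlignmentError(
            f"subject ids do not align: missing from table {missing}, "
            f"not in dataset {extra}")
    return tab.loc[ids]


def run_voxelwise(dataset: VoxelDataset, covariates: pd.DataFrame,
                  config: AnalysisConfig,
                  plan: ResamplePlan | None = None) -> StatMapSet:
    """Run the full per-voxel moderated-mediation analysis.

    ``covariates`` needs columns subject_id, group (0/1) and
    performance.  A single stratified resample plan (created here from
    the bootstrap seed unless supplied) is shared across all voxels.
    """
    tab = align_covariates(covariates, dataset.subject_ids)
    A = tab["group"].to_numpy(dtype=float)
    C = tab["performance"].to_numpy(dtype=float)
    if not np.isin(A, (YOUNG, OLD)).all():
        raise AlignmentError("group codes must be 0 (young) or 1 (old)")
    data = np.asarray(dataset.data, dtype=float)
    n, V = data.shape
    if V == 0:
        raise InsufficientDataError("mask selects no voxels")

    if plan is None:
        plan = make_resample_plan(A, config.bootstrap)

    med = _batch_mediator(A, data)
    mod = _batch_outcome(A, data, C, moderated=True)
    simp = _batch_outcome(A, data, C, moderated=False)

    # arbitration: moderated iff the interaction is significant (strict <)
    label = np.full(V, MODEL_DEGENERATE, dtype=int)
    is_mod = mod["good"] & (mod["v_p"] < config.height_alpha)
    is_simp = mod["good"] & ~is_mod & simp["good"]
    label[is_mod] = MODEL_MODERATED
    label[is_simp] = MODEL_SIMPLE
    n_degen = int(np.count_nonzero(label == MODEL_DEGENERATE))
    if n_degen:
        logger.info("flagged %d/%d voxels as degenerate", n_degen, V)

    # coefficient maps follow the selected model per voxel
    b = np.where(is_mod, mod["b"], simp["b"])
    b_t = np.where(is_mod, mod["b_t"], simp["b_t"])
    b_p = np.where(is_mod, mod["b_p"], simp["b_p"])
    c_prime = np.where(is_mod, mod["c_prime"], simp["c_prime"])
    c_prime_t = np.where(is_mod, mod["c_prime_t"], simp["c_prime_t"])
    c_prime_p = np.where(is_mod, mod["c_prime_p"], simp["c_prime_p"])
    # interaction maps always report the moderated fit (what arbitration
    # saw); the indirect effect uses v only where the moderated model won
    v_eff = np.where(is_mod, mod["v"], 0.0)

    ind_young = med["a"] * b
    ind_old = med["a"] * (b + v_eff)

    ci = {k: np.full(V, np.nan) for k in
          ("ci_young_lower", "ci_young_upper", "ci_old_lower", "ci_old_upper")}
    n_dropped = np.zeros(V, dtype=int)
    settings = config.bootstrap
    max_bad = 0.01 * plan.n_resamples
    active = np.flatnonzero(label != MODEL_DEGENERATE)
    for vx in active:
        kind = "moderated" if label[vx] == MODEL_MODERATED else "simple"
        dy, do, good = indirect_draws(data[:, vx], C, plan, kind)
        n_bad = int(np.count_nonzero(~good))
        if n_bad > max_bad:
            label[vx] = MODEL_DEGENERATE
            continue
        n_dropped[vx] = n_bad
        for key, draws, point in (("young", dy[good], ind_young[vx]),
                                  ("old", do[good], ind_old[vx])):
            if settings.ci_method == "percentile":
                lo, hi = percentile_interval(draws, settings.alpha)
            elif settings.ci_method == "bca":
                # jackknife over subjects is prohibitive per voxel; the
                # voxelwise engine uses BC; use bootstrap_indirect for
                # single-voxel BCa
                lo, hi, _ = bc_interval(draws, point, settings.alpha)
            else:
                lo, hi, _ = bc_interval(draws, point, settings.alpha)
            ci[f"ci_{key}_lower"][vx] = lo
            ci[f"ci_{key}_upper"][vx] = hi

    young_mask, old_mask = A == YOUNG, A == OLD
    maps = {
        "a": med["a"], "a_t": med["a_t"], "a_p": med["a_p"],
        "b": b, "b_t": b_t, "b_p": b_p,
        "c_prime": c_prime, "c_prime_t": c_prime_t, "c_prime_p": c_prime_p,
        "v": np.where(mod["good"], mod["v"], 0.0),
        "v_t": np.where(mod["good"], mod["v_t"], 0.0),
        "v_p": np.where(mod["good"], mod["v_p"], 1.0),
        "ind_young": ind_young, "ind_old": ind_old,
        **ci,
        "dual_young_t": _group_one_sample_t(data[young_mask]),
        "dual_old_t": _group_one_sample_t(data[old_mask]),
        "model_label": label.astype(float),
        "n_dropped": n_dropped.astype(float),
    }
    # degenerate voxels carry no inference
    degen = label == MODEL_DEGENERATE
    for key in ("ind_young", "ind_old", "ci_young_lower", "ci_young_upper",
                "ci_old_lower", "ci_old_upper"):
        maps[key] = np.where(degen, np.nan, maps[key])
    return StatMapSet(mask=np.asarray(dataset.mask, dtype=bool),
                      affine=np.asarray(dataset.affine, dtype=float),
                      maps=maps)


def _ci_significant(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (lower > 0.0) | (upper < 0.0)


def exclusive_partition(maps: StatMapSet, config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Split voxels into the two mutually exclusive significant sets.

    Moderated-mediation voxels have a significant interaction (that is
    what selected the moderated model) and a significant indirect effect
    in at least one group.  Mediation voxels carry the simple model with
    a significant indirect effect and are additionally masked against
    the moderated set, so the two flat boolean masks never intersect.
    """
    label = maps["model_label"]
    sig_y = _ci_significant(maps["ci_young_lower"], maps["ci_young_upper"])
    sig_o = _ci_significant(maps["ci_old_lower"], maps["ci_old_upper"])
    moderated = (label == MODEL_MODERATED) & \
        (maps["v_p"] < config.height_alpha) & (sig_y | sig_o)
    mediation = (label == MODEL_SIMPLE) & (sig_y | sig_o) & ~moderated
    return moderated, mediation
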