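"""Synthetic cohorts with known ground-truth path coefficients.

The generator instantiates the structural model directly: per voxel,
brain activity is B = b0 + a*A + smoothed noise; performance is driven
by a designated region, C = b0 + c'*A + (b + v*A)*B_driver + noise.
Effect regions are hard-edged spheres (only the noise field is
smoothed), so the truth maps are exact at every voxel and parameter
recovery at region peaks is unbiased.  The driver readout is the B
value at the driver region's center voxel: a region-mean readout would
make any single voxel a noisy proxy for the generative variable and
attenuate its fitted coefficients, leaving no voxel where the nominal
truth holds.

Defaults mirror the study conditions: 39 young and 45 old subjects, one
~75-voxel effect region with a = 0.625, b = -0.021, v = 0.109 and
c' = 0.041 (magnitudes of the superior-frontal peak of the reference
moderated-mediation table), group switch costs near 0.22 s (young) and
0.29 s (old), and a smoothed unit-variance noise field emulating the
8 mm FWHM smoothing of preprocessed 4 mm-scale contrast images on a
scaled-down 10x10x10 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import TRIAL_DEADLINE_S
from .engine import VoxelDataset
from .exceptions import ConfigError

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class EffectRegion:
    """A spherical patch of true path coefficients."""

    center: tuple[int, int, int]
    radius: float
    a: float
    b: float
    v: float


@dataclass(frozen=True)
class SynthSpec:
    """Everything needed to generate one synthetic cohort."""

    n_young: int = 39
    n_old: int = 45
    volume_shape: tuple[int, int, int] = (10, 10, 10)
    voxel_size_mm: float = 4.0
    effect_regions: tuple[EffectRegion, ...] = (
        EffectRegion(center=(4, 4, 4), radius=2.6, a=0.625, b=-0.021, v=0.109),
    )
    driver_region: int = 0
    c_prime: float = 0.041
    brain_intercept: float = -0.45
    performance_intercept: float = 0.21
    noise_sd: float = 1.0
    smooth_fwhm_vox: float = 2.0
    performance_noise_sd: float = 0.09
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0 or self.performance_noise_sd <= 0:
            raise ConfigError("noise standard deviations must be positive")
        shape = np.asarray(self.volume_shape)
        for region in self.effect_regions:
            c = np.asarray(region.center)
            if ((c - region.radius < 0) | (c + region.radius >= shape)).any():
                raise ConfigError(f"effect region at {region.center} leaves the volume")
        if self.effect_regions and not (
                0 <= self.driver_region < len(self.effect_regions)):
            raise ConfigError("driver_region must index an effect region")

    @property
    def affine(self) -> np.ndarray:
        """Voxel->mm transform centered on the volume."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -0.5 * (np.asarray(self.volume_shape) - 1) * self.voxel_size_mm
        return aff


@dataclass(frozen=True)
class TruthMaps:
    """Generative per-voxel coefficients; zero outside effect regions."""

    a: np.ndarray
    b: np.ndarray
    v: np.ndarray


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def truth_maps(spec: SynthSpec) -> TruthMaps:
    shape = spec.volume_shape
    a = np.zeros(shape)
    b = np.zeros(shape)
    v = np.zeros(shape)
    for region in spec.effect_regions:
        m = _sphere_mask(shape, region.center, region.radius)
        a[m], b[m], v[m] = region.a, region.b, region.v
    return TruthMaps(a=a, b=b, v=v)


def _smoothing_norm(sigma: float) -> float:
    """Factor by which separable Gaussian smoothing shrinks a white field's sd."""
    if sigma <= 0:
        return 1.0
    radius = int(4.0 * sigma + 0.5) + 1
    impulse = np.zeros(2 * radius + 1)
    impulse[radius] = 1.0
    kernel = ndimage.gaussian_filter1d(impulse, sigma, mode="constant")
    return float(np.sqrt(np.sum(kernel**2)) ** 3)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    """Spatially correlated noise rescaled to per-voxel standard deviation sd.

    Wrap-mode filtering keeps the field stationary; the rescaling undoes
    the variance shrinkage of the convolution so ``sd`` is the effective
    marginal sd.
    """
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return sd * white
    smoothed = ndimage.gaussian_filter(white, sigma, mode="wrap")
    return sd * smoothed / _smoothing_norm(sigma)


def generate_cohort(spec: SynthSpec) -> tuple[pd.DataFrame, VoxelDataset, TruthMaps]:
    """Generate (subject table, voxel dataset, truth maps) for one cohort.

    Deterministic in ``spec.seed``.  The subject table carries the group
    code and the performance value (switch cost, seconds); the dataset
    holds one contrast image per subject over a full-volume mask.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_young + spec.n_old
    A = np.concatenate([np.zeros(spec.n_young), np.ones(spec.n_old)])
    truth = truth_maps(spec)
    shape = spec.volume_shape
    sigma = spec.smooth_fwhm_vox * FWHM_TO_SIGMA

    volumes = np.empty((n,) + tuple(shape))
    for i in range(n):
        noise = _smooth_noise(rng, shape, sigma, spec.noise_sd)
        volumes[i] = spec.brain_intercept + truth.a * A[i] + noise

    if spec.effect_regions:
        driver_center = spec.effect_regions[spec.driver_region].center
        driver = spec.effect_regions[spec.driver_region]
        b_driver = volumes[(slice(None),) + tuple(driver_center)]
        slope = driver.b + driver.v * A
    else:
        b_driver = np.zeros(n)
        slope = np.zeros(n)
    C = (spec.performance_intercept + spec.c_prime * A + slope * b_driver
         + rng.normal(0.0, spec.performance_noise_sd, size=n))

    subject_ids = tuple(f"sub-{i + 1:03d}" for i in range(n))
    table = pd.DataFrame({
        "subject_id": subject_ids,
        "group": A.astype(int),
        "performance": C,
    })
    mask = np.ones(shape, dtype=bool)
    dataset = VoxelDataset(
        data=volumes.reshape(n, -1)[:, mask.ravel()],
        mask=mask, affine=spec.affine, subject_ids=subject_ids)
    return table, dataset, truth


#: reference condition medians, per-subject switch costs and accuracies.
#: the mean per-subject cost is a separate target from the difference of
#: condition medians (medians do not subtract), so it is stated explicitly
DEFAULT_PERFORMANCE_TARGETS = {
    0: {"median_single": 0.69, "cost": 0.22,
        "acc_single": 0.94, "acc_switch": 0.92,
        "sd_single": 0.079, "sd_cost": 0.093},
    1: {"median_single": 0.82, "cost": 0.29,
        "acc_single": 0.90, "acc_switch": 0.83,
        "sd_single": 0.14, "sd_cost": 0.16},
}

TRIALS_PER_CONDITION = 144  # 12 blocks of 12 trials
NOGO_FRACTION = 1.0 / 6.0
RT_LOG_SD = 0.25


def generate_trials(spec: SynthSpec,
                    performance_targets: dict | None = None) -> pd.DataFrame:
    """Trial-level data whose correct-trial medians recover the targets.

    Each subject gets a latent single-task median and switch cost drawn
    around the group targets; trial RTs are lognormal about the latent
    median, and any draw beyond the 1.9 s deadline becomes a no-response
    trial.  No-go trials are marked and are correct exactly when no
    response was made.
    """
    targets = performance_targets or DEFAULT_PERFORMANCE_TARGETS
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_young + spec.n_old
    A = np.concatenate([np.zeros(spec.n_young, dtype=int),
                        np.ones(spec.n_old, dtype=int)])
    rows = []
    for i in range(n):
        g = targets[int(A[i])]
        if g["median_single"] + g["cost"] >= TRIAL_DEADLINE_S:
            raise ConfigError("target medians must lie below the trial deadline")
        m_single = max(0.2, rng.normal(g["median_single"], g["sd_single"]))
        cost = rng.normal(g["cost"], g["sd_cost"])
        sid = f"sub-{i + 1:03d}"
        for cond, med, acc in (("single", m_single, g["acc_single"]),
                               ("switch", m_single + cost, g["acc_switch"])):
            med = float(np.clip(med, 0.2, TRIAL_DEADLINE_S - 0.05))
            for t in range(TRIALS_PER_CONDITION):
                is_nogo = rng.random() < NOGO_FRACTION
                if is_nogo:
                    withheld = rng.random() < 0.95
                    rows.append({"subject_id": sid, "group": int(A[i]),
                                 "condition": cond, "trial": t,
                                 "rt": np.nan if withheld else med,
                                 "correct": withheld, "is_nogo": True})
                    continue
                rt = med * np.exp(RT_LOG_SD * rng.standard_normal())
                if rt > TRIAL_DEADLINE_S:
                    rows.append({"subject_id": sid, "group": int(A[i]),
                                 "condition": cond, "trial": t, "rt": np.nan,
                                 "correct": False, "is_nogo": False})
                else:
                    rows.append({"subject_id": sid, "group": int(A[i]),
                                 "condition": cond, "trial": t, "rt": rt,
                                 "correct": bool(rng.random() < acc),
                                 "is_nogo": False})
    return pd.DataFrame(rows)


def spec_to_dict(spec: SynthSpec) -> dict:
    """Serializable form of a SynthSpec (for YAML round-tripping)."""
    d = asdict(spec)
    d["volume_shape"] = list(spec.volume_shape)
    d["effect_regions"] = [
        {"center": list(r.center), "radius": r.radius,
         "a": r.a, "b": r.b, "v": r.v}
        for r in spec.effect_regions]
    return d


def spec_from_dict(d: dict) -> SynthSpec:
    d = dict(d)
    allowed = set(SynthSpec.__dataclass_fields__)
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown SynthSpec keys: {sorted(unknown)}")
    if "volume_shape" in d:
        d["volume_shape"] = tuple(int(x) for x in d["volume_shape"])
    if "effect_regions" in d:
        d["effect_regions"] = tuple(
            EffectRegion(center=tuple(int(x) for x in r["center"]),
                         radius=float(r["radius"]), a=float(r["a"]),
                         b=float(r["b"]), v=float(r["v"]))
            for r in d["effect_regions"])
    return SynthSpec(**d)
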