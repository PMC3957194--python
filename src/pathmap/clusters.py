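"""Height+extent thresholding, 3-D component labeling and cluster tables.

Suprathreshold voxels are grouped into connected components under a
configurable neighborhood (6, 18 or 26; default 18, the convention of
the SPM software family), components smaller than the extent threshold
are discarded, and survivors are reported with their peak statistics and
peak coordinates in template-space millimeters via the image affine.
Sub-peaks are local maxima at least 8 mm apart, the common reporting
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .engine import AnalysisConfig, StatMapSet

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

ModelFamily = Literal["moderated_mediation", "mediation"]


@dataclass(frozen=True)
class Peak:
    """One local maximum within a cluster."""

    voxel: tuple[int, int, int]
    mm: tuple[float, float, float]
    value: float


@dataclass(frozen=True)
class Cluster:
    """A suprathreshold connected component with its peak statistics."""

    label: int
    size: int
    peak: Peak
    sub_peaks: tuple[Peak, ...]
    peak_stats: dict[str, float]


@dataclass
class ClusterTable:
    """Table-style summary of all surviving clusters of one family."""

    model_family: ModelFamily
    rows: list[Cluster]
    extent_threshold: int
    connectivity: int
    height_alpha: float
    maps: StatMapSet | None = field(default=None, repr=False)

    def to_dataframe(self, rounding: int = 3,
                     region_lookup: Callable[[tuple[float, float, float]], str] | None = None
                     ) -> pd.DataFrame:
        """Flatten peaks and sub-peaks into one row per reported locus."""
        records = []
        for cluster in self.rows:
            for rank, peak in enumerate((cluster.peak, *cluster.sub_peaks)):
                rec = {
                    "region": region_lookup(peak.mm) if region_lookup else "",
                    "x": peak.mm[0], "y": peak.mm[1], "z": peak.mm[2],
                    "cluster_size": cluster.size if rank == 0 else np.nan,
                    "is_subpeak": rank > 0,
                }
                stats = cluster.peak_stats if rank == 0 else (
                    _stats_at(self.maps, peak.voxel) if self.maps is not None else {})
                rec.update({k: (round(val, rounding)
                                if isinstance(val, float) and np.isfinite(val) else val)
                            for k, val in stats.items()})
                records.append(rec)
        if not records:
            return pd.DataFrame(columns=[
                "region", "x", "y", "z", "cluster_size", "is_subpeak",
                *_PEAK_STAT_FIELDS, "ind_young_sig", "ind_old_sig"])
        return pd.DataFrame.from_records(records)

    def write_tsv(self, path, rounding: int = 3) -> None:
        self.to_dataframe(rounding=rounding).to_csv(path, sep="\t", index=False)


def connected_components(binary_volume, connectivity: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components; labels dense from 1.

    Returns (labeled volume, sizes) where sizes[i] is the voxel count of
    label i+1.
    """
    vol = np.asarray(binary_volume, dtype=bool)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    labeled, n = ndimage.label(vol, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labeled.ravel(), minlength=n + 1)[1:]
    return labeled, sizes


def voxel_to_mm(affine: np.ndarray, voxel) -> tuple[float, float, float]:
    """Apply the affine to a 0-based (i, j, k) voxel index."""
    ijk1 = np.append(np.asarray(voxel, dtype=float), 1.0)
    return tuple(float(x) for x in (affine @ ijk1)[:3])


def mm_to_voxel(affine: np.ndarray, mm) -> tuple[int, int, int]:
    """Invert the affine back to the nearest 0-based voxel index."""
    xyz1 = np.append(np.asarray(mm, dtype=float), 1.0)
    ijk = np.linalg.solve(affine, xyz1)[:3]
    return tuple(int(round(x)) for x in ijk)


def localize_peaks(cluster_mask: np.ndarray, stat_volume: np.ndarray,
                   affine: np.ndarray, min_separation_mm: float = 8.0
                   ) -> tuple[Peak, list[Peak]]:
    """Find the global peak and well-separated sub-peaks of one cluster.

    The peak maximizes |stat| over the cluster.  Sub-peaks are local
    maxima of |stat| (26-neighborhood, restricted to the cluster) kept
    greedily in descending order subject to a minimum millimeter
    separation from every already-kept locus.
    """
    mask = np.asarray(cluster_mask, dtype=bool)
    stat = np.where(mask, np.abs(stat_volume), -np.inf)
    # strict local maxima: value above every 26-neighbor (plateaus of tied
    # values are not peaks; t-maps are continuous so ties are degenerate)
    footprint = _STRUCTURES[26].copy()
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(stat, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    is_max = mask & (stat > neigh_max)
    if not is_max.any():  # constant cluster: fall back to the first voxel
        first = tuple(np.argwhere(mask)[0])
        is_max[first] = True
    candidates = np.argwhere(is_max)
    order = np.argsort(-stat[is_max])
    candidates = candidates[order]

    kept: list[Peak] = []
    kept_mm: list[np.ndarray] = []
    for ijk in candidates:
        mm = np.asarray(voxel_to_mm(affine, ijk))
        if any(np.linalg.norm(mm - prev) < min_separation_mm for prev in kept_mm):
            continue
        kept.append(Peak(voxel=tuple(int(i) for i in ijk), mm=tuple(mm),
                         value=float(stat_volume[tuple(ijk)])))
        kept_mm.append(mm)
    return kept[0], kept[1:]


_PEAK_STAT_FIELDS = (
    "a", "a_p", "b", "b_p", "c_prime", "c_prime_p", "v", "v_p",
    "dual_young_t", "dual_old_t",
    "ind_young", "ind_old",
    "ci_young_lower", "ci_young_upper", "ci_old_lower", "ci_old_upper",
)


def _stats_at(maps: StatMapSet, voxel) -> dict[str, float]:
    out = {}
    for name in _PEAK_STAT_FIELDS:
        if name in maps.maps:
            out[name] = float(maps.volume(name, fill=np.nan)[tuple(voxel)])
    if np.isfinite(out.get("ci_young_lower", np.nan)):
        out["ind_young_sig"] = not (out["ci_young_lower"] <= 0.0 <= out["ci_young_upper"])
        out["ind_old_sig"] = not (out["ci_old_lower"] <= 0.0 <= out["ci_old_upper"])
    return out


def threshold_and_cluster(sig_mask: np.ndarray, maps: StatMapSet,
                          family: ModelFamily, config: AnalysisConfig) -> ClusterTable:
    """Apply the extent threshold and build the cluster table.

    ``sig_mask`` is a 3-D boolean volume (one of the exclusive partition
    masks embedded in the mask geometry).  The cluster peak maximizes
    the |interaction t| for the moderated family and the largest
    |indirect point estimate| across groups for the mediation family.
    """
    labeled, sizes = connected_components(sig_mask, config.connectivity)
    if family == "moderated_mediation":
        stat_volume = maps.volume("v_t", fill=0.0)
    else:
        iy = np.nan_to_num(maps.volume("ind_young", fill=0.0))
        io = np.nan_to_num(maps.volume("ind_old", fill=0.0))
        stat_volume = np.where(np.abs(io) >= np.abs(iy), io, iy)

    rows: list[Cluster] = []
    for lab, size in enumerate(sizes, start=1):
        if size < config.extent_threshold:
            continue
        cmask = labeled == lab
        peak, sub_peaks = localize_peaks(cmask, stat_volume, maps.affine)
        rows.append(Cluster(
            label=lab, size=int(size), peak=peak, sub_peaks=tuple(sub_peaks),
            peak_stats=_stats_at(maps, peak.voxel)))
    rows.sort(key=lambda c: -c.size)
    return ClusterTable(model_family=family, rows=rows,
                        extent_threshold=config.extent_threshold,
                        connectivity=config.connectivity,
                        height_alpha=config.height_alpha, maps=maps)
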