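"""Whole-brain information mapping: searchlight cross-classification,
Gaussian smoothing, threshold-free cluster enhancement (TFCE) and
sign-flip permutation correction.

The searchlight runs the identical normalize -> pairwise-SVM ->
cross-classify chain as the ROI analysis inside a sphere (default radius
9 mm in world coordinates) around every in-mask voxel, and assigns the
mean pairwise accuracy to the center.

TFCE integrates cluster extent and height over all thresholds:
TFCE(v) = sum_h e_h(v)^E * h^H * dh, where e_h(v) is the size of the
26-connected component containing v at threshold h. Defaults E = 0.5,
H = 2, dh = max/100 — the literature-standard parameterization. Group
correction uses sign-flip permutation of chance-centered subject maps
with the max-TFCE statistic, yielding FWE-corrected voxel p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import mvpa as _mvpa
from .mvpa import LabelMap, get_scheme
from .roi import CONNECTIVITY_26, PatternSet, VolumeGeometry, sphere_indices

__all__ = [
    "SearchlightMap",
    "TfceParams",
    "run_searchlight",
    "smooth_map",
    "tfce",
    "tfce_corrected_pmap",
    "cluster_table",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SearchlightMap:
    """Per-center accuracy volume; nan outside the mask / at skipped
    centers."""

    data: np.ndarray
    geometry: VolumeGeometry
    scheme: str
    mask: np.ndarray
    subject: int | None = None


def run_searchlight(train: PatternSet, test: PatternSet, scheme,
                    geometry: VolumeGeometry, mask: np.ndarray,
                    radius_mm: float = 9.0,
                    label_map: LabelMap | None = None, cost: float = 1.0,
                    normalization: str = "zscore") -> SearchlightMap:
    """Sphere-wise cross-classification over every in-mask voxel.

    ``train``/``test`` must be whole-mask pattern sets carrying
    ``voxel_indices``; each center's sphere picks the matching pattern
    columns and runs the same decoding chain as the ROI analysis. Spheres
    with fewer than 2 voxels are skipped (nan, flagged).
    """
    scheme = get_scheme(scheme)
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    if train.voxel_indices is None or test.voxel_indices is None:
        raise ValueError("pattern sets must carry voxel indices")
    if not np.array_equal(train.voxel_indices, test.voxel_indices):
        raise ValueError("train/test voxel grids differ")
    col_of = {int(v): c for c, v in enumerate(train.voxel_indices)}
    out = np.full(geometry.shape, np.nan)
    centers = np.argwhere(mask)
    for ijk in centers:
        flat = sphere_indices(ijk, radius_mm, geometry, mask)
        cols = np.array([col_of[v] for v in flat if int(v) in col_of],
                        dtype=int)
        if cols.size < 2:
            continue
        res = _mvpa.decode(train.subset_voxels(cols),
                           test.subset_voxels(cols), scheme,
                           label_map=label_map, cost=cost,
                           normalization=normalization)
        out[tuple(ijk)] = res.accuracy
    return SearchlightMap(data=out, geometry=geometry, scheme=scheme.name,
                          mask=mask)


def smooth_map(data: np.ndarray, fwhm_mm: float,
               geometry: VolumeGeometry) -> np.ndarray:
    """Gaussian smoothing with per-axis sigma = FWHM / (2 sqrt(2 ln 2)),
    converted from mm to voxels; fwhm 0 is the identity. nans are treated
    as zeros with renormalization over the valid support."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in geometry.voxel_size]
    valid = np.isfinite(data)
    filled = np.where(valid, data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / den, np.nan)
    out[~valid] = np.nan
    return out


@dataclass(frozen=True)
class TfceParams:
    E: float = 0.5
    H: float = 2.0
    dh: float | None = None      # None -> max/100
    n_steps: int = 100

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")


def tfce(stat_map: np.ndarray, params: TfceParams = TfceParams(),
         mask: np.ndarray | None = None, two_sided: bool = False) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic volume.

    Sums e^E * h^H * dh over thresholds h = dh, 2dh, ..., max. With
    ``two_sided`` the transform is applied separately to the negated map
    and subtracted, so negative clusters get negative scores.
    """
    stat = np.asarray(stat_map, dtype=float)
    if not np.isfinite(stat[np.isfinite(stat)]).all():
        raise ValueError("stat map must be finite inside the mask")
    if mask is None:
        mask = np.isfinite(stat)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(stat)

    def _one_sided(m):
        vals = np.where(mask, m, 0.0)
        vmax = vals.max(initial=0.0)
        out = np.zeros_like(vals)
        if vmax <= 0:
            return out
        dh = params.dh if params.dh is not None else vmax / params.n_steps
        import warnings
        if dh >= vmax:
            warnings.warn("dh >= map maximum: TFCE degenerates to a single "
                          "threshold step")
        h = dh
        while h <= vmax + 1e-12:
            supra = vals >= h
            lab, n = ndimage.label(supra, structure=CONNECTIVITY_26)
            if n == 0:
                break
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            out += np.where(supra,
                            sizes[lab] ** params.E * h ** params.H * dh, 0.0)
            h += dh
        return out

    result = _one_sided(stat)
    if two_sided:
        result = result - _one_sided(-stat)
    return result


def _group_tmap(maps_2d: np.ndarray) -> np.ndarray:
    """One-sample t across subjects (rows); zero-variance voxels -> 0."""
    n = maps_2d.shape[0]
    mean = maps_2d.mean(axis=0)
    sd = maps_2d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def tfce_corrected_pmap(subject_maps, params: TfceParams = TfceParams(),
                        n_perm: int = 1000, seed=0, center: float = 0.0,
                        mask: np.ndarray | None = None):
    """FWE-corrected voxel p-values by max-TFCE sign-flip permutation.

    ``subject_maps`` is a list/array of per-subject volumes (already
    chance-centered for accuracy maps, or raw contrasts vs 0); per
    iteration each subject's map is multiplied by a random sign, the group
    t-map TFCE-enhanced, and its maximum recorded. Corrected p per voxel =
    (#{max-null >= observed} + 1) / (n_perm + 1).
    """
    maps = np.asarray([np.asarray(m, dtype=float) for m in subject_maps])
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 subject maps")
    shape = maps.shape[1:]
    if mask is None:
        mask = np.all(np.isfinite(maps), axis=0)
    maps = np.where(mask, maps - center, 0.0)
    flat = maps.reshape(maps.shape[0], -1)
    t_obs = _group_tmap(flat).reshape(shape)
    tfce_obs = tfce(t_obs, params, mask=mask)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for it in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=maps.shape[0])
        t_perm = _group_tmap(flat * signs[:, None]).reshape(shape)
        max_null[it] = tfce(t_perm, params, mask=mask).max(initial=0.0)
    pmap = np.ones(shape)
    pmap[mask] = (np.array([(max_null >= v).sum() for v in
                            tfce_obs[mask]]) + 1) / (n_perm + 1)
    pmap[~mask] = np.nan
    return pmap, tfce_obs, max_null


def cluster_table(pmap: np.ndarray, stat_map: np.ndarray,
                  p_threshold: float = 0.005,
                  min_size: int = 50) -> pd.DataFrame:
    """Suprathreshold clusters (p < p_threshold, 26-connected) of at least
    ``min_size`` voxels, with size, peak statistic and peak voxel index."""
    supra = np.nan_to_num(pmap, nan=1.0) < p_threshold
    lab, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    rows = []
    for c in range(1, n + 1):
        vox = np.argwhere(lab == c)
        if vox.shape[0] < min_size:
            continue
        stats_here = stat_map[lab == c]
        peak_local = np.argmax(stats_here)
        rows.append({
            "cluster": len(rows) + 1,
            "n_voxels": int(vox.shape[0]),
            "peak_stat": float(stats_here[peak_local]),
            "peak_i": int(vox[peak_local, 0]),
            "peak_j": int(vox[peak_local, 1]),
            "peak_k": int(vox[peak_local, 2]),
            "min_p": float(np.nanmin(pmap[lab == c])),
        })
    return pd.DataFrame(rows, columns=["cluster", "n_voxels", "peak_stat",
                                       "peak_i", "peak_j", "peak_k", "min_p"])
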