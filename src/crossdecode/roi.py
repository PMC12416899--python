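"""Volume geometry, ROI masks, functional ROI definition and pattern
extraction.

All voxel data in this package are stored flattened in C order over the
grid ``geometry.shape``; 4-D NIfTI I/O converts at the boundary. Distances
(searchlight spheres) are computed in world millimetres through the affine,
so anisotropic grids are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import BetaMap, parse_regressor_name

__all__ = [
    "VolumeGeometry",
    "RoiMask",
    "PatternSet",
    "extract_patterns",
    "define_functional_roi",
    "sphere_indices",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_bold_nifti",
]

#: 26-neighbour 3-D connectivity used for all cluster operations.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid: shape, isotropic-or-not voxel size, voxel->world affine."""

    shape: tuple
    voxel_size: tuple           # mm per axis
    affine: np.ndarray = None   # 4x4; default diagonal from voxel_size

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            object.__setattr__(self, "affine", aff)
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_voxels(self):
        return int(np.prod(self.shape))

    def world_coords(self, ijk):
        """Voxel indices (n, 3) -> world mm coordinates (n, 3)."""
        ijk = np.atleast_2d(ijk)
        hom = np.hstack([ijk, np.ones((ijk.shape[0], 1))])
        return (np.asarray(self.affine) @ hom.T).T[:, :3]


@dataclass
class RoiMask:
    """Boolean voxel set on a geometry."""

    data: np.ndarray             # bool, geometry.shape
    label: str
    geometry: VolumeGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != tuple(self.geometry.shape):
            raise ValueError("mask shape does not match geometry")
        if self.n_voxels == 0:
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def n_voxels(self):
        return int(self.data.sum())

    @property
    def flat_indices(self):
        return np.flatnonzero(self.data.ravel())


@dataclass
class PatternSet:
    """Samples x voxels matrix of beta patterns, the unit of decoding.

    ``conditions`` are 1..4 ids (face id or scene category), ``runs`` the
    chunk labels, ``period`` one of cue / delay / stim / oneback_delay
    (plus the delay-split variants), ``modality`` face or scene.
    ``voxel_indices`` are flat grid indices so patterns can be reassembled
    losslessly and sliced by searchlight spheres.
    """

    X: np.ndarray
    conditions: np.ndarray
    runs: np.ndarray
    period: str
    modality: str
    roi_label: str = ""
    voxel_indices: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=int)
        self.runs = np.asarray(self.runs, dtype=int)
        if np.isnan(self.X).any():
            raise ValueError("patterns contain missing values")
        if not (self.X.shape[0] == self.conditions.size == self.runs.size):
            raise ValueError("inconsistent sample counts")

    @property
    def n_samples(self):
        return self.X.shape[0]

    @property
    def n_voxels(self):
        return self.X.shape[1]

    def subset_voxels(self, cols):
        return replace(self, X=self.X[:, cols],
                       voxel_indices=None if self.voxel_indices is None
                       else self.voxel_indices[cols])


def extract_patterns(beta_maps, roi_mask: RoiMask, period: str,
                     modality: str) -> PatternSet:
    """Extract per-run condition betas inside an ROI.

    ``beta_maps`` is the list of per-run :class:`BetaMap` (run ids are
    their positions, 1-based). One sample per run x condition regressor of
    the requested period/modality, ordered run-major then condition-minor.
    """
    idx = roi_mask.flat_indices
    if len(beta_maps) == 0:
        raise ValueError("no beta maps given")
    rows, conds, runs = [], [], []
    for r, bm in enumerate(beta_maps, start=1):
        found = []
        for name in bm.names:
            parsed = parse_regressor_name(name)
            if parsed is None:
                continue
            p, m, c = parsed
            if p == period and m == modality:
                found.append((c, name))
        if not found:
            raise ValueError(
                f"run {r}: no regressors for period={period!r} "
                f"modality={modality!r}")
        for c, name in sorted(found):
            rows.append(bm.by_name(name)[idx])
            conds.append(c)
            runs.append(r)
    return PatternSet(X=np.vstack(rows), conditions=conds, runs=runs,
                      period=period, modality=modality,
                      roi_label=roi_mask.label, voxel_indices=idx)


def define_functional_roi(contrast_map, geometry: VolumeGeometry,
                          search_region: RoiMask,
                          threshold_mode: str = "p",
                          threshold: float = 0.001,
                          lenient_threshold: float | None = 0.05,
                          label: str = "functional_roi") -> RoiMask:
    """Largest contiguous suprathreshold cluster inside a search region.

    The contrast map's voxelwise t values are thresholded either at an
    uncorrected p (``threshold_mode='p'``, using the map's df) or at a raw
    t/statistic value (``'stat'``); 26-connected components intersected
    with ``search_region``; the largest surviving cluster becomes the ROI.
    If nothing survives, the lenient threshold is tried; if that also
    yields nothing, an empty-ROI error is raised.
    """
    stat = contrast_map.t_values if getattr(contrast_map, "t_values", None) \
        is not None else contrast_map.values
    stat = np.asarray(stat, dtype=float).reshape(geometry.shape)

    def _cut(th):
        if threshold_mode == "p":
            tcrit = stats.t.ppf(1.0 - th, max(contrast_map.df, 1))
        elif threshold_mode == "stat":
            tcrit = th
        else:
            raise ValueError("threshold_mode must be 'p' or 'stat'")
        supra = (stat > tcrit) & search_region.data
        if not supra.any():
            return None
        lab, n = ndimage.label(supra, structure=CONNECTIVITY_26)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        return lab == np.argmax(sizes)

    cluster = _cut(threshold)
    if cluster is None and lenient_threshold is not None:
        cluster = _cut(lenient_threshold)
    if cluster is None:
        raise ValueError(
            f"no suprathreshold voxels for ROI {label!r}, even at the "
            f"lenient threshold")
    return RoiMask(data=cluster, label=label, geometry=geometry)


def sphere_indices(center_ijk, radius_mm: float, geometry: VolumeGeometry,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Flat indices of in-mask voxels within ``radius_mm`` of a center.

    Distances are Euclidean in world coordinates via the affine; the
    center is included and the sphere is truncated at the mask/grid
    boundary.
    """
    center_ijk = np.asarray(center_ijk, dtype=int)
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if mask is not None and not mask[tuple(center_ijk)]:
        raise ValueError(f"center {tuple(center_ijk)} outside the mask")
    # candidate offsets from voxel-size bounding box
    vs = np.asarray(geometry.voxel_size)
    half = np.floor(radius_mm / vs).astype(int)
    ranges = [np.arange(max(0, c - h), min(s, c + h + 1))
              for c, h, s in zip(center_ijk, half, geometry.shape)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(geometry.world_coords(grid)
                       - geometry.world_coords(center_ijk[None, :]), axis=1)
    grid = grid[d <= radius_mm + 1e-9]
    if mask is not None:
        keep = mask[grid[:, 0], grid[:, 1], grid[:, 2]]
        grid = grid[keep]
    return np.ravel_multi_index((grid[:, 0], grid[:, 1], grid[:, 2]),
                                geometry.shape)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_mask_nifti(mask: RoiMask, path):
    import nibabel as nib
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          np.asarray(mask.geometry.affine))
    nib.save(img, str(path))


def load_mask_nifti(path, label: str) -> RoiMask:
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    geom = VolumeGeometry(shape=data.shape,
                          voxel_size=tuple(img.header.get_zooms()[:3]),
                          affine=np.asarray(img.affine))
    return RoiMask(data=data, label=label, geometry=geom)


def save_bold_nifti(bold_2d: np.ndarray, geometry: VolumeGeometry, path):
    """Write (n_scans, n_voxels) data as a 4-D NIfTI volume."""
    import nibabel as nib
    vol = bold_2d.T.reshape(*geometry.shape, bold_2d.shape[0])
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32),
                          np.asarray(geometry.affine))
    nib.save(img, str(path))


def roi_table(masks) -> pd.DataFrame:
    """Summary table (label, voxel count) for a collection of ROI masks."""
    return pd.DataFrame(
        [{"roi": m.label, "n_voxels": m.n_voxels} for m in masks])
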