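"""Seed-based voxelwise connectivity maps and proportional thresholding.

A seed analysis takes the mean time course of a small spherical region (or
a bilateral pair pooled into one series), computes its association with
every in-mask voxel's time course under a chosen measure (wsdm, dm, or
pearson), and yields a 3D connectivity map per subject.  Because different
measures live on different scales, maps are thresholded proportionally —
retaining the top (100 - q)% of in-mask association values — rather than at
a fixed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .metrics import association

__all__ = [
    "BoldDataset",
    "SeedSpec",
    "ConnectivityMap",
    "extract_seed_series",
    "seed_map",
    "proportional_threshold",
]


@dataclass
class BoldDataset:
    """A preprocessed 4D BOLD recording with its brain mask and metadata.

    ``volume`` is (x, y, z, t); ``affine`` maps voxel indices to world
    (mm) coordinates, as stored in a NIfTI header.  The data are assumed
    already preprocessed (realigned, nuisance-regressed, band-passed);
    this package consumes, never produces, that pipeline.
    """

    volume: NDArray[np.float64]
    mask: NDArray[np.bool_]
    affine: NDArray[np.float64]
    tr_seconds: float
    subject_id: str = "sub-000"
    site_id: str = "site1"
    group: str | None = None

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.volume.ndim != 4:
            raise ValueError(f"volume must be 4D (x,y,z,t), got ndim={self.volume.ndim}")
        if self.mask.shape != self.volume.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.volume.shape[:3]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.volume.shape[3]


@dataclass(frozen=True)
class SeedSpec:
    """A named seed: one or more sphere centers (world mm) and a radius.

    Bilateral pairs are given as two centers; their in-mask voxels are
    pooled into a single mean series (one map per network).
    """

    name: str
    centers: tuple[tuple[float, float, float], ...]
    radius_mm: float = 6.0

    def __post_init__(self):
        if len(self.centers) < 1:
            raise ValueError("seed needs at least one center")
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")


@dataclass
class ConnectivityMap:
    """Per-subject 3D map of association values against a seed."""

    values: NDArray[np.float64]
    mask: NDArray[np.bool_]
    measure: str
    seed: SeedSpec | None = None
    subject_id: str = "sub-000"
    site_id: str = "site1"
    group: str | None = None
    threshold_percentile: float | None = None


def _voxel_world_coords(shape: tuple[int, int, int], affine: NDArray) -> NDArray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    homo = np.c_[idx, np.ones(len(idx))]
    return (homo @ affine.T)[:, :3]


def sphere_mask(
    shape: tuple[int, int, int],
    affine: NDArray,
    center_mm: tuple[float, float, float],
    radius_mm: float,
) -> NDArray[np.bool_]:
    """Boolean mask of voxels whose world-space centers lie within the sphere."""
    coords = _voxel_world_coords(shape, affine)
    d2 = np.sum((coords - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
    return (d2 <= radius_mm**2).reshape(shape)


def extract_seed_series(data: BoldDataset, seed: SeedSpec) -> NDArray[np.float64]:
    """Mean time course over the union of in-mask voxels of all seed spheres.

    Every sphere must intersect the brain mask; an empty intersection
    raises, naming the offending center.
    """
    union = np.zeros(data.mask.shape, dtype=bool)
    for center in seed.centers:
        sph = sphere_mask(data.mask.shape, data.affine, center, seed.radius_mm) & data.mask
        if not sph.any():
            raise ValueError(
                f"seed {seed.name!r}: sphere at {tuple(center)} mm "
                f"(r={seed.radius_mm} mm) does not intersect the brain mask"
            )
        union |= sph
    return data.volume[union].mean(axis=0)


def seed_map(data: BoldDataset, seed: SeedSpec, measure: str = "wsdm", **kwargs) -> ConnectivityMap:
    """Voxelwise association between the seed series and every in-mask voxel."""
    series = extract_seed_series(data, seed)
    values = map_against_series(data, series, measure, **kwargs)
    return ConnectivityMap(
        values=values,
        mask=data.mask.copy(),
        measure=measure,
        seed=seed,
        subject_id=data.subject_id,
        site_id=data.site_id,
        group=data.group,
    )


def map_against_series(
    data: BoldDataset, series: NDArray, measure: str, **kwargs
) -> NDArray[np.float64]:
    """Association of one reference series with every in-mask voxel series."""
    values = np.zeros(data.mask.shape)
    flat_idx = np.flatnonzero(data.mask.ravel())
    voxels = data.volume.reshape(-1, data.n_volumes)
    out = np.empty(flat_idx.size)
    for k, i in enumerate(flat_idx):
        out[k] = association(series, voxels[i], measure, **kwargs).value
    values.ravel()[flat_idx] = out
    return values


def proportional_threshold(cmap: ConnectivityMap, percentile: float) -> ConnectivityMap:
    """Zero in-mask values strictly below the q-th percentile of in-mask values.

    The percentile is computed over in-mask voxels only (association values
    exist nowhere else); values equal to the cutoff are retained, so an
    all-constant map survives intact and re-thresholding at the same
    percentile is idempotent.  Retains ~(100 - q)% of in-mask voxels.
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError(f"percentile must lie in [0, 100), got {percentile}")
    inmask = cmap.values[cmap.mask]
    cutoff = np.percentile(inmask, percentile) if percentile > 0 else -np.inf
    values = cmap.values.copy()
    values[cmap.mask & (cmap.values < cutoff)] = 0.0
    return replace_map(cmap, values=values, threshold_percentile=percentile)


def replace_map(cmap: ConnectivityMap, **changes) -> ConnectivityMap:
    fields = dict(
        values=cmap.values,
        mask=cmap.mask,
        measure=cmap.measure,
        seed=cmap.seed,
        subject_id=cmap.subject_id,
        site_id=cmap.site_id,
        group=cmap.group,
        threshold_percentile=cmap.threshold_percentile,
    )
    fields.update(changes)
    return ConnectivityMap(**fields)
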