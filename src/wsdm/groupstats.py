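"""Group-level statistics on connectivity maps.

One-sample t-maps display a group's connectivity against zero (with
family-wise correction and a cluster-extent filter); two-sample t-maps test
hypo-connectivity in patients against controls (one-sided, uncorrected
p < 0.001, extent >= 30 voxels); conjunction intersects significance masks
across acquisition sites; and the reproducibility metric correlates paired
voxel T-values between two sites' maps, with an OLS slope whose difference
across measures is testable.

Family-wise correction here is Bonferroni over in-mask voxels by default,
with a sign-flip max-T permutation option; both are exact-level under
their assumptions and depend on nothing beyond the maps themselves.
Connected components use 26-connectivity, the common convention for 3D
cluster extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage, stats

from .seedmap import ConnectivityMap

__all__ = [
    "GroupStatMap",
    "ReproducibilityResult",
    "one_sample_tmap",
    "two_sample_tmap",
    "conjunction",
    "reproducibility",
    "compare_slopes",
    "extent_filter",
]

_T_CAP = 1e6  # stands in for +/- infinity at zero-variance voxels
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GroupStatMap:
    """Voxelwise t-statistics with a post-threshold significance mask."""

    t_values: NDArray[np.float64]
    df: int
    significant: NDArray[np.bool_]
    mask: NDArray[np.bool_]
    contrast: str
    alpha: float
    extent: int


@dataclass(frozen=True)
class ReproducibilityResult:
    """Cross-site consistency of two t-maps over their joint in-mask voxels.

    ``rho`` is Spearman by default (the measure's scale-free choice);
    ``slope``/``slope_se`` come from the OLS regression of map-2 T-values
    on map-1 T-values and feed the slope-comparison test.
    """

    rho: float
    p_value: float
    slope: float
    slope_se: float
    intercept: float
    n_voxels: int
    method: str = "spearman"


def _stack(maps: list[ConnectivityMap]) -> tuple[NDArray, NDArray]:
    if len(maps) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(maps)}")
    shape = maps[0].values.shape
    mask = maps[0].mask
    for m in maps[1:]:
        if m.values.shape != shape or m.mask.shape != mask.shape:
            raise ValueError("connectivity maps are on different grids")
        mask = mask & m.mask
    data = np.stack([m.values for m in maps])
    return data, mask


def extent_filter(significant: NDArray[np.bool_], extent: int) -> NDArray[np.bool_]:
    """Remove connected components (26-connectivity) smaller than ``extent``."""
    if extent <= 1:
        return significant.copy()
    labels, n = ndimage.label(significant, structure=_STRUCT_26)
    if n == 0:
        return significant.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= extent
    keep[0] = False
    return keep[labels]


def _max_t_threshold(data: NDArray, mask: NDArray, alpha: float, n_perm: int, rng) -> float:
    """Sign-flip max-T permutation threshold for a one-sample t-map."""
    flat = data[:, mask]
    n = flat.shape[0]
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None]
        flipped = flat * signs
        m = flipped.mean(axis=0)
        s = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, m / (s / np.sqrt(n)), 0.0)
        maxima[k] = t.max()
    return float(np.quantile(maxima, 1.0 - alpha))


def one_sample_tmap(
    maps: list[ConnectivityMap],
    *,
    alpha: float = 0.05,
    extent: int = 30,
    correction: str = "bonferroni",
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> GroupStatMap:
    """One-sample t-map against zero with FWE control and extent filtering.

    Family-wise error is controlled by Bonferroni over in-mask voxels
    (default) or by a sign-flip max-T permutation (``correction="max_t"``).
    Zero-variance voxels with a non-zero mean get a capped t value (the
    limit of certainty); zero-mean zero-variance voxels get t = 0.
    """
    data, mask = _stack(maps)
    n = data.shape[0]
    m = data.mean(axis=0)
    s = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, m / (s / np.sqrt(n)), np.sign(m) * _T_CAP)
    t[~mask] = 0.0
    df = n - 1
    n_vox = int(mask.sum())
    if correction == "bonferroni":
        t_crit = float(stats.t.isf(alpha / n_vox, df))
    elif correction == "max_t":
        t_crit = _max_t_threshold(data, mask, alpha, n_permutations, np.random.default_rng(rng))
    elif correction == "none":
        t_crit = float(stats.t.isf(alpha, df))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    sig = mask & (t >= t_crit)
    sig = extent_filter(sig, extent)
    return GroupStatMap(
        t_values=t, df=df, significant=sig, mask=mask,
        contrast="one-sample", alpha=alpha, extent=extent,
    )


def two_sample_tmap(
    controls: list[ConnectivityMap],
    patients: list[ConnectivityMap],
    *,
    alpha: float = 0.001,
    extent: int = 30,
    contrast: str = "controls>patients",
) -> GroupStatMap:
    """One-sided two-sample t-map (pooled variance), uncorrected alpha + extent.

    The default contrast tests hypo-connectivity in patients
    (controls > patients); ``contrast="patients>controls"`` flips the sign.
    """
    if contrast not in ("controls>patients", "patients>controls"):
        raise ValueError(f"unknown contrast {contrast!r}")
    data_c, mask_c = _stack(controls)
    data_p, mask_p = _stack(patients)
    if data_c.shape[1:] != data_p.shape[1:]:
        raise ValueError("groups are on different grids")
    mask = mask_c & mask_p
    n1, n2 = data_c.shape[0], data_p.shape[0]
    m1, m2 = data_c.mean(axis=0), data_p.mean(axis=0)
    v1 = data_c.var(axis=0, ddof=1)
    v2 = data_p.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2 if contrast == "controls>patients" else m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.sign(diff) * _T_CAP)
    t[~mask] = 0.0
    df = n1 + n2 - 2
    t_crit = float(stats.t.isf(alpha, df))
    sig = extent_filter(mask & (t >= t_crit), extent)
    return GroupStatMap(
        t_values=t, df=df, significant=sig, mask=mask,
        contrast=contrast, alpha=alpha, extent=extent,
    )


def conjunction(a: GroupStatMap, b: GroupStatMap) -> NDArray[np.bool_]:
    """Voxels significant in both maps (overlap of significance masks)."""
    if a.significant.shape != b.significant.shape:
        raise ValueError("stat maps are on different grids")
    return a.significant & b.significant


def reproducibility(
    a: GroupStatMap,
    b: GroupStatMap,
    *,
    method: str = "spearman",
    suprathreshold_only: bool = False,
) -> ReproducibilityResult:
    """Voxel-wise correlation of paired T-values between two sites' maps.

    Pairs are drawn from the joint in-mask region (optionally restricted to
    voxels suprathreshold in either map).  Zero-variance pairs cannot occur
    in-mask since t-maps are zeroed only outside.  Rho > 0.2 with p < 0.001
    is read as large cross-site consistency; the OLS slope of b's T-values
    on a's supports the slope-comparison test between measures.
    """
    if a.t_values.shape != b.t_values.shape:
        raise ValueError("stat maps are on different grids")
    joint = a.mask & b.mask
    if suprathreshold_only:
        joint &= a.significant | b.significant
    ta, tb = a.t_values[joint], b.t_values[joint]
    if ta.size < 3:
        raise ValueError(f"need at least 3 paired voxels, got {ta.size}")
    if method == "spearman":
        rho, p = stats.spearmanr(ta, tb)
    elif method == "pearson":
        rho, p = stats.pearsonr(ta, tb)
    else:
        raise ValueError(f"unknown method {method!r}")
    ols = stats.linregress(ta, tb)
    return ReproducibilityResult(
        rho=float(rho), p_value=float(p), slope=float(ols.slope),
        slope_se=float(ols.stderr), intercept=float(ols.intercept),
        n_voxels=int(ta.size), method=method,
    )


def compare_slopes(r1: ReproducibilityResult, r2: ReproducibilityResult) -> tuple[float, float]:
    """Two-slope comparison t-test; returns (t, two-sided p).

    t = (b1 - b2) / sqrt(se1^2 + se2^2) on n1 + n2 - 4 degrees of freedom,
    the standard test for equality of two independent regression slopes.
    """
    if r1.n_voxels != r2.n_voxels:
        raise ValueError(
            f"slope comparison requires the same voxel pairing "
            f"({r1.n_voxels} vs {r2.n_voxels} pairs)"
        )
    se = np.hypot(r1.slope_se, r2.slope_se)
    if se == 0:
        return (0.0, 1.0) if r1.slope == r2.slope else (np.inf, 0.0)
    t = (r1.slope - r2.slope) / se
    df = r1.n_voxels + r2.n_voxels - 4
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), p
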