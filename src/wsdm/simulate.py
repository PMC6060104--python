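"""Synthetic BOLD-like signals with controllable linear/non-linear coupling.

Resting-state BOLD fluctuations, after standard band-pass preprocessing,
carry their power in roughly 0.01-0.08 Hz at repetition times of 2-3 s over
150-300 volumes.  The generator emulates exactly that regime: white noise
is band-limited in the frequency domain (zero-phase, so filter ringing
cannot create spurious symbol patterns) and coupled pairs are formed as

    y = sqrt(1 - s^2) * e  +  s * f(x)

with coupling strength s in [0, 1], f drawn from a family of linear and
non-linear links (identity, square, sine, lag), and e an independent
band-limited noise.  s = 0 gives exact independence; s = 1 a noiseless
functional relation.

``gen_toy_brain`` extends this to a miniature 4D two-group experiment: a
seed region sharing a latent source, a target region coupled to that source
with group-specific strength (patients weaker than controls — the
hypo-connectivity structure expected of the salience network in bvFTD), an
independent background, and per-site noise/duration parameters emulating
heterogeneous acquisition across centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .seedmap import BoldDataset

__all__ = [
    "CouplingScenario",
    "ToyBrainSpec",
    "band_limited_noise",
    "gen_coupled_series",
    "gen_toy_brain",
]

COUPLING_KINDS = ("linear", "quadratic", "sine", "lagged", "independent")


@dataclass(frozen=True)
class CouplingScenario:
    """A coupled-pair recipe: kind of link, strength, length, noise, seed."""

    kind: str = "quadratic"
    strength: float = 0.9
    n_samples: int = 200
    tr_seconds: float = 2.5
    band_hz: tuple[float, float] = (0.01, 0.08)
    lag: int = 2
    seed: int | None = None


@dataclass(frozen=True)
class ToyBrainSpec:
    """A miniature two-group, (optionally) two-site 4D dataset recipe.

    Defaults mirror a modest clinical resting-state study: 20 subjects per
    group, ~200 volumes at TR 2.5 s, with a second site differing in noise
    level and series length.  ``coupling_controls``/``coupling_patients``
    set the seed-to-target coupling strength per group; patients may not
    exceed controls (hypo-connectivity by design).
    """

    shape: tuple[int, int, int] = (14, 14, 6)
    n_controls: int = 20
    n_patients: int = 20
    n_volumes: int = 200
    tr_seconds: float = 2.5
    kind: str = "quadratic"
    coupling_controls: float = 0.8
    coupling_patients: float = 0.2
    voxel_noise: float = 0.4
    voxel_size_mm: float = 3.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    sites: tuple[dict, ...] = field(
        default_factory=lambda: (
            {"site_id": "site1", "noise_scale": 1.0, "n_volumes": None},
            {"site_id": "site2", "noise_scale": 1.3, "n_volumes": 180},
        )
    )

    def __post_init__(self):
        if self.coupling_patients > self.coupling_controls:
            raise ValueError("patients' coupling must not exceed controls' (hypo-connectivity)")
        if self.kind not in COUPLING_KINDS:
            raise ValueError(f"unknown coupling kind {self.kind!r}")


def band_limited_noise(
    n_samples: int,
    tr_seconds: float,
    band_hz: tuple[float, float] = (0.01, 0.08),
    *,
    rng: np.random.Generator,
    size: int | tuple = (),
) -> NDArray[np.float64]:
    """Zero-phase band-limited Gaussian noise, unit variance, time on last axis.

    White noise is transformed to the frequency domain, coefficients outside
    the pass band zeroed, and transformed back; the response is exactly zero
    outside the band and phase is untouched, avoiding ringing artifacts that
    would imprint structure on the up/down symbol sequence.
    """
    shape = (size,) if isinstance(size, int) else tuple(size)
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=tr_seconds)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(keep):
        raise ValueError("pass band contains no Fourier frequency at this length/TR")
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    out -= out.mean(axis=-1, keepdims=True)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd == 0, 1.0, sd)


def _standardize(v: NDArray) -> NDArray:
    v = v - v.mean(axis=-1, keepdims=True)
    sd = v.std(axis=-1, keepdims=True)
    return v / np.where(sd == 0, 1.0, sd)


def _apply_link(x: NDArray, kind: str, lag: int) -> NDArray:
    if kind == "linear":
        f = x
    elif kind == "quadratic":
        f = x**2
    elif kind == "sine":
        f = np.sin(np.pi * x)
    elif kind == "lagged":
        f = np.roll(x, lag, axis=-1)
    elif kind == "independent":
        f = np.zeros_like(x)
    else:
        raise ValueError(f"unknown coupling kind {kind!r}")
    return _standardize(f)


def gen_coupled_series(
    scenario: CouplingScenario, *, rng: np.random.Generator | int | None = None
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Generate one (x, y) pair under the scenario's coupling.

    x is band-limited noise; y mixes an independent band-limited noise with
    the link f(x) so that strength 0 yields exact independence and the
    variance contributions add in quadrature.  Fully reproducible given the
    scenario seed (or an explicit generator).
    """
    if not 0.0 <= scenario.strength <= 1.0:
        raise ValueError(f"strength must lie in [0, 1], got {scenario.strength}")
    if scenario.n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if rng is None:
        rng = scenario.seed
    rng = np.random.default_rng(rng)
    x, e = band_limited_noise(
        scenario.n_samples, scenario.tr_seconds, scenario.band_hz, rng=rng, size=2
    )
    s = scenario.strength
    kind = scenario.kind if s > 0 else "independent"
    y = np.sqrt(1.0 - s**2) * e + s * _apply_link(x, kind, scenario.lag)
    return x, y


def gen_toy_brain(
    spec: ToyBrainSpec, *, rng: np.random.Generator | int | None = None
) -> tuple[list[BoldDataset], dict[str, NDArray[np.bool_]]]:
    """Generate per-subject 4D datasets plus ground-truth region masks.

    Layout: the seed region is a small block in one corner of the grid, the
    target region a disjoint block in the opposite corner; everything else
    is background.  For each subject, seed voxels share a latent source
    (plus voxel noise), target voxels couple to f(source) with the group's
    strength, and background voxels are independent.  Returns the datasets
    (labels in ``subject_id``/``group``) and masks ``{"seed", "target",
    "brain"}``.
    """
    rng = np.random.default_rng(rng)
    nx, ny, nz = spec.shape
    brain = np.ones(spec.shape, dtype=bool)
    seed_mask = np.zeros(spec.shape, dtype=bool)
    target_mask = np.zeros(spec.shape, dtype=bool)
    seed_mask[1:4, 1:4, 1:3] = True
    target_mask[nx - 5 : nx - 1, ny - 5 : ny - 1, 1 : nz - 1] = True
    if np.any(seed_mask & target_mask):
        raise ValueError("seed and target regions overlap")

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    datasets: list[BoldDataset] = []
    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients
    n_sites = len(spec.sites)
    for idx, group in enumerate(groups):
        site = spec.sites[idx % n_sites]
        n_vol = site.get("n_volumes") or spec.n_volumes
        noise_scale = site.get("noise_scale", 1.0)
        strength = spec.coupling_controls if group == "control" else spec.coupling_patients

        source = band_limited_noise(n_vol, spec.tr_seconds, spec.band_hz, rng=rng)
        vol = noise_scale * band_limited_noise(
            n_vol, spec.tr_seconds, spec.band_hz, rng=rng, size=spec.shape
        )
        vol[seed_mask] = source + spec.voxel_noise * vol[seed_mask]
        link = _apply_link(source, spec.kind, lag=2)
        # site noise scale applies to the target's noise share, not the signal
        vol[target_mask] = strength * link + np.sqrt(1.0 - strength**2) * vol[target_mask]
        datasets.append(
            BoldDataset(
                volume=vol,
                mask=brain,
                affine=affine,
                tr_seconds=spec.tr_seconds,
                subject_id=f"sub-{idx:03d}",
                site_id=site.get("site_id", "site1"),
                group=group,
            )
        )
    masks = {"seed": seed_mask, "target": target_mask, "brain": brain}
    return datasets, masks
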