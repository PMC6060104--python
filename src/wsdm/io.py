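"""NIfTI and delimited-text I/O, seed configuration, and the full pipeline.

Volumes, masks, and maps travel as NIfTI-1; time series, feature tables and
reports as delimited text; seeds and run settings as YAML.  All user-facing
coordinates are world mm (the volume's stored frame); array indices are
0-based and internal.  ``run_pipeline`` chains seed maps -> proportional
thresholding -> group statistics -> cross-site reproducibility ->
classification, writing each stage's outputs together with a manifest
(config, RNG seed, input checksums) from which every number is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import groupstats as _groupstats
from .seedmap import BoldDataset, ConnectivityMap, SeedSpec, proportional_threshold, seed_map
from .simulate import ToyBrainSpec, gen_toy_brain

__all__ = [
    "RunConfig",
    "read_bold",
    "write_bold",
    "write_map",
    "read_series_table",
    "read_seed_config",
    "run_pipeline",
]

log = logging.getLogger("wsdm")


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    ``tr_seconds`` overrides NIfTI-header TR when set (shared-data headers
    are often wrong).  The RNG seed is recorded in every output manifest.
    """

    measure: str = "wsdm"
    percentile: float = 30.0
    thresholds: tuple[float, ...] = _classify.DEFAULT_THRESHOLDS
    classifier: str = "svm"
    alpha_one_sample: float = 0.05
    alpha_two_sample: float = 0.001
    extent: int = 30
    seed_radius_mm: float = 6.0
    tr_seconds: float | None = None
    rng_seed: int = 0
    out_dir: str = "wsdm-out"
    extra: dict = field(default_factory=dict)


def read_bold(
    path: str | Path,
    *,
    mask_path: str | Path | None = None,
    tr_seconds: float | None = None,
    subject_id: str | None = None,
    site_id: str = "site1",
    group: str | None = None,
) -> BoldDataset:
    """Load a 4D NIfTI volume (+ optional companion mask) as a BoldDataset.

    TR is taken from the header's time axis unless overridden.  Without a
    companion mask, voxels with non-zero temporal variance form the mask.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got ndim={data.ndim}")
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr_seconds <= 0:
            raise ValueError(f"{path}: header TR unusable; pass tr_seconds explicitly")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = data.std(axis=3) > 0
    return BoldDataset(
        volume=data,
        mask=mask,
        affine=img.affine,
        tr_seconds=tr_seconds,
        subject_id=subject_id or Path(path).name.split(".")[0],
        site_id=site_id,
        group=group,
    )


def write_bold(data: BoldDataset, path: str | Path, *, mask_path: str | Path | None = None) -> None:
    """Write a BoldDataset as NIfTI-1 (TR stored on the 4th zoom)."""
    img = nib.Nifti1Image(data.volume.astype(np.float32), data.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], data.tr_seconds))
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(data.mask.astype(np.uint8), data.affine), str(mask_path))


def write_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def read_series_table(path: str | Path) -> pd.DataFrame:
    """Read numeric series from delimited text, one series per column.

    Delimiter is sniffed (comma/tab/whitespace); a header row is used when
    present, otherwise columns are named s0, s1, ...
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    first = df.iloc[0]
    if not pd.to_numeric(first, errors="coerce").notna().all():
        df = pd.read_csv(path, sep=None, engine="python", header=0)
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df.astype(float)


def read_seed_config(path: str | Path) -> list[SeedSpec]:
    """Load seeds from YAML: a list of {name, centers (mm), radius_mm}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seeds = raw["seeds"] if isinstance(raw, dict) else raw
    return [
        SeedSpec(
            name=s["name"],
            centers=tuple(tuple(float(c) for c in ctr) for ctr in s["centers"]),
            radius_mm=float(s.get("radius_mm", 6.0)),
        )
        for s in seeds
    ]


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    datasets: list[BoldDataset] | None = None,
    seeds: list[SeedSpec] | None = None,
    *,
    toy_spec: ToyBrainSpec | None = None,
    measures: tuple[str, ...] | None = None,
) -> dict:
    """Run seed maps -> thresholding -> group stats -> reproducibility -> classification.

    With no datasets, a toy two-group dataset is generated from ``toy_spec``
    (or its defaults) and the generator's seed region is used as the seed.
    Returns the report bundle as a dict and writes it (plus a manifest)
    under ``config.out_dir``.
    """
    if config.measure not in ("wsdm", "dm", "pearson"):
        raise ValueError(f"unknown measure {config.measure!r}")
    rng = np.random.default_rng(config.rng_seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    measures = measures or (config.measure,)

    if datasets is None:
        spec = toy_spec or ToyBrainSpec()
        log.info("generating toy dataset: %s", spec)
        datasets, masks = gen_toy_brain(spec, rng=rng)
        if seeds is None:
            ijk = np.argwhere(masks["seed"]).mean(axis=0)
            center = tuple(nib.affines.apply_affine(datasets[0].affine, ijk))
            seeds = [SeedSpec(name="toy-seed", centers=(center,), radius_mm=spec.voxel_size_mm * 2)]
    if seeds is None:
        raise ValueError("seeds are required when datasets are supplied")

    sites = sorted({d.site_id for d in datasets})
    bundle: dict = {"config": config.__dict__ | {"thresholds": list(config.thresholds)},
                    "measures": {}, "sites": sites}
    for measure in measures:
        mres: dict = {"seed_maps": {}, "group_stats": {}, "classification": {}}
        stage = f"seed_map[{measure}]"
        try:
            maps = [seed_map(d, seeds[0], measure) for d in datasets]
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        thresholded = [proportional_threshold(m, config.percentile) for m in maps]
        mres["seed_maps"] = {
            m.subject_id: {"mean_inmask": float(m.values[m.mask].mean()), "checksum": _checksum(m.values)}
            for m in thresholded
        }

        site_tmaps = {}
        for site in sites:
            hc = [m for m in thresholded if m.site_id == site and m.group == "control"]
            pt = [m for m in thresholded if m.site_id == site and m.group == "patient"]
            if len(hc) >= 3:
                one = _groupstats.one_sample_tmap(
                    hc, alpha=config.alpha_one_sample, extent=config.extent
                )
                entry = {"one_sample_sig_voxels": int(one.significant.sum())}
                if len(pt) >= 3:
                    two = _groupstats.two_sample_tmap(
                        hc, pt, alpha=config.alpha_two_sample, extent=config.extent
                    )
                    entry["two_sample_sig_voxels"] = int(two.significant.sum())
                    site_tmaps[site] = two
                mres["group_stats"][site] = entry
        if len(site_tmaps) == 2:
            a, b = (site_tmaps[s] for s in sorted(site_tmaps))
            rep = _groupstats.reproducibility(a, b)
            mres["group_stats"]["reproducibility"] = {
                "rho": rep.rho, "p_value": rep.p_value,
                "slope": rep.slope, "n_voxels": rep.n_voxels,
            }
            mres["group_stats"]["conjunction_voxels"] = int(_groupstats.conjunction(a, b).sum())

        report = _classify.nested_cv(
            maps,
            classifier=config.classifier,
            thresholds=config.thresholds,
            rng=np.random.default_rng(config.rng_seed),
        )
        mres["classification"] = {
            "accuracy": report.accuracy,
            "pooled_accuracy": report.pooled_accuracy,
            "optimal_percentile": report.optimal_percentile,
            "auc": report.auc,
            "per_threshold_accuracy": {str(k): v for k, v in report.per_threshold_accuracy.items()},
        }
        bundle["measures"][measure] = mres

    manifest = {
        "rng_seed": config.rng_seed,
        "n_subjects": len(datasets),
        "inputs": {d.subject_id: _checksum(d.volume) for d in datasets},
        "seeds": [{"name": s.name, "centers": [list(c) for c in s.centers], "radius_mm": s.radius_mm} for s in seeds],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
    return bundle
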