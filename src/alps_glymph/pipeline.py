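"""End-to-end orchestration: phantom -> tensor fit -> ALPS -> volumes ->
cohort -> statistics, with a YAML config, per-stage seeds, and a JSON run
manifest (inputs, outputs, checksums) that makes re-runs idempotent."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import make_scheme
from .alpsindex import ROISpec, alps_from_maps, read_roi_file, write_roi_file
from .cohort import CohortParams, Marginal, simulate_cohort, write_cohort
from .phantom import PhantomSpec, build_alps_phantom
from .reports import (alps_correlation_table, group_comparison_table,
                      outcome_comparison_table, outcome_logistic_table)
from .tensorfit import axis_diffusivities, eigendecompose, fit_tensor_loglinear, load_dwi, save_maps
from .volumetry import load_mask, mask_volume, volume_report

logger = logging.getLogger(__name__)

STAGES = ("simulate_dwi", "fit_tensor", "alps", "volumes", "simulate_cohort", "stats")

_DEFAULTS: dict[str, Any] = {
    "out_dir": "runs/demo",
    "stages": list(STAGES),
    "phantom": {
        "shape": [96, 96, 40],
        "voxel_size_mm": [1.7, 1.7, 2.0],
        "s0": 1000.0,
        "noise_sigma": 0.0,
        "n_directions": 30,
        "b_value": 1000.0,
        "n_b0": 1,
        "seed": 0,
        "lesion": None,  # {center_vox, hematoma_radii_mm, lesion_radii_mm}
    },
    "alps": {
        "roi_file": None,  # None -> phantom ground-truth centers
        "roi_diameter_mm": 5.0,
        "lesion_side": "none",
    },
    "cohort": {
        "n_sich": 55,
        "n_hc": 97,
        "n_subtentorial": 9,
        "seed": 0,
        "volume_family": "lognormal",
    },
    "verbose": False,
}

_LESION_KEYS = {"center_vox", "hematoma_center_vox", "hematoma_radii_mm", "lesion_radii_mm"}


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled."""

    out_dir: Path
    stages: list[str]
    phantom: dict
    alps: dict
    cohort: dict
    verbose: bool = False

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _check_keys(block: dict, allowed, path: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")


def validate_config(source) -> RunConfig:
    """Load and validate a YAML config (path or dict); unknown keys are
    rejected with their key path, missing keys take defaults."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    _check_keys(raw, _DEFAULTS, "<root>")
    cfg = {k: (v.copy() if isinstance(v, dict) else v) for k, v in _DEFAULTS.items()}
    for key, val in raw.items():
        if isinstance(_DEFAULTS[key], dict) and val is not None:
            if not isinstance(val, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            _check_keys(val, _DEFAULTS[key], key)
            cfg[key].update(val)
        else:
            cfg[key] = val

    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")
    if cfg["alps"]["roi_diameter_mm"] <= 0:
        raise ValueError("alps.roi_diameter_mm must be positive")
    if cfg["phantom"]["noise_sigma"] < 0:
        raise ValueError("phantom.noise_sigma must be >= 0")
    if cfg["phantom"]["lesion"] is not None:
        _check_keys(cfg["phantom"]["lesion"], _LESION_KEYS, "phantom.lesion")
    if cfg["cohort"]["n_sich"] < 2 or cfg["cohort"]["n_hc"] < 2:
        raise ValueError("cohort group sizes must be >= 2")
    return RunConfig(
        out_dir=Path(cfg["out_dir"]),
        stages=list(cfg["stages"]),
        phantom=cfg["phantom"],
        alps=cfg["alps"],
        cohort=cfg["cohort"],
        verbose=bool(cfg["verbose"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def phantom_spec_from_config(cfg: RunConfig) -> PhantomSpec:
    p = cfg.phantom
    lesion = p.get("lesion") or {}
    return PhantomSpec(
        shape=tuple(p["shape"]),
        voxel_size_mm=tuple(p["voxel_size_mm"]),
        s0=float(p["s0"]),
        noise_sigma=float(p["noise_sigma"]),
        scheme=make_scheme(int(p["n_directions"]), float(p["b_value"]), int(p["n_b0"])),
        seed=int(p["seed"]),
        lesion_center_vox=tuple(lesion["center_vox"]) if lesion else None,
        hematoma_center_vox=(tuple(lesion["hematoma_center_vox"])
                             if lesion.get("hematoma_center_vox") else None),
        hematoma_radii_mm=(tuple(lesion["hematoma_radii_mm"])
                           if lesion.get("hematoma_radii_mm") else None),
        lesion_radii_mm=tuple(lesion["lesion_radii_mm"]) if lesion else None,
    )


def cohort_params_from_config(cfg: RunConfig) -> CohortParams:
    c = cfg.cohort
    params = CohortParams(
        n_sich=int(c["n_sich"]), n_hc=int(c["n_hc"]),
        n_subtentorial=int(c["n_subtentorial"]),
    )
    family = c.get("volume_family", "lognormal")
    for key in ("hemorrhage_ml", "edema_ml"):
        m = params.marginals[key]
        params.marginals[key] = Marginal(m.mean, m.sd, family)
    return params


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    A stage whose outputs already exist with checksums recorded under an
    identical config is skipped (idempotent re-runs). Identical config and
    seeds produce identical outputs.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    config_hash = hashlib.sha256(
        json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
    ).hexdigest()
    previous = {}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == config_hash:
                previous = old.get("stages", {})
        except (json.JSONDecodeError, OSError):
            pass

    manifest: dict = {
        "version": __version__,
        "config_hash": config_hash,
        "config": cfg.to_jsonable(),
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def _finish(stage: str, outputs: dict[str, Path], extra: Optional[dict] = None) -> None:
        entry = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "checksums": {k: _sha256(Path(v)) for k, v in outputs.items()},
        }
        if extra:
            entry.update(extra)
        manifest["stages"][stage] = entry
        artifacts.update(outputs)

    def _reusable(stage: str) -> bool:
        entry = previous.get(stage)
        if not entry:
            return False
        try:
            ok = all(
                Path(p).exists() and _sha256(Path(p)) == entry["checksums"][k]
                for k, p in entry["outputs"].items()
            )
        except KeyError:
            return False
        if ok:
            manifest["stages"][stage] = entry
            artifacts.update({k: Path(p) for k, p in entry["outputs"].items()})
            logger.info("stage %s: outputs up to date, skipped", stage)
        return ok

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if _reusable(stage):
            continue
        logger.info("stage %s: running", stage)
        if stage == "simulate_dwi":
            spec = phantom_spec_from_config(cfg)
            dwi, truth = build_alps_phantom(spec)
            paths = dwi.save(out, "dwi")
            np.save(out / "region_map.npy", truth.region_map)
            rois = [
                ROISpec(hemisphere=h, fiber_class=f, center_vox=c,
                        diameter_mm=cfg.alps["roi_diameter_mm"])
                for (h, f), c in truth.roi_centers.items()
            ]
            write_roi_file(rois, out / "truth_rois.json")
            (out / "truth_alps.json").write_text(json.dumps(truth.analytic_alps, indent=2))
            paths |= {"truth_rois": out / "truth_rois.json",
                      "truth_alps": out / "truth_alps.json"}
            if truth.lesion_masks is not None:
                import nibabel as nib
                for name, arr in (("hematoma_mask", truth.lesion_masks.hematoma),
                                  ("lesion_mask", truth.lesion_masks.total_lesion)):
                    p = out / f"{name}.nii.gz"
                    nib.save(nib.Nifti1Image(arr.astype(np.uint8), spec.affine), p)
                    paths[name] = p
            _finish(stage, paths, {"seed": spec.seed,
                                   "analytic_alps": truth.analytic_alps})
        elif stage == "fit_tensor":
            for key in ("dwi", "bval", "bvec"):
                if key not in artifacts:
                    raise RuntimeError(
                        f"stage fit_tensor: missing dependency output {key!r} "
                        "(run simulate_dwi or point the config at existing files)"
                    )
            dwi = load_dwi(artifacts["dwi"], artifacts["bval"], artifacts["bvec"])
            field_ = fit_tensor_loglinear(dwi)
            feats = eigendecompose(field_)
            _finish(stage, save_maps(feats, out / "maps"))
        elif stage == "alps":
            for key in ("Dxx", "Dyy", "Dzz"):
                if key not in artifacts:
                    raise RuntimeError("stage alps: missing tensor maps; run fit_tensor first")
            import nibabel as nib
            maps = {k: np.asarray(nib.load(str(artifacts[k])).dataobj, dtype=float)
                    for k in ("Dxx", "Dyy", "Dzz")}
            vox = np.asarray(validate_voxel_size(artifacts["Dxx"]))
            roi_file = cfg.alps["roi_file"] or artifacts.get("truth_rois")
            if roi_file is None:
                raise RuntimeError("stage alps: no ROI file configured and no phantom truth")
            rois = read_roi_file(roi_file)
            result, means = alps_from_maps(
                maps["Dxx"], maps["Dyy"], maps["Dzz"], rois, vox,
                lesion_side=cfg.alps["lesion_side"],
            )
            payload = {"alps": result.to_dict(),
                       "roi_means": {h: vars(m) for h, m in means.items()}}
            p = out / "alps.json"
            p.write_text(json.dumps(payload, indent=2))
            _finish(stage, {"alps": p})
        elif stage == "volumes":
            if "hematoma_mask" not in artifacts or "lesion_mask" not in artifacts:
                logger.info("stage volumes: no lesion masks available, skipped")
                continue
            hem, hem_aff, _ = load_mask(artifacts["hematoma_mask"])
            les, les_aff, _ = load_mask(artifacts["lesion_mask"])
            report = volume_report(hem, hem_aff, les, les_aff)
            p = out / "volumes.json"
            p.write_text(json.dumps(report.to_dict(), indent=2))
            _finish(stage, {"volumes": p})
        elif stage == "simulate_cohort":
            params = cohort_params_from_config(cfg)
            table = simulate_cohort(params, seed=int(cfg.cohort["seed"]))
            p = out / "cohort.csv"
            write_cohort(table, p)
            _finish(stage, {"cohort": p}, {"seed": int(cfg.cohort["seed"])})
        elif stage == "stats":
            if "cohort" not in artifacts:
                raise RuntimeError("stage stats: missing cohort table; run simulate_cohort first")
            table = pd.read_csv(artifacts["cohort"])
            outputs = {}
            for name, fn in (
                ("group_comparison", group_comparison_table),
                ("outcome_comparison", outcome_comparison_table),
                ("outcome_logistic", outcome_logistic_table),
                ("alps_correlations", alps_correlation_table),
            ):
                p = out / f"{name}.csv"
                fn(table).to_csv(p, index=False)
                outputs[name] = p
            _finish(stage, outputs)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_voxel_size(nifti_path) -> tuple[float, float, float]:
    import nibabel as nib
    img = nib.load(str(nifti_path))
    return tuple(float(v) for v in img.header.get_zooms()[:3])
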