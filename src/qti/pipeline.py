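"""End-to-end orchestration: design -> simulate -> reconstruct -> infer ->
angiography, driven by a YAML config, writing all artifacts plus a JSON run
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

import qti
from qti.acquisition import acquire, make_coils, make_phantom, make_spiral
from qti.design import default_prior, make_ramp_design, optimize_ramp, RampSpec
from qti.inference import InferencePrior, fit_maps
from qti.io import (design_from_yaml, load_kspace, prior_from_yaml,
                    save_design, save_kspace, save_landscape_csv, save_nifti)
from qti.projections import ProjectionSpec, combine_frames, mip
from qti.recon import (ReconConfig, admm_reconstruct, build_subspace,
                       project_to_time)

log = logging.getLogger("qti")

__all__ = ["run_pipeline"]

_STAGES = ("design", "simulate", "recon", "infer", "angio")


def _parse_grid(spec: str) -> np.ndarray:
    lo, hi, step = (float(x) for x in str(spec).split(":"))
    return np.arange(lo, hi + step / 2, step)


def run_pipeline(config_path, out_dir=None) -> dict:
    """Execute the stages named in the config in order with shared seeds.

    Returns the manifest dict (also written to ``manifest.json``).  Stage
    failures raise; artifacts of completed stages are preserved.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out = Path(out_dir or cfg.get("out_dir", "qti_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = {
        "qti_version": qti.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "stages": {},
    }
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s: %(message)s")
    stages = cfg.get("stages", list(_STAGES))
    design = None
    frames = None
    mask_support = None
    fov = float(cfg.get("fov_mm", 225.0))

    for stage in stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        log.info("stage %s (seed=%d)", stage, seed)
        scfg = cfg.get(stage, {}) or {}

        if stage == "design":
            prior = (prior_from_yaml(scfg["prior"]) if "prior" in scfg
                     else default_prior())
            grid_a = _parse_grid(scfg.get("grid_a", "1:15:1"))
            grid_b = _parse_grid(scfg.get("grid_b", "40:90:5"))
            best, land = optimize_ramp(
                grid_a, grid_b, prior,
                n_samples=int(scfg.get("samples", 200)), seed=seed,
            )
            design = make_ramp_design(best)
            save_design(out / "design.yaml", design)
            save_landscape_csv(out / "landscape.csv", land)
            manifest["stages"]["design"] = {
                "alpha_a": best.alpha_a, "alpha_b": best.alpha_b,
                "duration_s": design.duration_s,
            }
        elif stage == "simulate":
            if design is None:
                design = (design_from_yaml(scfg["design"])
                          if isinstance(scfg.get("design"), dict)
                          else make_ramp_design(RampSpec(
                              alpha_a=float(scfg.get("alpha_a", 7)),
                              alpha_b=float(scfg.get("alpha_b", 70)),
                              N=int(scfg.get("N", 260)))))
            matrix = int(scfg.get("matrix", 64))
            phantom = make_phantom(
                scfg.get("phantom", "brain2d"), (matrix, matrix),
                fov_mm=fov, seed=seed,
                vessel_velocity=float(scfg.get("vessel_velocity", 50.0)),
            )
            sampling = make_spiral(fov_mm=fov, matrix=matrix,
                                   n_repetitions=design.N)
            coils = make_coils(phantom.shape,
                               int(scfg.get("n_coils", 4)), seed=seed + 1)
            noise_sd = float(scfg.get("noise_sd", 0.0))
            data = acquire(phantom, design, sampling, coils,
                           noise_sd=noise_sd, seed=seed + 2)
            save_kspace(out / "kspace.h5", data, phantom=phantom)
            for key in ("T1", "T2", "rho", "v"):
                save_nifti(out / f"phantom_{key}.nii.gz",
                           getattr(phantom, key), fov_mm=fov)
            mask_support = phantom.support
            manifest["stages"]["simulate"] = {
                "matrix": matrix, "noise_sd": noise_sd,
                "n_coils": coils.n_coils,
            }
        elif stage == "recon":
            data, phantom = load_kspace(out / "kspace.h5")
            design = data.design
            prior = default_prior()
            basis = build_subspace(design, prior,
                                   n_signals=int(scfg.get("n_signals", 1000)),
                                   R=int(scfg.get("rank", 10)), seed=seed + 3)
            rc = ReconConfig(lam=float(scfg.get("lam", 0.001)),
                             patch=int(scfg.get("patch", 8)),
                             n_iters=int(scfg.get("iters", 50)),
                             cg_iters=int(scfg.get("cg_iters", 10)))
            coeffs, info = admm_reconstruct(data, basis, rc, seed=seed + 4)
            frames = project_to_time(coeffs)
            np.save(out / "coeffs.npy", coeffs.coeffs)
            save_nifti(out / "frames.nii.gz",
                       np.moveaxis(np.abs(frames), 0, -1), fov_mm=fov)
            if phantom is not None:
                mask_support = phantom.support
            manifest["stages"]["recon"] = {
                "rank": basis.R, "iterations": info["iterations"],
                "lam_abs": info["lam_abs"],
            }
        elif stage == "infer":
            if frames is None:
                raise RuntimeError("infer requires a reconstructed series")
            mask = mask_support if mask_support is not None else (
                np.abs(frames).mean(axis=0)
                > 0.05 * np.abs(frames).mean(axis=0).max())
            maps = fit_maps(frames, mask, design,
                            prior=InferencePrior(),
                            method=scfg.get("method", "dict"),
                            seed=seed + 5)
            for name, m in maps.items():
                save_nifti(out / f"map_{name}.nii.gz", m, fov_mm=fov)
            manifest["stages"]["infer"] = {
                "method": scfg.get("method", "dict"),
                "n_voxels": int(mask.sum()),
            }
        elif stage == "angio":
            if frames is None:
                raise RuntimeError("angio requires a reconstructed series")
            n = frames.shape[0]
            start = int(scfg.get("start", n - 160 if n >= 160 else 0))
            spec = ProjectionSpec(start=start, end=n - 1)
            combined = combine_frames(frames, spec)
            save_nifti(out / "angio_combined.nii.gz", combined, fov_mm=fov)
            proj = mip(combined[None], axis=0)  # single slice: identity
            save_nifti(out / "angio_mip.nii.gz", proj, fov_mm=fov)
            manifest["stages"]["angio"] = {"frames": [start, n - 1]}
        manifest["stages"][stage]["seconds"] = round(time.time() - t0, 2)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
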