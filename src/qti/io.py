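"""File formats: YAML designs and priors, HDF5 k-space, NIfTI maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from qti.acquisition import CoilSet, DigitalPhantom, KSpaceData, SpiralSampling
from qti.design import RampSpec, TissueClass, TissueClassPrior, make_ramp_design
from qti.epg import AcquisitionDesign

__all__ = [
    "design_to_yaml", "design_from_yaml", "save_design", "load_design",
    "prior_from_yaml", "save_kspace", "load_kspace",
    "save_frames", "load_frames", "save_nifti", "save_landscape_csv",
]


def design_to_yaml(design: AcquisitionDesign) -> dict:
    return {
        "flip_deg": [float(f) for f in design.flip_deg],
        "TR_ms": float(design.TR),
        "TE_ms": float(design.TE),
        "slice_mm": float(design.d),
        "invert": bool(design.invert),
        "N": design.N,
    }


def design_from_yaml(doc: dict) -> AcquisitionDesign:
    """Build a design from a mapping; ``flip_deg`` may be an explicit list
    or a ramp spec ``{a: ..., b: ...}`` interpolated over N repetitions."""
    flips = doc["flip_deg"]
    if isinstance(flips, dict):
        spec = RampSpec(
            alpha_a=float(flips["a"]), alpha_b=float(flips["b"]),
            N=int(doc["N"]), TR=float(doc["TR_ms"]), TE=float(doc["TE_ms"]),
            d=float(doc.get("slice_mm", 2.0)), invert=bool(doc.get("invert", True)),
        )
        return make_ramp_design(spec)
    return AcquisitionDesign(
        flip_deg=np.asarray(flips, dtype=float),
        TR=float(doc["TR_ms"]), TE=float(doc["TE_ms"]),
        d=float(doc.get("slice_mm", 2.0)), invert=bool(doc.get("invert", True)),
    )


def save_design(path, design: AcquisitionDesign) -> None:
    Path(path).write_text(yaml.safe_dump(design_to_yaml(design)))


def load_design(path) -> AcquisitionDesign:
    return design_from_yaml(yaml.safe_load(Path(path).read_text()))


def prior_from_yaml(path) -> TissueClassPrior:
    """Load a tissue-class prior: list of {name, T1_ms, T2_ms, sigma_T1,
    sigma_T2, mu} entries (sigmas default to 10% of the mean)."""
    doc = yaml.safe_load(Path(path).read_text())
    classes, weights = [], []
    for c in doc["classes"]:
        t1, t2 = float(c["T1_ms"]), float(c["T2_ms"])
        classes.append(TissueClass(
            name=c["name"], T1=t1, T2=t2,
            sigma_T1=float(c.get("sigma_T1", 0.1 * t1)),
            sigma_T2=float(c.get("sigma_T2", 0.1 * t2)),
        ))
        weights.append(float(c.get("mu", 0.0)))
    return TissueClassPrior(classes=tuple(classes), weights=tuple(weights))


def save_kspace(path, data: KSpaceData, phantom: DigitalPhantom | None = None):
    """HDF5 layout: /kspace (t, coil, sample), /traj (t, sample, 2 cycles/FOV),
    /coils, optional /phantom/{T1,T2,rho,v,labels}; design YAML as attribute."""
    s = data.sampling
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.y)
        traj = np.stack([s.coords(t) for t in range(s.n_repetitions)])
        f.create_dataset("traj", data=traj)
        f.create_dataset("coils", data=data.coils.maps)
        f.attrs["design"] = yaml.safe_dump(design_to_yaml(data.design))
        f.attrs["noise_sd"] = data.noise_sd
        f.attrs["matrix"] = s.matrix
        f.attrs["fov_mm"] = s.fov_mm
        if phantom is not None:
            g = f.create_group("phantom")
            for k in ("T1", "T2", "rho", "v", "labels"):
                g.create_dataset(k, data=getattr(phantom, k))
            g.attrs["label_names"] = json.dumps(list(phantom.label_names))
            g.attrs["fov_mm"] = phantom.fov_mm


def load_kspace(path):
    """Inverse of :func:`save_kspace`; returns (KSpaceData, phantom | None).

    The trajectory is restored as an explicit per-repetition sampling (one
    'interleave' per repetition, no further rotation)."""
    with h5py.File(path, "r") as f:
        y = f["kspace"][:]
        traj = f["traj"][:]
        coils = CoilSet(maps=f["coils"][:])
        design = design_from_yaml(yaml.safe_load(f.attrs["design"]))
        sampling = SpiralSampling(
            base_k=traj,
            interleave_idx=np.arange(traj.shape[0]),
            angle_deg=np.zeros(traj.shape[0]),
            n_dense=0, matrix=int(f.attrs["matrix"]),
            fov_mm=float(f.attrs["fov_mm"]),
        )
        data = KSpaceData(y=y, noise_sd=float(f.attrs["noise_sd"]),
                          design=design, sampling=sampling, coils=coils)
        phantom = None
        if "phantom" in f:
            g = f["phantom"]
            phantom = DigitalPhantom(
                T1=g["T1"][:], T2=g["T2"][:], rho=g["rho"][:], v=g["v"][:],
                labels=g["labels"][:],
                label_names=tuple(json.loads(g.attrs["label_names"])),
                fov_mm=float(g.attrs["fov_mm"]),
            )
    return data, phantom


def save_frames(path, frames: np.ndarray, design: AcquisitionDesign,
                fov_mm: float = 225.0) -> None:
    """Complex reconstructed time series as HDF5 (NIfTI only keeps the
    magnitude, so inference reads this format)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames)
        f.attrs["design"] = yaml.safe_dump(design_to_yaml(design))
        f.attrs["fov_mm"] = fov_mm


def load_frames(path):
    with h5py.File(path, "r") as f:
        frames = f["frames"][:]
        design = design_from_yaml(yaml.safe_load(f.attrs["design"]))
        fov = float(f.attrs["fov_mm"])
    return frames, design, fov


def save_nifti(path, img: np.ndarray, fov_mm: float | None = None) -> None:
    """Write a real image/volume as NIfTI with FOV-derived voxel spacing.

    Complex input is stored as magnitude; the frame axis (if any) should be
    last, matching the NIfTI convention of spatial-then-temporal axes.
    """
    arr = np.abs(img) if np.iscomplexobj(img) else np.asarray(img)
    affine = np.eye(4)
    if fov_mm is not None:
        sp = fov_mm / arr.shape[0]
        affine[0, 0] = affine[1, 1] = sp
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


def save_landscape_csv(path, landscape: list[dict]) -> None:
    import csv

    keys = list(landscape[0].keys())
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=keys)
        w.writeheader()
        w.writerows(landscape)
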