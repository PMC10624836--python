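"""File formats: HDF5 frame stacks, CSV positions, TIFF images, YAML config.

HDF5 layout for a diffraction stack::

    /frames        uint32 (or float64 for noiseless), n x N x N
    /positions_nm  float64, n x 2
    /meta          attrs: energy_keV, distance_m, pixel_pitch_um,
                   exposure_ms, flux_scale, step_nm, beamsize_nm, seed, poisson

Integer frames round-trip bit-exactly.  Phase images are written as 32-bit
float TIFF with a JSON sidecar carrying grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .rpie import ReconResult
from .simkit import DetectorGeometry, DiffractionStack, ScanPlan

__all__ = ["write_stack", "read_stack", "write_positions_csv",
           "read_positions_csv", "write_phase_tiff", "read_phase_tiff",
           "write_recon", "load_config", "save_config"]


def write_stack(path, stack: DiffractionStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames)
        f.create_dataset("positions_nm", data=stack.plan.positions_nm)
        meta = f.create_group("meta")
        meta.attrs["exposure_ms"] = stack.exposure_ms
        meta.attrs["flux_scale"] = stack.flux_scale
        meta.attrs["step_nm"] = stack.plan.step_nm
        meta.attrs["beamsize_nm"] = stack.plan.beamsize_nm
        meta.attrs["poisson"] = stack.poisson
        if stack.seed is not None:
            meta.attrs["seed"] = stack.seed
        if stack.geometry is not None:
            g = stack.geometry
            meta.attrs["energy_keV"] = g.energy_keV
            meta.attrs["distance_m"] = g.distance_m
            meta.attrs["n_pixels"] = g.n_pixels
            meta.attrs["pixel_pitch_um"] = g.pixel_pitch_um


def read_stack(path) -> DiffractionStack:
    with h5py.File(path, "r") as f:
        for name in ("frames", "positions_nm", "meta"):
            if name not in f:
                raise ValueError(f"malformed stack file: missing dataset '{name}'")
        frames = f["frames"][...]
        positions = f["positions_nm"][...]
        meta = dict(f["meta"].attrs)
    geometry = None
    if "energy_keV" in meta:
        geometry = DetectorGeometry(float(meta["energy_keV"]), float(meta["distance_m"]),
                                    int(meta["n_pixels"]), float(meta["pixel_pitch_um"]))
    plan = ScanPlan(positions, float(meta["step_nm"]), float(meta["beamsize_nm"]))
    return DiffractionStack(frames, float(meta["exposure_ms"]), float(meta["flux_scale"]),
                            plan, geometry, int(meta.get("seed", 0)),
                            bool(meta.get("poisson", False)))


def write_positions_csv(path, plan: ScanPlan) -> None:
    df = pd.DataFrame({"index": np.arange(plan.n_points),
                       "x_nm": plan.positions_nm[:, 0],
                       "y_nm": plan.positions_nm[:, 1]})
    df.to_csv(path, index=False)


def read_positions_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("index", "x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"malformed positions CSV: missing column '{col}'")
    return df[["x_nm", "y_nm"]].to_numpy()


def write_phase_tiff(path, phase: np.ndarray, pixel_size_nm: float | None = None,
                     origin_nm: tuple[float, float] | None = None,
                     extra_meta: dict | None = None) -> None:
    tifffile.imwrite(path, np.asarray(phase, dtype=np.float32))
    meta = dict(extra_meta or {})
    if pixel_size_nm is not None:
        meta["pixel_size_nm"] = pixel_size_nm
    if origin_nm is not None:
        meta["origin_nm"] = list(origin_nm)
    if meta:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_phase_tiff(path) -> tuple[np.ndarray, dict]:
    img = tifffile.imread(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(img), meta


def write_recon(outdir, name: str, recon: ReconResult, options_meta: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"pixel_size_nm": recon.pixel_size_nm, "origin_nm": list(recon.origin_nm),
            "final_error": float(recon.final_error)}
    if options_meta:
        meta["options"] = options_meta
    write_phase_tiff(outdir / f"{name}_phase.tiff", recon.phase, extra_meta=meta)
    tifffile.imwrite(outdir / f"{name}_amplitude.tiff",
                     recon.amplitude.astype(np.float32))


def write_corpus(path, pairs) -> None:
    """Persist a training corpus as paired HDF5 datasets."""
    if not pairs:
        raise ValueError("cannot persist an empty corpus")
    with h5py.File(path, "w") as f:
        f.create_dataset("diffraction",
                         data=np.stack([p.diffraction for p in pairs]))
        f.create_dataset("phase",
                         data=np.stack([p.phase_label for p in pairs]))
        f.create_dataset("positions_nm",
                         data=np.array([p.position_nm for p in pairs]))
        f.create_dataset("scan_id",
                         data=np.array([p.scan_id for p in pairs], dtype=np.int64))


def read_corpus(path):
    from .continual import LabeledPair

    with h5py.File(path, "r") as f:
        for name in ("diffraction", "phase", "positions_nm", "scan_id"):
            if name not in f:
                raise ValueError(f"malformed corpus file: missing dataset '{name}'")
        d = f["diffraction"][...]
        ph = f["phase"][...]
        pos = f["positions_nm"][...]
        sid = f["scan_id"][...]
    return [LabeledPair(d[i], ph[i], (float(pos[i, 0]), float(pos[i, 1])),
                        int(sid[i])) for i in range(d.shape[0])]


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
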