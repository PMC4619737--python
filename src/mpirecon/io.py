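"""Readers and writers for the pipeline's on-disk formats.

pFOV stacks and raw signals travel as HDF5; image volumes as NIfTI
(.nii/.nii.gz) or TIFF, with 1D vectors as plain CSV; configs as YAML or
JSON; solve reports as CSV + JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .geometry import ScanGeometry
from .signal_chain import DriveTrajectory, RawSignal

__all__ = [
    "save_pfov_stack",
    "load_pfov_stack",
    "validate_stack_mean_free",
    "save_image",
    "load_image",
    "save_raw_signal",
    "load_raw_signal",
    "load_config",
    "save_solve_report",
]


def save_pfov_stack(path, stack: np.ndarray, geometry: ScanGeometry) -> None:
    """Write a pFOV stack: dataset /pfov plus geometry attributes."""
    stack = np.asarray(stack, dtype=np.float64).reshape(geometry.stack_shape)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("pfov", data=stack)
        ds.attrs["pfov_width"] = geometry.pfov_width
        ds.attrs["overlap"] = geometry.overlap
        ds.attrs["shift"] = geometry.shift
        ds.attrs["n_pfov"] = geometry.n_pfov
        ds.attrs["drive_axis"] = geometry.drive_axis
        ds.attrs["image_shape"] = np.asarray(geometry.image_shape)


def load_pfov_stack(path) -> tuple[np.ndarray, ScanGeometry]:
    with h5py.File(path, "r") as f:
        ds = f["pfov"]
        geom = ScanGeometry(
            image_shape=tuple(int(v) for v in ds.attrs["image_shape"]),
            pfov_width=int(ds.attrs["pfov_width"]),
            overlap=int(ds.attrs["overlap"]),
            n_pfov=int(ds.attrs["n_pfov"]),
            drive_axis=int(ds.attrs["drive_axis"]),
        )
        stack = np.asarray(ds[()], dtype=float)
    if stack.shape != geom.stack_shape:
        raise ValueError(f"stack shape {stack.shape} != geometry {geom.stack_shape}")
    return stack, geom


def validate_stack_mean_free(stack: np.ndarray, rtol: float = 1e-9) -> None:
    """Check every drive-axis line of every block is mean-free."""
    stack = np.asarray(stack, dtype=float)
    lines = stack.reshape(-1, stack.shape[-1])
    scale = max(np.abs(stack).max(), 1e-300)
    bad = np.abs(lines.mean(axis=1)) > rtol * scale
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} pFOV line(s) are not mean-free "
            f"(first offender: line {int(np.flatnonzero(bad)[0])})"
        )


def save_image(path, image: np.ndarray) -> None:
    """Write an image volume; format chosen by extension.

    .nii/.nii.gz via NIfTI, .tif/.tiff via TIFF, .csv for 1D vectors.
    """
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(image, affine=np.eye(4)), str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image)
    elif path.suffix == ".csv":
        if image.ndim != 1:
            raise ValueError("CSV image output is for 1D vectors only")
        np.savetxt(str(path), image, delimiter=",")
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def load_image(path) -> np.ndarray:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(str(path)), dtype=float)
    if path.suffix == ".csv":
        return np.loadtxt(str(path), delimiter=",", ndmin=1)
    raise ValueError(f"unsupported image format: {path.name}")


def save_raw_signal(path, signal: RawSignal) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=signal.samples)
        f.create_dataset("positions", data=signal.positions)
        f.create_dataset("velocities", data=signal.velocities)
        t = signal.trajectory
        for key in ("drive_frequency", "drive_amplitude", "shift_rate",
                    "sample_rate", "duration"):
            f.attrs[key] = getattr(t, key)


def load_raw_signal(path) -> RawSignal:
    with h5py.File(path, "r") as f:
        traj = DriveTrajectory(
            drive_frequency=float(f.attrs["drive_frequency"]),
            drive_amplitude=float(f.attrs["drive_amplitude"]),
            shift_rate=float(f.attrs["shift_rate"]),
            sample_rate=float(f.attrs["sample_rate"]),
            duration=float(f.attrs["duration"]),
        )
        return RawSignal(
            samples=np.asarray(f["samples"][()], dtype=float),
            positions=np.asarray(f["positions"][()], dtype=float),
            velocities=np.asarray(f["velocities"][()], dtype=float),
            trajectory=traj,
        )


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path.name} must be a mapping")
    return cfg


def save_solve_report(csv_path, json_path, report) -> None:
    """Write per-iteration objectives as CSV and a summary as JSON."""
    rows = np.column_stack([np.arange(1, len(report.iterates) + 1),
                            np.asarray(report.iterates)])
    np.savetxt(str(csv_path), rows, delimiter=",", header="iteration,objective",
               comments="")
    summary = {
        "final_objective": float(report.final_objective),
        "n_iters": int(report.n_iters),
        "step_size": float(report.step_size),
        "converged": bool(report.converged),
    }
    Path(json_path).write_text(json.dumps(summary, indent=2))
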