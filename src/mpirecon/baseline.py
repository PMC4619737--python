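"""Baseline 1D DC-recovery stitching, Wiener deconvolution, and metrics.

The baseline reimplements, in spirit, the line-by-line continuity approach
that preceded the convex formulation: each drive-axis line is stitched
left to right, offsetting every pFOV so its overlap region matches the
running estimate, then anchoring the FOV edge at zero.  Because lines are
processed independently, noise in the per-line offsets shows up as banding
across the transverse axes — the artifact the joint optimization removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry, unvectorize

__all__ = [
    "ReconReport",
    "stitch_1d_dc",
    "wiener_deconvolve",
    "banding_index",
    "compare_reconstructions",
]


@dataclass
class ReconReport:
    """Error metrics of one reconstruction against ground truth."""

    label: str
    rmse: float
    rmse_up_to_dc: float
    banding_index: float


def stitch_1d_dc(stack: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Sequential per-line DC stitching of a pFOV stack.

    Per drive-axis line: the first pFOV is placed as-is; each subsequent
    pFOV is offset by (mean of the current estimate over the overlap −
    mean of the pFOV over the overlap); overlapping pixels are averaged;
    finally the line is shifted so the first FOV-edge pixel is zero.

    Returns the stitched image in ``image_shape`` layout.
    """
    if geometry.overlap < 1:
        raise ValueError("stitching requires a nonzero overlap")
    stack = np.asarray(stack, dtype=float).reshape(geometry.stack_shape)
    N, p, d, s = (geometry.n_pfov, geometry.pfov_width, geometry.shift,
                  geometry.overlap)
    t = geometry.n_transverse
    L = geometry.drive_extent
    blocks = stack.reshape(N, t, p)

    out = np.zeros((t, L))
    for line in range(t):
        acc = np.zeros(L)
        cnt = np.zeros(L)
        acc[:p] = blocks[0, line]
        cnt[:p] = 1.0
        for k in range(1, N):
            start = k * d
            est = acc[start : start + s] / np.maximum(cnt[start : start + s], 1.0)
            offset = est.mean() - blocks[k, line, :s].mean()
            shifted = blocks[k, line] + offset
            acc[start : start + p] += shifted
            cnt[start : start + p] += 1.0
        stitched = acc / np.maximum(cnt, 1.0)
        out[line] = stitched - stitched[0]  # anchor the FOV edge at zero
    vec = out.reshape(-1)
    return unvectorize(vec, geometry)


def wiener_deconvolve(image: np.ndarray, kernel: np.ndarray, nsr: float) -> np.ndarray:
    """Wiener deconvolution W = H* / (|H|² + nsr) in the Fourier domain.

    ``nsr`` is the (assumed flat) noise-to-signal power ratio; 0 gives an
    inverse filter.  The kernel is embedded centered so the output is not
    shifted.  Real-valued output of the input's shape.
    """
    if nsr < 0:
        raise ValueError("nsr must be >= 0")
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    pad = np.zeros(image.shape)
    slices = tuple(slice(0, k) for k in kernel.shape)
    pad[slices] = kernel
    # center the kernel at the origin so H carries no linear phase
    pad = np.roll(pad, [-(k // 2) for k in kernel.shape], axis=range(image.ndim))
    H = np.fft.fftn(pad)
    W = np.conj(H) / (np.abs(H) ** 2 + nsr + (1e-300 if nsr == 0 else 0.0))
    return np.real(np.fft.ifftn(np.fft.fftn(image) * W))


def estimate_nsr(image: np.ndarray, corner_frac: float = 0.125) -> float:
    """Noise-to-signal power ratio estimated from a signal-free corner patch."""
    image = np.asarray(image, dtype=float)
    patch = image[tuple(slice(0, max(int(corner_frac * s), 2)) for s in image.shape)]
    noise_power = float(np.var(patch))
    signal_power = float(np.mean(image**2))
    return noise_power / max(signal_power, 1e-300)


def banding_index(error: np.ndarray, drive_axis: int = -1) -> float:
    """Std of per-line means of the error along the drive axis.

    Line-independent DC mistakes shift whole drive-axis lines up or down;
    the spread of those per-line offsets quantifies banding.
    """
    error = np.asarray(error, dtype=float)
    line_means = error.mean(axis=drive_axis)
    return float(np.std(line_means))


def compare_reconstructions(truth: np.ndarray, estimates, labels=None,
                            drive_axis: int = -1) -> list[ReconReport]:
    """RMSE, DC-invariant RMSE and banding index for each estimate."""
    truth = np.asarray(truth, dtype=float)
    if labels is None:
        labels = [f"estimate_{i}" for i in range(len(estimates))]
    reports = []
    for label, est in zip(labels, estimates):
        est = np.asarray(est, dtype=float)
        if est.shape != truth.shape:
            raise ValueError(f"{label}: shape {est.shape} != truth {truth.shape}")
        err = est - truth
        rmse = float(np.sqrt(np.mean(err**2)))
        c = -float(np.mean(err))  # offset minimizing RMSE(est + c, truth)
        rmse_dc = float(np.sqrt(np.mean((err + c) ** 2)))
        reports.append(
            ReconReport(label=label, rmse=rmse, rmse_up_to_dc=rmse_dc,
                        banding_index=banding_index(err, drive_axis))
        )
    return reports
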