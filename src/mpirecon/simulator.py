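"""Synthetic scan simulation: phantoms, PSFs, native images, pFOV data.

The imaging chain being emulated: a non-negative nanoparticle density is
convolved with a strictly positive, smooth point spread function to form
the *native image*; the scanner acquires the native image as overlapping
partial FOVs along the drive axis; hardware direct-feedthrough filtering
destroys the mean of every drive-axis line within every pFOV.  The
simulator reproduces exactly that sequence, with optional additive white
Gaussian receive noise, and is the fixture generator for every test in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import scipy.ndimage

from .geometry import ScanGeometry, vectorize, unvectorize
from .operators import make_forward, make_segmentation

__all__ = [
    "PhantomSpec",
    "PSFModel",
    "NoiseModel",
    "make_phantom",
    "psf_kernel",
    "native_image",
    "simulate_partial_fovs",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    kind : one of {"point", "points", "helix", "vessel_tree", "random_blobs"}.
    shape : image dimensions in pixels.
    pixel_pitch_mm : physical size of a pixel (isotropic), used by the
        mm-specified kinds.
    tube_id_mm : inner diameter of the helix tubing (default 0.6 mm).
    cylinder_od_mm : outer diameter of the cylinder the helix winds around
        (default 27 mm).
    length_mm : axial length of the helix (default 65 mm).
    n_turns : helix turns over the length.
    n_points / n_blobs : counts for the random kinds.
    seed : RNG seed for the random kinds.
    """

    kind: str = "random_blobs"
    shape: tuple[int, ...] = (32, 64)
    pixel_pitch_mm: float = 0.5
    tube_id_mm: float = 0.6
    cylinder_od_mm: float = 27.0
    length_mm: float = 65.0
    n_turns: float = 4.0
    n_points: int = 5
    n_blobs: int = 6
    seed: int = 0


@dataclass
class PSFModel:
    """Point-spread-function model.

    family : "gaussian" or "langevin_derivative".  Both are strictly
        positive, even-symmetric and normalized to unit sum; the
        Langevin-derivative family uses dL/du with L(u) = coth(u) - 1/u,
        the line shape of an ideal saturating tracer.
    fwhm : full width at half maximum per axis, in pixels (scalar or
        per-axis sequence).
    support_radius : kernel half-width in pixels; defaults to ~3 FWHM.
    """

    family: str = "gaussian"
    fwhm: float | tuple[float, ...] = 4.0
    support_radius: int | None = None


@dataclass
class NoiseModel:
    """Additive white Gaussian noise on pFOV samples."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def _rasterize_curve(shape, points, radius_px):
    """Mark voxels within radius_px of a densely sampled curve."""
    vol = np.zeros(shape)
    idx = np.round(points).astype(int)
    r = max(int(np.ceil(radius_px)), 0)
    for pt, ipt in zip(points, idx):
        lo = [max(c - r, 0) for c in ipt]
        hi = [min(c + r + 1, s) for c, s in zip(ipt, shape)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, pt))
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        vol[sub] = np.maximum(vol[sub], (d2 <= radius_px**2).astype(float))
    return vol


def _helix_points(spec: PhantomSpec, shape):
    """Sample two interleaved helices on a cylinder, axis along last axis."""
    pitch = spec.pixel_pitch_mm
    length_px = spec.length_mm / pitch
    rad_px = 0.5 * spec.cylinder_od_mm / pitch
    axis_len = min(length_px, shape[-1] - 1)
    center = [0.5 * (s - 1) for s in shape[:-1]]
    z0 = 0.5 * (shape[-1] - 1 - axis_len)
    n_samp = max(int(8 * axis_len), 200)
    tgrid = np.linspace(0.0, 1.0, n_samp)
    curves = []
    for phase in (0.0, np.pi):
        theta = 2 * np.pi * spec.n_turns * tgrid + phase
        z = z0 + axis_len * tgrid
        if len(shape) == 3:
            x = center[0] + rad_px * np.cos(theta)
            y = center[1] + rad_px * np.sin(theta)
            pts = np.stack([x, y, z], axis=1)
        else:  # 2D: project the cylinder onto the plane
            x = center[0] + rad_px * np.cos(theta)
            pts = np.stack([x, z], axis=1)
        curves.append(pts)
    return curves


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Build a non-negative density map; deterministic given the seed."""
    shape = tuple(int(v) for v in spec.shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"phantom shape must be positive: {shape}")
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "point":
        vol = np.zeros(shape)
        vol[tuple(s // 2 for s in shape)] = 1.0
        return vol

    if spec.kind == "points":
        vol = np.zeros(shape)
        for _ in range(spec.n_points):
            vol[tuple(rng.integers(0, s) for s in shape)] = rng.uniform(0.5, 1.5)
        return vol

    if spec.kind == "helix":
        radius_px = 0.5 * spec.tube_id_mm / spec.pixel_pitch_mm
        if radius_px < 0.5:
            warnings.warn(
                "tube diameter below pixel pitch; rasterizing a single-voxel-thick tube"
            )
            radius_px = 0.5
        vol = np.zeros(shape)
        for pts in _helix_points(spec, shape):
            vol = np.maximum(vol, _rasterize_curve(shape, pts, radius_px))
        return vol

    if spec.kind == "vessel_tree":
        # a trunk along the last axis that forks into two branches
        radius_px = max(0.5 * spec.tube_id_mm / spec.pixel_pitch_mm, 0.8)
        center = np.array([0.5 * (s - 1) for s in shape])
        L = shape[-1]
        t_trunk = np.linspace(0.1 * L, 0.55 * L, 8 * L)
        trunk = np.tile(center, (t_trunk.size, 1))
        trunk[:, -1] = t_trunk
        vol = _rasterize_curve(shape, trunk, radius_px)
        t_br = np.linspace(0.55 * L, 0.9 * L, 8 * L)
        for sgn in (+1.0, -1.0):
            br = np.tile(center, (t_br.size, 1))
            br[:, -1] = t_br
            br[:, 0] = center[0] + sgn * 0.25 * shape[0] * (t_br - t_br[0]) / (
                t_br[-1] - t_br[0]
            )
            vol = np.maximum(vol, _rasterize_curve(shape, br, radius_px))
        return vol

    if spec.kind == "random_blobs":
        vol = np.zeros(shape)
        coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        for _ in range(spec.n_blobs):
            mu = [rng.uniform(0.15 * s, 0.85 * s) for s in shape]
            width = [rng.uniform(0.04 * s + 1, 0.12 * s + 1) for s in shape]
            amp = rng.uniform(0.5, 1.5)
            g = amp * np.exp(
                -sum(((c - m) / w) ** 2 for c, m, w in zip(coords, mu, width))
            )
            vol += g
        # keep the FOV edges along the last axis clear of tracer, the scan
        # prescription that pins the global DC value
        taper = np.ones(shape[-1])
        edge = max(shape[-1] // 8, 2)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        taper[:edge] = ramp
        taper[-edge:] = ramp[::-1]
        vol *= taper
        vol[vol < 1e-3 * vol.max()] = 0.0
        return vol

    raise ValueError(f"unknown phantom kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

def _langevin_derivative(u: np.ndarray) -> np.ndarray:
    # dL/du for L(u) = coth(u) - 1/u; even, positive, peak 1/3 at u=0
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-4
    out[small] = 1.0 / 3.0 - u[small] ** 2 / 15.0
    ub = u[~small]
    out[~small] = 1.0 / ub**2 - 1.0 / np.sinh(ub) ** 2
    return out


def psf_kernel(model: PSFModel, ndim: int) -> np.ndarray:
    """Sample a separable, strictly positive, unit-sum kernel."""
    fwhm = np.atleast_1d(np.asarray(model.fwhm, dtype=float))
    if fwhm.size == 1:
        fwhm = np.full(ndim, float(fwhm[0]))
    if fwhm.size != ndim:
        raise ValueError(f"fwhm must be scalar or length-{ndim}")
    if np.any(fwhm <= 0):
        raise ValueError("fwhm must be positive")
    axes = []
    for f in fwhm:
        radius = model.support_radius or max(int(np.ceil(3.0 * f)), 1)
        x = np.arange(-radius, radius + 1, dtype=float)
        if model.family == "gaussian":
            sigma = f / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            line = np.exp(-0.5 * (x / sigma) ** 2)
        elif model.family == "langevin_derivative":
            # dL/du falls to half its peak near |u| ≈ 2.0
            scale = f / (2.0 * 2.0)
            line = _langevin_derivative(x / max(scale, 1e-9))
        else:
            raise ValueError(f"unknown PSF family {model.family!r}")
        line = np.maximum(line, 1e-300)  # strict positivity on the support
        axes.append(line)
    kern = axes[0]
    for line in axes[1:]:
        kern = np.multiply.outer(kern, line)
    return kern / kern.sum()


def native_image(density: np.ndarray, psf) -> np.ndarray:
    """Convolve the density with the PSF (replicate edge handling).

    ``psf`` may be a :class:`PSFModel` or an explicit kernel array.
    """
    density = np.asarray(density, dtype=float)
    kern = psf_kernel(psf, density.ndim) if isinstance(psf, PSFModel) else np.asarray(psf)
    if any(k > s for k, s in zip(kern.shape, density.shape)):
        raise ValueError(f"kernel {kern.shape} larger than image {density.shape}")
    out = scipy.ndimage.convolve(density, kern, mode="nearest")
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Partial-FOV data
# ---------------------------------------------------------------------------

def simulate_partial_fovs(image: np.ndarray, geometry: ScanGeometry,
                          noise: NoiseModel | None = None,
                          dc_mode: str = "remove") -> np.ndarray:
    """Acquire an image as overlapping pFOV blocks, with optional DC loss.

    dc_mode="remove": output = per-line re-centered (S·ρ + noise), i.e.
    exactly A·ρ in the noiseless case, and mean-free per drive-axis line
    even with noise (noise is added before the DC filter, as in hardware).
    dc_mode="keep": output = S·ρ + noise, for baseline testing.

    Returns the stack in working layout ``(N, *transverse, p)``.
    """
    if dc_mode not in ("remove", "keep"):
        raise ValueError(f"dc_mode must be 'remove' or 'keep', got {dc_mode!r}")
    rho = vectorize(np.asarray(image, dtype=float), geometry)
    data = make_segmentation(geometry).forward(rho)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data = data + rng.normal(0.0, noise.sigma, size=data.size)
    if dc_mode == "remove":
        lines = data.reshape(-1, geometry.pfov_width)
        data = (lines - lines.mean(axis=1, keepdims=True)).reshape(-1)
    return data.reshape(geometry.stack_shape)
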