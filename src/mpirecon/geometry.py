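"""Scan geometry for partial-FOV acquisitions.

A partial FOV (pFOV) is the stretch of the image the field-free region
sweeps during one drive-field traversal.  Adjacent pFOVs overlap along the
drive axis; the shift between consecutive pFOV start pixels is
``d = p - s`` where ``p`` is the pFOV width and ``s`` the overlap, both in
pixels.  Only integer shifts are supported: gridding is expected to choose
pixel grids that make the shift integral.

Vectorization convention
------------------------
Images are vectorized row-major with the drive axis fastest-varying.  The
*working layout* of an image array is therefore its axes permuted so the
drive axis is last; ``vectorize``/``unvectorize`` handle the permutation.
A pFOV stack has working shape ``(n_pfov, *transverse_shape, pfov_width)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import numpy as np

__all__ = ["ScanGeometry", "vectorize", "unvectorize"]


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of an overlapping partial-FOV scan.

    Parameters
    ----------
    image_shape
        Pixels per image axis (1-3 axes).
    pfov_width
        pFOV extent ``p`` along the drive axis, in pixels.
    overlap
        Shared pixels ``s`` between adjacent pFOVs; the shift is ``p - s``.
    n_pfov
        Number of pFOVs ``N``.
    drive_axis
        Axis of ``image_shape`` along which the drive field sweeps.
    """

    image_shape: tuple[int, ...]
    pfov_width: int
    overlap: int
    n_pfov: int
    drive_axis: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape", tuple(int(v) for v in self.image_shape))
        ndim = len(self.image_shape)
        if not 1 <= ndim <= 3:
            raise ValueError(f"image_shape must have 1-3 axes, got {ndim}")
        if any(v <= 0 for v in self.image_shape):
            raise ValueError(f"image_shape entries must be positive: {self.image_shape}")
        axis = self.drive_axis if self.drive_axis >= 0 else ndim + self.drive_axis
        if not 0 <= axis < ndim:
            raise ValueError(f"drive_axis {self.drive_axis} invalid for {ndim}-D image")
        object.__setattr__(self, "drive_axis", axis)
        p, s, n = self.pfov_width, self.overlap, self.n_pfov
        if p < 1 or n < 1:
            raise ValueError("pfov_width and n_pfov must be >= 1")
        d = p - s
        if not 1 <= d <= p:
            raise ValueError(
                f"overlap {s} with pfov_width {p} gives shift {d}; need 1 <= shift <= width"
            )
        extent = d * (n - 1) + p
        if self.image_shape[axis] != extent:
            raise ValueError(
                f"drive-axis extent {self.image_shape[axis]} inconsistent with "
                f"shift*(N-1)+p = {extent} (p={p}, s={s}, N={n})"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def shift(self) -> int:
        """Drive-axis shift ``d = p - s`` between consecutive pFOVs."""
        return self.pfov_width - self.overlap

    @property
    def drive_extent(self) -> int:
        return self.image_shape[self.drive_axis]

    @property
    def transverse_shape(self) -> tuple[int, ...]:
        return tuple(
            v for i, v in enumerate(self.image_shape) if i != self.drive_axis
        )

    @property
    def n_transverse(self) -> int:
        return prod(self.transverse_shape) if self.transverse_shape else 1

    @property
    def n_pixels(self) -> int:
        """Image vector length ``n``."""
        return prod(self.image_shape)

    @property
    def n_data(self) -> int:
        """Data vector length ``m = N * n_transverse * p``."""
        return self.n_pfov * self.n_transverse * self.pfov_width

    @property
    def working_shape(self) -> tuple[int, ...]:
        """Image shape with the drive axis moved last."""
        return self.transverse_shape + (self.drive_extent,)

    @property
    def stack_shape(self) -> tuple[int, ...]:
        """pFOV stack shape ``(N, *transverse, p)``."""
        return (self.n_pfov,) + self.transverse_shape + (self.pfov_width,)

    def pfov_start(self, k: int) -> int:
        """Drive-axis start pixel of pFOV ``k``."""
        return k * self.shift


def vectorize(image: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Flatten an image row-major with the drive axis fastest-varying."""
    image = np.asarray(image)
    if image.shape != geometry.image_shape:
        raise ValueError(f"image shape {image.shape} != geometry {geometry.image_shape}")
    return np.moveaxis(image, geometry.drive_axis, -1).reshape(-1)


def unvectorize(vec: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Inverse of :func:`vectorize`: vector back to ``image_shape``."""
    vec = np.asarray(vec)
    if vec.size != geometry.n_pixels:
        raise ValueError(f"vector length {vec.size} != n_pixels {geometry.n_pixels}")
    work = vec.reshape(geometry.working_shape)
    return np.moveaxis(work, -1, geometry.drive_axis)
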