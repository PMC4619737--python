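"""SVD conditioning diagnostics of the 1D forward operator.

The singular spectrum of ``A = D S`` explains when DC recovery is well
posed: the global image mean is in the nullspace (one zero singular
value), while pixels covered by ``c`` overlapping pFOVs contribute
singular-value plateaus at √c — the signal-averaging gain.  Dropping the
DC singular value ("reduced A") leaves a modest condition number that
degrades only when the overlap becomes a small fraction of the pFOV
width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry
from .operators import make_forward, materialize

__all__ = [
    "SVDReport",
    "coverage_profile",
    "operator_svd",
    "condition_number_reduced",
    "plateau_value",
    "overlap_sweep",
    "default_fig_geometry",
]

DC_THRESHOLD = 1e-10  # relative cutoff for "the DC singular value"


def default_fig_geometry(pfov_width: int = 20, overlap: int = 15,
                         n_pfov: int = 18) -> ScanGeometry:
    """The reference 1D analysis geometry: p=20, s=15, N=18 (n=105).

    N=18 is the pFOV count whose 4-fold-coverage plateau contains exactly
    64 singular values; the reduced condition number there is ~6.
    """
    d = pfov_width - overlap
    n = d * (n_pfov - 1) + pfov_width
    return ScanGeometry((n,), pfov_width, overlap, n_pfov)


def coverage_profile(geometry: ScanGeometry) -> np.ndarray:
    """Number of pFOV windows acquiring each drive-axis pixel."""
    if len(geometry.image_shape) != 1:
        raise ValueError("coverage_profile expects a 1D geometry")
    cov = np.zeros(geometry.drive_extent, dtype=int)
    for k in range(geometry.n_pfov):
        start = geometry.pfov_start(k)
        cov[start : start + geometry.pfov_width] += 1
    return cov


@dataclass
class SVDReport:
    """Full SVD of the dense 1D forward operator plus derived diagnostics."""

    singular_values: np.ndarray          # descending
    right_singular_vectors: np.ndarray   # columns of V, matching order
    coverage: np.ndarray
    condition_number_reduced: float
    geometry: ScanGeometry


def operator_svd(geometry: ScanGeometry, max_entries: int = 50_000_000) -> SVDReport:
    """Materialize A for a 1D geometry and compute its full SVD."""
    if len(geometry.image_shape) != 1:
        raise ValueError("operator_svd expects a 1D geometry")
    A = materialize(make_forward(geometry), max_entries=max_entries,
                    check_adjoint=False)
    _, sv, vt = np.linalg.svd(A, full_matrices=False)
    cov = coverage_profile(geometry)
    return SVDReport(
        singular_values=sv,
        right_singular_vectors=vt.T,
        coverage=cov,
        condition_number_reduced=_reduced_condition(sv),
        geometry=geometry,
    )


def _reduced_condition(sv: np.ndarray) -> float:
    keep = sv[sv > DC_THRESHOLD * sv[0]]
    if keep.size < 2:
        raise ValueError("fewer than two retained singular values; degenerate geometry")
    return float(keep[0] / keep[-1])


def condition_number_reduced(geometry: ScanGeometry) -> float:
    """σ_max/σ_min of A after discarding the near-zero DC singular value."""
    return operator_svd(geometry).condition_number_reduced


def plateau_value(report: SVDReport, coverage_level: int = 4,
                  energy_fraction: float = 0.75) -> float:
    """Magnitude of the singular-value plateau for a given coverage level.

    Selects singular vectors with at least ``energy_fraction`` of their
    energy on pixels acquired exactly ``coverage_level`` times and returns
    the median of the matching singular values — the √coverage averaging
    gain of that image region.
    """
    mask = report.coverage == coverage_level
    if not mask.any():
        raise ValueError(f"no pixels with coverage {coverage_level}")
    V = report.right_singular_vectors
    energy = (V[mask, :] ** 2).sum(axis=0) / (V**2).sum(axis=0)
    sel = report.singular_values[energy >= energy_fraction]
    if sel.size == 0:
        raise ValueError("no singular vectors supported on the requested region")
    return float(np.median(sel))


def plateau_count(report: SVDReport, value: float, rtol: float = 0.02) -> int:
    """Number of singular values within ``rtol`` of ``value``."""
    sv = report.singular_values
    return int(np.sum(np.abs(sv - value) <= rtol * value))


def overlap_sweep(pfov_width: int, overlaps, n_pixels: int = 105) -> dict[int, float]:
    """Reduced condition number as a function of pFOV overlap.

    Sweeps the pulse-sequence overlap at (approximately) fixed FOV length
    ``n_pixels``: for each overlap the pFOV count is chosen so the image
    extent is as close to ``n_pixels`` as integer shifts allow.  Returns
    ``{overlap: condition_number_reduced}``; the condition number
    improves (decreases) with overlap, and degrades noticeably only once
    the overlap is a small fraction of the pFOV width.
    """
    table: dict[int, float] = {}
    for s in overlaps:
        s = int(s)
        d = pfov_width - s
        if d < 1:
            raise ValueError(f"overlap {s} >= pfov_width {pfov_width}")
        N = max(round((n_pixels - pfov_width) / d) + 1, 2)
        geom = default_fig_geometry(pfov_width, s, N)
        table[s] = condition_number_reduced(geom)
    return table


def sweep_trend_slope(table: dict[int, float]) -> float:
    """Least-squares slope of condition number vs overlap over a sweep."""
    x = np.array(sorted(table), dtype=float)
    y = np.array([table[int(v)] for v in x])
    if x.size == 1:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])
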