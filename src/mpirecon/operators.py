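"""Matrix-free linear operators for the partial-FOV forward model.

The forward model of DC-filtered x-space acquisition is ``A = D S``:
``S`` segments the image into overlapping pFOV blocks along the drive axis
and ``D`` removes the mean of every drive-axis line within every block
(the DC component lost to direct-feedthrough filtering).  Storing these as
sparse matrices is wasteful at volume scale, so each operator is encoded
as a pair of functions (forward apply, adjoint apply) with shape metadata;
``materialize`` recovers the dense matrix for small problems and
``dot_product_test`` checks adjoint consistency on random probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import ScanGeometry

__all__ = [
    "LinearMap",
    "StackedSystem",
    "make_segmentation",
    "make_dc_removal",
    "make_forward",
    "make_gradient",
    "stack_operators",
    "materialize",
    "dot_product_test",
]

DENSE_GUARD = 50_000_000  # max entries materialize() will allocate


class LinearMap:
    """A linear operator encoded as forward/adjoint functions.

    Parameters
    ----------
    n_rows, n_cols
        Shape ``(m, n)`` of the represented matrix.
    forward
        Callable mapping a length-``n`` vector to a length-``m`` vector.
    adjoint
        Callable mapping a length-``m`` vector to a length-``n`` vector;
        must implement the exact transpose of ``forward``.
    label
        Short name used in reports and error messages.
    domain_shape
        Optional working-layout image shape of the domain (metadata used
        when stacking regularizer blocks).
    """

    def __init__(self, n_rows, n_cols, forward, adjoint, label="map", domain_shape=None):
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self._forward = forward
        self._adjoint = adjoint
        self.label = label
        self.domain_shape = tuple(domain_shape) if domain_shape is not None else None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.size != self.n_cols:
            raise ValueError(f"{self.label}: forward input length {x.size} != {self.n_cols}")
        y = np.asarray(self._forward(x), dtype=float).reshape(-1)
        if y.size != self.n_rows:
            raise RuntimeError(f"{self.label}: forward output length {y.size} != {self.n_rows}")
        return y

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size != self.n_rows:
            raise ValueError(f"{self.label}: adjoint input length {y.size} != {self.n_rows}")
        x = np.asarray(self._adjoint(y), dtype=float).reshape(-1)
        if x.size != self.n_cols:
            raise RuntimeError(f"{self.label}: adjoint output length {x.size} != {self.n_cols}")
        return x

    __call__ = forward

    def __matmul__(self, other: "LinearMap") -> "LinearMap":
        """Composition ``self @ other`` (apply ``other`` first)."""
        if self.n_cols != other.n_rows:
            raise ValueError(
                f"cannot compose {self.label}{self.shape} with {other.label}{other.shape}"
            )
        return LinearMap(
            self.n_rows,
            other.n_cols,
            lambda x: self.forward(other.forward(x)),
            lambda y: other.adjoint(self.adjoint(y)),
            label=f"{self.label}∘{other.label}",
            domain_shape=other.domain_shape,
        )

    def scaled(self, c: float) -> "LinearMap":
        c = float(c)
        return LinearMap(
            self.n_rows,
            self.n_cols,
            lambda x: c * self.forward(x),
            lambda y: c * self.adjoint(y),
            label=f"{c:g}·{self.label}",
            domain_shape=self.domain_shape,
        )

    def __repr__(self) -> str:
        return f"LinearMap({self.label}, {self.n_rows}x{self.n_cols})"


def identity_map(n: int, label: str = "I") -> LinearMap:
    return LinearMap(n, n, lambda x: x.copy(), lambda y: y.copy(), label=label)


def vstack_maps(maps: list[LinearMap], label: str = "stack") -> LinearMap:
    """Stack operators vertically: ``[M1; M2; ...]``."""
    n = maps[0].n_cols
    if any(m.n_cols != n for m in maps):
        raise ValueError("vstack requires equal n_cols")
    rows = [m.n_rows for m in maps]
    offsets = np.concatenate([[0], np.cumsum(rows)])
    m_total = int(offsets[-1])

    def forward(x):
        return np.concatenate([m.forward(x) for m in maps])

    def adjoint(y):
        out = np.zeros(n)
        for m, lo, hi in zip(maps, offsets[:-1], offsets[1:]):
            out += m.adjoint(y[lo:hi])
        return out

    return LinearMap(m_total, n, forward, adjoint, label=label,
                     domain_shape=maps[0].domain_shape)


# ---------------------------------------------------------------------------
# Segmentation S
# ---------------------------------------------------------------------------

def make_segmentation(geometry: ScanGeometry) -> LinearMap:
    """Segmentation operator S: image -> stack of overlapping pFOV blocks.

    pFOV ``k`` copies the drive-axis window ``[k*d, k*d + p)`` of every
    transverse line.  The adjoint scatters block values back and sums, so
    ``SᵀS`` is diagonal with the per-pixel coverage counts.
    """
    p, d, N = geometry.pfov_width, geometry.shift, geometry.n_pfov
    t = geometry.n_transverse
    L = geometry.drive_extent
    n, m = geometry.n_pixels, geometry.n_data

    def forward(x):
        lines = x.reshape(t, L)
        # (t, N, p) windows at stride d, then blocks-first layout (N, t, p)
        win = sliding_window_view(lines, p, axis=1)[:, ::d, :]
        return np.ascontiguousarray(np.swapaxes(win, 0, 1)).reshape(-1)

    def adjoint(y):
        blocks = y.reshape(N, t, p)
        out = np.zeros((t, L))
        for k in range(N):
            out[:, k * d : k * d + p] += blocks[k]
        return out.reshape(-1)

    return LinearMap(m, n, forward, adjoint, label="S",
                     domain_shape=geometry.working_shape)


# ---------------------------------------------------------------------------
# DC removal D
# ---------------------------------------------------------------------------

def make_dc_removal(geometry: ScanGeometry) -> LinearMap:
    """DC-removal operator D: subtract each drive-axis line's mean.

    Block-diagonal in ``R = I_p - (1/p) 11ᵀ``, one block per drive-axis
    line per pFOV.  R is an orthogonal projection, hence symmetric and
    idempotent; the adjoint equals the forward map.
    """
    p = geometry.pfov_width
    m = geometry.n_data

    def apply(y):
        lines = y.reshape(-1, p)
        return (lines - lines.mean(axis=1, keepdims=True)).reshape(-1)

    return LinearMap(m, m, apply, apply, label="D")


# ---------------------------------------------------------------------------
# Forward model A = D S
# ---------------------------------------------------------------------------

def make_forward(geometry: ScanGeometry) -> LinearMap:
    """Forward model ``A = D S`` mapping an image to mean-free pFOV data."""
    A = make_dc_removal(geometry) @ make_segmentation(geometry)
    A.label = "A"
    return A


# ---------------------------------------------------------------------------
# Finite-difference gradient
# ---------------------------------------------------------------------------

def make_gradient(axis: int, image_shape: tuple[int, ...]) -> LinearMap:
    """Forward-difference gradient along ``axis`` of a working-layout image.

    Uses a replicate (Neumann) boundary: the last difference along the
    axis is zero, so constants map to zero exactly.  The adjoint is the
    exact transpose (a negative divergence with matching boundary).
    """
    shape = tuple(int(v) for v in image_shape)
    ndim = len(shape)
    ax = axis if axis >= 0 else ndim + axis
    if not 0 <= ax < ndim:
        raise ValueError(f"axis {axis} out of range for shape {shape}")
    n = int(np.prod(shape))

    def forward(x):
        img = x.reshape(shape)
        g = np.zeros(shape)
        src = [slice(None)] * ndim
        dst = [slice(None)] * ndim
        src[ax] = slice(1, None)
        dst[ax] = slice(0, -1)
        g[tuple(dst)] = img[tuple(src)] - img[tuple(dst)]
        return g.reshape(-1)

    def adjoint(y):
        g = y.reshape(shape)
        out = np.zeros(shape)
        sl_head = [slice(None)] * ndim
        sl_head[ax] = slice(0, -1)
        sl_tail = [slice(None)] * ndim
        sl_tail[ax] = slice(1, None)
        out[tuple(sl_tail)] += g[tuple(sl_head)]
        out[tuple(sl_head)] -= g[tuple(sl_head)]
        return out.reshape(-1)

    return LinearMap(n, n, forward, adjoint, label=f"∇{ax}", domain_shape=shape)


# ---------------------------------------------------------------------------
# Stacked system T, w
# ---------------------------------------------------------------------------

@dataclass
class StackedSystem:
    """The stacked least-squares system ``min ‖Tρ − w‖², ρ ≥ 0``.

    ``T = [A; √α I; √β_i ∇_i]`` and ``w = [b; 0; 0]``, with the √ scaling
    chosen so ``‖Tρ − w‖²`` equals the regularized objective
    ``‖Aρ − b‖² + α‖ρ‖² + Σ_i β_i‖∇_iρ‖²`` exactly.
    """

    T: LinearMap
    w: np.ndarray
    A: LinearMap
    b: np.ndarray
    alpha: float
    beta: tuple[float, ...]


def _beta_tuple(beta, ndim: int) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(beta, dtype=float))
    if arr.size == 1:
        arr = np.full(ndim, float(arr[0]))
    if arr.size != ndim:
        raise ValueError(f"beta must be scalar or length-{ndim}, got {arr.size}")
    return tuple(float(v) for v in arr)


def stack_operators(A: LinearMap, alpha, beta, b: np.ndarray) -> StackedSystem:
    """Build the stacked system from the forward model and penalty weights.

    Weight blocks with zero weight are dropped, so with α = β = 0 the
    stacked operator is A itself and ``w = b``.
    """
    if A.domain_shape is None:
        raise ValueError("A must carry a domain_shape to build gradient blocks")
    alpha = float(alpha)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    betas = _beta_tuple(beta, len(A.domain_shape))
    if any(v < 0 for v in betas):
        raise ValueError("beta weights must be >= 0")
    b = np.asarray(b, dtype=float).reshape(-1)
    if b.size != A.n_rows:
        raise ValueError(f"b length {b.size} != A rows {A.n_rows}")

    maps = [A]
    if alpha > 0:
        maps.append(identity_map(A.n_cols).scaled(np.sqrt(alpha)))
    for ax, bv in enumerate(betas):
        if bv > 0:
            maps.append(make_gradient(ax, A.domain_shape).scaled(np.sqrt(bv)))
    T = A if len(maps) == 1 else vstack_maps(maps, label="T")
    T.label = "T"
    w = np.zeros(T.n_rows)
    w[: b.size] = b
    return StackedSystem(T=T, w=w, A=A, b=b, alpha=alpha, beta=betas)


# ---------------------------------------------------------------------------
# Dense materialization and the dot-product test
# ---------------------------------------------------------------------------

def materialize(op: LinearMap, max_entries: int = DENSE_GUARD,
                check_adjoint: bool = True, rtol: float = 1e-12) -> np.ndarray:
    """Return the dense matrix of ``op`` by applying it to identity columns.

    Also materializes the adjoint and verifies it equals the transpose to
    ``rtol`` (relative to the largest entry), guarding against silently
    inconsistent operator pairs.
    """
    m, n = op.shape
    if m * n > max_entries:
        raise ValueError(
            f"{op.label}: {m}x{n} = {m * n} entries exceeds guard {max_entries}"
        )
    cols = np.empty((m, n))
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        cols[:, j] = op.forward(e)
        e[j] = 0.0
    if check_adjoint:
        rows = np.empty((n, m))
        f = np.zeros(m)
        for i in range(m):
            f[i] = 1.0
            rows[:, i] = op.adjoint(f)
            f[i] = 0.0
        scale = max(np.abs(cols).max(), 1e-300)
        err = np.abs(rows - cols.T).max() / scale
        if err > rtol:
            raise AssertionError(
                f"{op.label}: adjoint deviates from transpose by {err:.3e} (rtol {rtol})"
            )
    return cols


def dot_product_test(op: LinearMap, n_trials: int = 100, seed: int = 0) -> float:
    """Max relative discrepancy of ⟨Ax, y⟩ vs ⟨x, Aᵀy⟩ over random probes.

    Standard-normal probes drawn from a seeded generator; deterministic
    given the seed.  A correct adjoint gives values at roundoff level
    (≲1e-12); an incorrect one gives O(1).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        x = rng.standard_normal(op.n_cols)
        y = rng.standard_normal(op.n_rows)
        ax = op.forward(x)
        aty = op.adjoint(y)
        num = abs(float(ax @ y) - float(x @ aty))
        den = np.linalg.norm(ax) * np.linalg.norm(y) + 1e-300
        worst = max(worst, num / den)
    return worst
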