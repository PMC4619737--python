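"""Non-negative regularized least-squares DC recovery.

The reconstruction solves

    minimize  ‖Aρ − b‖² + α‖ρ‖² + Σ_i β_i‖∇_iρ‖²   subject to  ρ ≥ 0

restated as ``min ‖Tρ − w‖², ρ ≥ 0`` with the stacked operator of
:func:`mpirecon.operators.stack_operators`.  The problem is convex; it is
solved by FISTA (accelerated proximal gradient) where the proximal step is
projection onto the non-negative orthant.  The step size comes from a
power-iteration estimate of the largest eigenvalue of TᵀT.

The Tikhonov term does double duty: it conditions the inverse and, because
the global image mean lies in the nullspace of A, it selects the feasible
reconstruction with the smallest total DC value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .operators import LinearMap, StackedSystem, materialize

__all__ = [
    "ReconConfig",
    "SolveReport",
    "objective_value",
    "project_nonnegative",
    "lipschitz_estimate",
    "fista_solve",
    "reference_solve",
]


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    alpha : Tikhonov weight (objective units); conditions the DC mode.
    beta : smoothness weight, scalar or one per image axis.
    max_iters : FISTA iteration budget (fixed-count stopping by default).
    rel_tol : optional relative objective-change stopping threshold;
        0 disables early stopping.
    power_iters : power-method iterations for the Lipschitz estimate.
    seed : seed for the power-method probe.
    monotone : if True, reject accelerated steps that increase the
        objective (monotone FISTA); plain FISTA may oscillate slightly.
    """

    alpha: float = 0.15
    beta: float | tuple[float, ...] = 0.04
    max_iters: int = 10
    rel_tol: float = 0.0
    power_iters: int = 50
    seed: int = 0
    monotone: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or np.any(np.asarray(self.beta) < 0):
            raise ValueError("regularization weights must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")


@dataclass
class SolveReport:
    iterates: list[float] = field(default_factory=list)
    final_objective: float = np.nan
    n_iters: int = 0
    step_size: float = np.nan
    converged: bool = False


def objective_value(rho, A: LinearMap, b, alpha, beta) -> float:
    """The regularized data-consistency objective at ``rho``.

    Equals ``‖Tρ − w‖²`` of the stacked form exactly (the stacked rows are
    scaled by the square roots of the weights).
    """
    from .operators import _beta_tuple, make_gradient

    rho = np.asarray(rho, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    r = A.forward(rho) - b
    val = float(r @ r) + float(alpha) * float(rho @ rho)
    if A.domain_shape is not None:
        betas = _beta_tuple(beta, len(A.domain_shape))
        for ax, bv in enumerate(betas):
            if bv > 0:
                g = make_gradient(ax, A.domain_shape).forward(rho)
                val += bv * float(g @ g)
    return val


def project_nonnegative(rho: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the non-negative orthant."""
    return np.maximum(np.asarray(rho, dtype=float), 0.0)


def lipschitz_estimate(T: LinearMap, power_iters: int = 50, seed: int = 0) -> float:
    """Estimate λ_max(TᵀT) = σ_max(T)² by seeded power iteration."""
    if power_iters < 10:
        raise ValueError("power_iters must be >= 10")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(T.n_cols)
    nv = np.linalg.norm(v)
    if nv == 0:
        v[0] = 1.0
        nv = 1.0
    v /= nv
    lam = 0.0
    for _ in range(power_iters):
        u = T.adjoint(T.forward(v))
        lam = float(v @ u)
        nu = np.linalg.norm(u)
        if nu <= 1e-300:
            return 1e-12  # zero operator: tiny positive floor
        v = u / nu
    return max(lam, 1e-12)


def _stacked_objective(T: LinearMap, w: np.ndarray, x: np.ndarray) -> float:
    r = T.forward(x) - w
    return float(r @ r)


def fista_solve(system: StackedSystem, config: ReconConfig) -> tuple[np.ndarray, SolveReport]:
    """FISTA with non-negativity projection, started from the zero image.

    The gradient of ‖Tρ − w‖² is 2 Tᵀ(Tρ − w); the step is 1/(1.05 L)
    with L the power-iteration Lipschitz estimate.  Stops at the iteration
    budget or when the relative objective change drops below ``rel_tol``.
    If the objective exceeds 10x its initial value the step is halved and
    the solve restarted (at most three times) before raising.
    """
    T, w = system.T, system.w
    L = lipschitz_estimate(T, config.power_iters, config.seed)
    step = 1.0 / (1.05 * 2.0 * L)  # gradient has Lipschitz constant 2 λ_max

    for _attempt in range(4):
        x = np.zeros(T.n_cols)
        y = x.copy()
        t = 1.0
        f0 = _stacked_objective(T, w, x)
        report = SolveReport(iterates=[], step_size=step)
        diverged = False
        f_prev = f0
        for it in range(config.max_iters):
            grad = 2.0 * T.adjoint(T.forward(y) - w)
            z = project_nonnegative(y - step * grad)
            f_z = _stacked_objective(T, w, z)
            if config.monotone and f_z > f_prev:
                x_new, f = x, f_prev  # keep the best iterate so far
            else:
                x_new, f = z, f_z
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            # momentum always extrapolates from the accepted prox point z
            y = z + ((t - 1.0) / t_new) * (z - x)
            x, t, f_prev = x_new, t_new, f
            report.iterates.append(f)
            if f > 10.0 * max(f0, 1e-300):
                diverged = True
                break
            if config.rel_tol > 0 and it > 0:
                prev = report.iterates[-2]
                if abs(prev - f) <= config.rel_tol * max(prev, 1e-300):
                    report.converged = True
                    break
        if not diverged:
            report.n_iters = len(report.iterates)
            report.final_objective = report.iterates[-1] if report.iterates else f0
            if config.rel_tol == 0:
                report.converged = report.n_iters >= config.max_iters
            return x, report
        step *= 0.5
    raise RuntimeError("fista_solve diverged repeatedly despite step halving")


def reference_solve(system: StackedSystem, config: ReconConfig | None = None,
                    method: str = "nnls", max_n: int = 200,
                    pgd_iters: int = 200_000) -> np.ndarray:
    """Dense small-problem solver for the same non-negative least squares.

    Materializes T and either calls an active-set NNLS solver
    (``method="nnls"``) or runs a long, conservatively stepped projected
    gradient descent (``method="pgd"``).  Intended as a cross-check on
    small instances only.
    """
    T = system.T
    if T.n_cols > max_n:
        raise ValueError(f"reference_solve limited to n <= {max_n}, got {T.n_cols}")
    Td = materialize(T, check_adjoint=False)
    w = system.w
    if method == "nnls":
        x, _ = scipy.optimize.nnls(Td, w)
        return x
    if method == "pgd":
        lam = np.linalg.norm(Td, 2) ** 2
        step = 1.0 / (2.0 * 1.5 * max(lam, 1e-12))
        x = np.zeros(T.n_cols)
        TtT = Td.T @ Td
        Ttw = Td.T @ w
        for _ in range(pgd_iters):
            x = np.maximum(x - step * 2.0 * (TtT @ x - Ttw), 0.0)
        return x
    raise ValueError(f"unknown method {method!r}")
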