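"""mpirecon: convex x-space reconstruction for magnetic particle imaging.

Recovers the per-pFOV DC component lost to direct-feedthrough filtering
by solving a non-negative, Tikhonov- and smoothness-regularized least
squares problem over the whole volume with matrix-free linear operators.
"""

from .geometry import ScanGeometry, vectorize, unvectorize
from .operators import (
    LinearMap,
    StackedSystem,
    make_segmentation,
    make_dc_removal,
    make_forward,
    make_gradient,
    stack_operators,
    materialize,
    dot_product_test,
)
from .solver import (
    ReconConfig,
    SolveReport,
    objective_value,
    project_nonnegative,
    lipschitz_estimate,
    fista_solve,
    reference_solve,
)
from .simulator import (
    PhantomSpec,
    PSFModel,
    NoiseModel,
    make_phantom,
    psf_kernel,
    native_image,
    simulate_partial_fovs,
)
from .conditioning import (
    SVDReport,
    coverage_profile,
    operator_svd,
    condition_number_reduced,
    plateau_value,
    overlap_sweep,
    default_fig_geometry,
)
from .baseline import (
    ReconReport,
    stitch_1d_dc,
    wiener_deconvolve,
    banding_index,
    compare_reconstructions,
)
from .signal_chain import (
    DriveTrajectory,
    RawSignal,
    synthesize_signal_1d,
    remove_fundamental,
    velocity_compensate,
    grid_to_partial_fovs,
    make_trajectory,
    process_chain,
)

__version__ = "0.1.0"


def reconstruct(stack, geometry, config=None):
    """Convenience wrapper: pFOV stack -> reconstructed image.

    Builds ``A = D S`` for the geometry, stacks the regularizers from the
    config, runs FISTA and returns ``(image, SolveReport)`` with the image
    in ``image_shape`` layout.
    """
    import numpy as np

    config = config or ReconConfig()
    A = make_forward(geometry)
    b = np.asarray(stack, dtype=float).reshape(-1)
    system = stack_operators(A, config.alpha, config.beta, b)
    rho, report = fista_solve(system, config)
    return unvectorize(rho, geometry), report
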