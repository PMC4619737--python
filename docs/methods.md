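# Methods

## The forward model

A partial FOV (pFOV) is the drive-axis window an FFR traversal covers.
Geometry is parameterized by the pFOV width `p` (pixels), the overlap `s`
between adjacent pFOVs, and the pFOV count `N`; the shift between
consecutive pFOV start pixels is `d = p − s` and the drive-axis image
extent is `d(N−1) + p`.  Only integer shifts are supported — a gridder is
expected to choose pixel grids that make the shift integral.  The
block-form definition of the segmentation operator found in the
literature presumes `s ≤ p/2`; we define **S** generically as sliding
windows at stride `d`, which reduces to the block form for small overlaps
and handles coverage greater than two (the reference analysis geometry
has 4-fold coverage, `s = 15` with `p = 20`).

Images are vectorized row-major with the drive axis fastest-varying.  DC
removal acts per drive-axis line per pFOV block (`R = I_p − (1/p)11ᵀ` on
each line), which matches the block-diagonal structure of the operator
and the physics: the feedthrough filter destroys the mean of each
received line, not of a whole 3D block.  `R` is an orthogonal projection,
so **D** is its own adjoint, and a constant image is annihilated by
`A = DS` exactly — the global mean is the nullspace of the acquisition.

All operators are matrix-free (forward/adjoint closures with shape
metadata).  Correctness is established two ways: the dot-product test
(`⟨Ax, y⟩ = ⟨x, Aᵀy⟩` on seeded Gaussian probes, threshold 1e−10
relative) and dense materialization by applying the operator to identity
columns (guarded at 5×10⁷ entries), which also verifies that the
materialized adjoint is the exact transpose.

## The optimization

The objective ‖Aρ − b‖² + α‖ρ‖² + Σᵢ βᵢ‖∇ᵢρ‖² with ρ ≥ 0 is solved as
stacked non-negative least squares.  The stacked rows are scaled by √α
and √βᵢ so the stacked residual norm equals the objective *exactly*; a
literal reading of the stacked form would square the weights, and we
resolve that ambiguity in favor of the declared objective, reporting α
and β in objective units.

- **Gradients** are forward differences with a replicate (Neumann)
  boundary, so constants map to zero exactly and the adjoint is a simple
  negative divergence.  Blocks with zero weight are dropped, so
  α = β = 0 reduces the stacked operator to **A** itself.
- **Step size**: 1/(1.05·L̂) where L̂ is the gradient Lipschitz estimate
  2·λ̂max(TᵀT) from 50 seeded power iterations.  If the objective ever
  exceeds 10× its initial value the step is halved and the solve
  restarted (at most three times).
- **Initialization** is the zero image; stopping is by fixed iteration
  count (the scanner-style configurations use 10–30 iterations) or an
  optional relative objective-change tolerance.
- Plain FISTA is slightly non-monotone; a `monotone` flag enables
  monotone FISTA (reject steps that increase the objective) for
  diagnostics that assert descent.
- **Oracles**: `reference_solve` materializes T and solves the same
  problem with a dense active-set NNLS solver (or, optionally, a long
  conservatively-stepped projected gradient descent).  FISTA matches
  these to ≤1e−6 relative objective gap on small instances; an
  unconstrained analytic check against the normal equations covers the
  interior case.

### Choosing α and β

The Tikhonov weight does two jobs: it conditions the inverse and selects
the minimum-DC solution out of the nullspace.  It also *biases*: the
minimizer shrinks low-singular-value smooth modes by roughly
α/(α + σ²), independently of image scale.  Consequently:

- For **noiseless** recovery experiments the package uses small weights
  (α = β = 1e−3 for the 2D study geometry, 1e−4 for weakly-overlapped
  small geometries), which recover edge-zero phantoms to ≤1% relative
  RMSE.  Large weights would leave a purely bias-driven error of order
  10% no matter how many iterations run.
- For **noisy** data the scanner-style weights (α = 0.15, β = 0.04,
  10–30 iterations) are appropriate: the bias buys noise suppression,
  and the early-stopped iteration count acts as additional
  regularization.

The global image mean is unrecoverable in principle; with at least one
tracer-free pixel per line (standard scan prescription: keep one FOV
edge clear) the non-negativity constraint plus minimum-DC selection pins
it correctly.  For strictly positive phantoms the reconstruction is
correct up to a constant, and the recovered image touches zero.

## The simulator

The simulator is the package's fixture generator and defines the study
conditions: a non-negative density (point/points/helix/vessel-tree/blob
phantoms; the helix mirrors a two-tube 0.6 mm ID phantom wound on a
2.7 cm cylinder, rasterized by distance-to-curve thresholding), convolved
with a strictly positive even unit-sum PSF (Gaussian by default,
parameterized by FWHM; a Langevin-derivative line shape dL/du,
L(u) = coth u − 1/u, is provided as the saturating-tracer alternative —
the idealized theory fixes only positivity and smoothness, not a
closed form), then windowed into pFOVs with per-line mean removal and
optional additive white Gaussian noise (applied before the DC filter, as
in hardware; no noise model is inherited from theory, white Gaussian is
the package's choice).  The default 2D study condition is a 32×105 image,
pFOV width 20, overlap 15, 18 pFOVs, blob phantoms with tracer-free
drive-axis edges, and 5% of-peak noise where noise is called for.

What the simulator does **not** emulate: magnetization dynamics and
relaxation, coil sensitivity, focus-field inhomogeneity, hardware filter
phase distortion, or structured/correlated noise.  Passing round-trip
tests therefore demonstrates correctness of the linear DC-loss model and
the solver — not robustness to those hardware effects.

## The 1D signal chain

The chain synthesizes a received voltage `ρ_native(x(t))·ẋ(t)` plus a
feedthrough tone at the drive fundamental, filters it, velocity
compensates, and grids per traversal.  Numerical choices:

- **Trajectory**: the default steps the shift field once per full drive
  period (station scanning), so both sweeps of a period retrace the same
  pFOV window.  The signal is then periodic per station and the filtered
  band carries exactly the pFOV DC plus feedthrough — the property that
  makes DC-loss equivalence hold.  A continuously ramping shift is also
  supported; its backward sweeps undercover their windows, and the
  affected pixels are flagged and filled by within-line interpolation.
- **Harmonic filter**: the DC-to-1.5f₀ band and everything above
  harmonic `n + ½` are zeroed in the Fourier domain, one drive period at
  a time so every harmonic sits on an exact FFT bin (no leakage of the
  strong feedthrough tone).  The default passband is 15 harmonics.
- **Velocity compensation** divides by the instantaneous FFR speed and
  masks samples below 5% of peak speed (the turnarounds).
- **Gridding** bins valid samples to the nearest pixel with bin
  averaging; empty pixels are flagged and interpolated within the line;
  per-line means are removed afterward.  Hardware phase correction is a
  no-op on synthetic signals (no distortion is simulated).

End-to-end, the chain reproduces the operator-model simulation to ≤3%
relative RMSE on smooth images.

## Conditioning analysis

For 1D geometries the dense **A** is small enough for a full SVD.  The
spectrum has exactly one zero singular value (global DC); the "reduced"
condition number discards singular values below 1e−10·σmax.  Pixel
regions acquired by `c` overlapping pFOVs produce singular-value
plateaus at √c (for **S** alone this is exact: SᵀS is the diagonal
coverage-count matrix).  Plateau extraction selects singular vectors
with ≥75% of their energy on the exact-coverage region and reports the
median singular value.

The reference analysis geometry is `p = 20`, `s = 15`, `N = 18`
(n = 105): N = 18 is the unique pFOV count in 12–24 whose 4-fold plateau
holds exactly 64 singular values, and its reduced condition number is
6.05, which rounds to 6.  The condition number is
*not* N-stable (it grows roughly linearly from 4.4 at N = 12 to 7.7 at
N = 24, because the smallest retained mode is a long-wavelength one
whose singular value falls with FOV length), which is why the plateau
extent, not stability, identifies the geometry.

The overlap sweep holds the FOV length approximately fixed (choosing N
per overlap) rather than holding N fixed: comparing pulse sequences over
one FOV is the meaningful comparison, and it shows the documented trend
— conditioning improves with overlap and is nearly flat (max/min ≤ 2)
for overlaps of at least half the pFOV width.

## Baseline and metrics

The stitching baseline reimplements the sequential 1D continuity idea
from its description: per drive-axis line, each pFOV is offset to match
the running estimate's mean over the overlap, overlaps are uniformly
averaged, and the line is anchored to zero at the FOV edge.  It is
labeled a baseline, not an archival port — the historical blending
details are not recorded.  On noiseless data it is exact; under noise
its per-line independence produces banding, quantified as the standard
deviation of per-line mean errors along the drive axis
(`banding_index`).  Reported metrics are RMSE, DC-invariant RMSE
(minimum over a constant offset), and the banding index.

Wiener deconvolution uses `H*/(|H|² + nsr)` with the kernel embedded
centered; `nsr` defaults to a corner-patch noise/signal power estimate.
It assumes circular boundaries, so near-inverse settings (nsr ≲ 1e−4)
amplify boundary mismatch; matched settings never increase RMSE on
blurred-only inputs.

## Known limitations

- Only integer pFOV shifts; no field-free-line projection geometries or
  multi-channel receive.
- The 2D/3D solver analysis is validated on synthetic data only; the
  banding advantage over line-wise stitching holds on average across
  phantoms (and in ≥8/10 noise seeds for the study phantom) but bias
  from large α can erode it for phantoms with little edge clearance.
- SVD diagnostics require materializable (1D-scale) operators.
- Problem sizes in the shipped tests (n ≈ 10²–10³, 2D 32×105) are chosen
  so the full suite exercises every claim with dense oracles; the
  matrix-free solver itself scales to volumes.
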