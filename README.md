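# mpirecon

Convex x-space reconstruction for Magnetic Particle Imaging (MPI).

MPI images the density of magnetic nanoparticles by sweeping a field-free
region (FFR) across the field of view with a sinusoidal drive field.  The
drive field leaks directly into the receive coil, and the hardware filter
that removes this feedthrough also destroys the zero-frequency (DC)
component of every partial field of view (pFOV) — the stretch of image
covered by one drive traversal.  Reconstruction must therefore recover the
lost per-pFOV means so that the overlapping pFOVs assemble into one
consistent image.  Line-by-line continuity stitching can do this but
propagates noise independently per line, producing banding.  `mpirecon`
instead solves the recovery jointly over the whole volume as a convex
program.

## The model

The acquisition is linear: a segmentation operator **S** cuts the image
ρ into overlapping pFOV blocks (shift `d = p − s` for pFOV width `p` and
overlap `s`), and a DC-removal operator **D** (block-diagonal in
`R = I_p − (1/p)·11ᵀ`) subtracts the mean of every drive-axis line.  With
`A = DS` and measured pFOV data `b`, the reconstruction solves

    minimize_ρ  ‖Aρ − b‖² + α‖ρ‖² + Σᵢ βᵢ‖∇ᵢρ‖²    subject to  ρ ≥ 0

The smoothness (βᵢ) and non-negativity terms encode physics — the native
MPI image is a density convolved with a strictly positive, smooth PSF —
and the Tikhonov term (α) regularizes the one null direction of **A**
(the global image mean), selecting the feasible image with the smallest
total DC.  The problem is restated as non-negative least squares
`min ‖Tρ − w‖²`, `T = [A; √α I; √βᵢ ∇ᵢ]`, `w = [b; 0; 0]`, and solved by
FISTA with projection onto the non-negative orthant.  All operators are
matrix-free (forward/adjoint function pairs, validated by the dot-product
test and by dense materialization on small problems).

The package also provides a synthetic scan simulator (phantoms, PSF
models, pFOV formation with DC loss and noise), an idealized 1D x-space
signal chain (harmonic filtering, velocity compensation, gridding), SVD
conditioning diagnostics of **A**, the prior-art 1D stitching baseline,
and Wiener deconvolution post-processing — everything needed to exercise
the reconstruction without scanner data.

## Worked example

Simulate a noisy 2D scan (32×105 pixels, pFOV width 20, overlap 15,
18 pFOVs, 5% Gaussian noise), reconstruct with scanner-style weights,
and compare against line-wise stitching:

```
$ mpirecon simulate --config scan.yaml --outdir run --seed 3
$ mpirecon reconstruct --stack run/pfov.h5 --config recon.yaml \
      --out run/recon.nii.gz --report-prefix run/solve
reconstructed with alpha=0.15 beta=0.04 iters=30; final objective 115.322
$ mpirecon stitch-baseline --stack run/pfov.h5 --out run/baseline.nii.gz
$ mpirecon compare --truth run/native.nii.gz --estimate run/recon.nii.gz \
      --estimate run/baseline.nii.gz --drive-axis 1 --out run/metrics.csv
$ cat run/metrics.csv
label,rmse,rmse_up_to_dc,banding_index
recon.nii,0.085887244,0.082774804,0.031097129
baseline.nii,0.12645488,0.12597489,0.10944653
```

The joint reconstruction has both lower error and a ~3.5× lower banding
index (the spread of per-line mean errors along the drive axis) than the
line-independent baseline, which cannot share DC information across
lines.

The conditioning diagnostics reproduce the operator analysis:

```
$ mpirecon svd-report --outdir run/svd
n=105: condition number (DC removed) 6.053; reports in run/svd
```

`summary.json` reports one zero singular value (the global-DC nullspace),
a condition number of ~6 once that mode is dropped, and a singular-value
plateau at 2 = √4 for the interior pixels covered by four pFOVs — the
signal-averaging gain of the overlap.

## Layout

- `mpirecon.geometry` — scan geometry and vectorization conventions
- `mpirecon.operators` — matrix-free S, D, A, gradients, stacking, checks
- `mpirecon.solver` — FISTA non-negative least squares + dense oracles
- `mpirecon.simulator` — phantoms, PSFs, native images, pFOV simulation
- `mpirecon.signal_chain` — 1D raw-signal synthesis and x-space processing
- `mpirecon.conditioning` — SVD reports, condition numbers, overlap sweeps
- `mpirecon.baseline` — 1D stitching baseline, Wiener deconvolution, metrics
- `mpirecon.io` / `mpirecon.cli` — HDF5/NIfTI/TIFF/CSV formats and commands

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and numerical choices.
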