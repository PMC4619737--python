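#!/usr/bin/env python
"""Regenerate the three canned demonstration cases under fixtures/.

Cases: a 1D line (n=105), a 2D slice (32x64), and a 3D block (24x24x48),
each with phantom, native image, and noiseless + noisy pFOV stacks.  The
files are derived artifacts (HDF5/NIfTI) and are rebuilt from code rather
than versioned.

Usage:  python scripts/make_fixtures.py [--outdir fixtures] [--seed 0]
"""

import argparse
from pathlib import Path

from mpirecon import (
    NoiseModel,
    PhantomSpec,
    PSFModel,
    ScanGeometry,
    make_phantom,
    native_image,
    simulate_partial_fovs,
)
from mpirecon.io import save_image, save_pfov_stack

CASES = {
    "line_1d": dict(
        geometry=ScanGeometry((105,), 20, 15, 18),
        phantom=dict(kind="random_blobs", shape=(105,)),
        psf=dict(fwhm=4.0),
    ),
    "slice_2d": dict(
        geometry=ScanGeometry((32, 64), 14, 4, 6, drive_axis=1),
        phantom=dict(kind="random_blobs", shape=(32, 64)),
        psf=dict(fwhm=3.0, support_radius=5),
    ),
    "block_3d": dict(
        geometry=ScanGeometry((24, 24, 48), 12, 3, 5, drive_axis=2),
        phantom=dict(kind="vessel_tree", shape=(24, 24, 48)),
        psf=dict(fwhm=2.5, support_radius=4),
    ),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="fixtures")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    for name, case in CASES.items():
        out = Path(args.outdir) / name
        out.mkdir(parents=True, exist_ok=True)
        geom = case["geometry"]
        phantom = make_phantom(PhantomSpec(seed=args.seed, **case["phantom"]))
        native = native_image(phantom, PSFModel(**case["psf"]))
        save_image(out / "phantom.nii.gz", phantom)
        save_image(out / "native.nii.gz", native)
        clean = simulate_partial_fovs(native, geom, dc_mode="remove")
        save_pfov_stack(out / "pfov.h5", clean, geom)
        noisy = simulate_partial_fovs(
            native, geom, NoiseModel(sigma=0.05 * native.max(), seed=args.seed),
            dc_mode="remove")
        save_pfov_stack(out / "pfov_noisy.h5", noisy, geom)
        print(f"{name}: wrote 4 files to {out}")


if __name__ == "__main__":
    main()
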