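import numpy as np
import pytest

from mpirecon import (
    DriveTrajectory,
    PhantomSpec,
    PSFModel,
    RawSignal,
    ScanGeometry,
    grid_to_partial_fovs,
    make_phantom,
    make_trajectory,
    native_image,
    process_chain,
    remove_fundamental,
    simulate_partial_fovs,
    synthesize_signal_1d,
    velocity_compensate,
)


@pytest.fixture(scope="module")
def chain_geometry():
    return ScanGeometry((34,), 12, 10, 12)


@pytest.fixture(scope="module")
def chain_native(chain_geometry):
    phantom = make_phantom(PhantomSpec(kind="random_blobs", shape=(34,), seed=7))
    return native_image(phantom, PSFModel(fwhm=4.0))


@pytest.fixture(scope="module")
def chain_trajectory(chain_geometry):
    return make_trajectory(chain_geometry, samples_per_traversal=300)


class TestSynthesize:
    def test_uniform_image_yields_velocity(self, chain_geometry, chain_trajectory):
        native = np.ones(chain_geometry.n_pixels)
        raw = synthesize_signal_1d(native, chain_trajectory)
        np.testing.assert_allclose(raw.samples, raw.velocities, atol=1e-12)

    def test_empty_image_yields_pure_feedthrough(self, chain_trajectory):
        native = np.zeros(34)
        raw = synthesize_signal_1d(native, chain_trajectory, feedthrough_amp=2.0)
        t = chain_trajectory.times()
        expected = 2.0 * np.cos(2 * np.pi * chain_trajectory.drive_frequency * t)
        np.testing.assert_allclose(raw.samples, expected, atol=1e-12)

    def test_trajectory_leaving_image_rejected(self, chain_trajectory):
        with pytest.raises(ValueError):
            synthesize_signal_1d(np.ones(20), chain_trajectory)

    def test_sample_rate_validation(self):
        with pytest.raises(ValueError):
            DriveTrajectory(drive_frequency=100.0, drive_amplitude=5.0,
                            shift_rate=1.0, sample_rate=500.0, duration=1.0)


class TestHarmonicFilter:
    def test_fundamental_tone_suppressed(self, chain_trajectory):
        t = chain_trajectory.times()
        tone = np.cos(2 * np.pi * chain_trajectory.drive_frequency * t)
        raw = RawSignal(tone, chain_trajectory.positions(t),
                        chain_trajectory.velocities(t), chain_trajectory)
        out = remove_fundamental(raw, 15)
        suppression_db = 10 * np.log10(
            np.sum(out.samples**2) / np.sum(tone**2) + 1e-300)
        assert suppression_db < -60

    def test_passband_unchanged(self, chain_trajectory):
        t = chain_trajectory.times()
        f0 = chain_trajectory.drive_frequency
        sig = sum(np.sin(2 * np.pi * k * f0 * t + 0.1 * k) for k in range(2, 6))
        raw = RawSignal(sig, chain_trajectory.positions(t),
                        chain_trajectory.velocities(t), chain_trajectory)
        out = remove_fundamental(raw, 15)
        np.testing.assert_allclose(out.samples, sig, atol=1e-10)

    def test_band_above_nyquist_rejected(self, chain_trajectory):
        t = chain_trajectory.times()
        raw = RawSignal(np.zeros(t.size), chain_trajectory.positions(t),
                        chain_trajectory.velocities(t), chain_trajectory)
        with pytest.raises(ValueError):
            remove_fundamental(raw, 10_000)


class TestVelocityCompensation:
    def test_velocity_signal_compensates_to_one(self, chain_geometry,
                                                chain_trajectory):
        raw = synthesize_signal_1d(np.ones(chain_geometry.n_pixels),
                                   chain_trajectory)
        values, mask = velocity_compensate(raw)
        np.testing.assert_allclose(values[mask], 1.0, atol=1e-12)

    def test_turnarounds_masked(self, chain_trajectory):
        t = chain_trajectory.times()
        raw = RawSignal(np.zeros(t.size), chain_trajectory.positions(t),
                        chain_trajectory.velocities(t), chain_trajectory)
        _, mask = velocity_compensate(raw, velocity_floor=0.05)
        vmax = np.abs(raw.velocities).max()
        assert not mask[np.abs(raw.velocities) < 0.05 * vmax].any()
        assert mask[np.abs(raw.velocities) >= 0.05 * vmax].all()

    def test_compensated_samples_trace_native_profile(self, chain_geometry,
                                                      chain_native,
                                                      chain_trajectory):
        raw = synthesize_signal_1d(chain_native, chain_trajectory)
        values, mask = velocity_compensate(raw)
        expected = np.interp(raw.positions[mask],
                             np.arange(chain_native.size), chain_native)
        rel = (np.linalg.norm(values[mask] - expected)
               / np.linalg.norm(expected))
        assert rel <= 0.02


class TestGridding:
    def test_ramp_grids_to_demeaned_ramp(self):
        geom = ScanGeometry((6,), 6, 0, 1)
        positions = np.tile(np.arange(6.0), 100)
        values = positions.copy()  # linear ramp sampled uniformly
        mask = np.ones(positions.size, dtype=bool)
        stack = grid_to_partial_fovs(values, mask, positions, geom)
        line = stack.reshape(-1)
        expected = np.arange(6.0) - 2.5
        np.testing.assert_allclose(line, expected, atol=1e-12)

    def test_duplicates_averaged_not_summed(self):
        geom = ScanGeometry((3,), 3, 0, 1)
        positions = np.array([0.0, 1.0, 1.0, 1.0, 2.0])
        values = np.array([1.0, 2.0, 4.0, 6.0, 5.0])
        mask = np.ones(5, dtype=bool)
        stack = grid_to_partial_fovs(values, mask, positions, geom)
        line = stack.reshape(-1)
        expected = np.array([1.0, 4.0, 5.0])
        np.testing.assert_allclose(line, expected - expected.mean(), atol=1e-12)

    def test_empty_pfov_rejected(self):
        geom = ScanGeometry((8,), 4, 0, 2)
        positions = np.array([0.0, 1.0, 2.0, 3.0])  # never reaches pFOV 1
        values = np.zeros(4)
        mask = np.ones(4, dtype=bool)
        with pytest.raises(ValueError):
            grid_to_partial_fovs(values, mask, positions, geom)

    def test_averaging_reduces_noise_sqrt_k(self):
        geom = ScanGeometry((64,), 64, 0, 1)
        rng = np.random.default_rng(9)
        stds = []
        for k in (4, 64):
            n = 64 * k
            positions = np.repeat(np.arange(64.0), k)
            values = rng.standard_normal(n)
            mask = np.ones(n, dtype=bool)
            # many independent realizations to measure the gridded std
            reps = []
            for _ in range(300):
                vals = rng.standard_normal(n)
                st = grid_to_partial_fovs(vals, mask, positions, geom)
                reps.append(st.reshape(-1))
            stds.append(np.std(np.concatenate(reps)))
        ratio = stds[0] / stds[1]
        assert ratio == pytest.approx(np.sqrt(64 / 4), rel=0.10)

    def test_output_smaller_than_input(self, chain_geometry, chain_native,
                                       chain_trajectory):
        stack = process_chain(chain_native, chain_trajectory, chain_geometry)
        n_samples = chain_trajectory.times().size
        assert stack.size <= n_samples


class TestEndToEnd:
    def test_chain_matches_operator_simulation(self, chain_geometry,
                                               chain_native, chain_trajectory):
        stack = process_chain(chain_native, chain_trajectory, chain_geometry,
                              feedthrough_amp=5.0, n_harmonics=15)
        ref = simulate_partial_fovs(chain_native, chain_geometry,
                                    dc_mode="remove")
        rel = np.linalg.norm(stack - ref) / np.linalg.norm(ref)
        assert rel <= 0.03

    def test_point_source_peak_within_one_pixel(self, chain_geometry,
                                                chain_trajectory):
        from mpirecon import stitch_1d_dc

        density = np.zeros(chain_geometry.n_pixels)
        density[17] = 1.0
        native = native_image(density, PSFModel(fwhm=3.0))
        stack = process_chain(native, chain_trajectory, chain_geometry,
                              feedthrough_amp=2.0, n_harmonics=15)
        image = stitch_1d_dc(stack, chain_geometry)
        assert abs(int(np.argmax(image)) - 17) <= 1
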