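import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpirecon import (
    LinearMap,
    ScanGeometry,
    dot_product_test,
    make_dc_removal,
    make_forward,
    make_gradient,
    make_segmentation,
    materialize,
    stack_operators,
)
from mpirecon.solver import objective_value


def geometries_1d(max_p=30, max_n_pfov=20):
    """Hypothesis strategy over valid 1D scan geometries."""
    return st.tuples(
        st.integers(1, max_p),              # p
        st.integers(1, max_p),              # d (clamped to <= p)
        st.integers(1, max_n_pfov),         # N
    ).map(lambda t: _build_geom(t[0], min(t[1], t[0]), t[2]))


def _build_geom(p, d, N):
    n = d * (N - 1) + p
    return ScanGeometry((n,), p, p - d, N)


def coverage_oracle(geom):
    """Brute-force per-pixel window counts."""
    cov = np.zeros(geom.drive_extent, dtype=int)
    for k in range(geom.n_pfov):
        cov[k * geom.shift : k * geom.shift + geom.pfov_width] += 1
    return cov


class TestSegmentation:
    def test_windowing_1d(self, tiny_geometry):
        S = make_segmentation(tiny_geometry)
        out = S.forward(np.array([1.0, 2, 3, 4, 5]))
        np.testing.assert_array_equal(out, [1, 2, 3, 2, 3, 4, 3, 4, 5])

    def test_single_pfov_is_identity(self):
        g = ScanGeometry((6,), 6, 0, 1)
        S = make_segmentation(g)
        np.testing.assert_array_equal(materialize(S), np.eye(6))

    def test_sts_diagonal_equals_coverage(self):
        g = ScanGeometry((95,), 20, 15, 16)
        Sd = materialize(make_segmentation(g))
        StS = Sd.T @ Sd
        cov = coverage_oracle(g)
        assert cov.max() == 4
        np.testing.assert_allclose(np.diag(StS), cov, atol=1e-12)
        np.testing.assert_allclose(StS, np.diag(np.diag(StS)), atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(geometries_1d())
    def test_singular_values_are_sqrt_coverage(self, geom):
        Sd = materialize(make_segmentation(geom), check_adjoint=False)
        sv = np.linalg.svd(Sd, compute_uv=False)
        expected = np.sqrt(np.sort(coverage_oracle(geom))[::-1])
        np.testing.assert_allclose(np.sort(sv), np.sort(expected), atol=1e-10)

    def test_transverse_lines_segment_independently(self):
        g = ScanGeometry((2, 5), 3, 2, 3, drive_axis=1)
        img = np.array([[1.0, 2, 3, 4, 5], [10.0, 20, 30, 40, 50]])
        from mpirecon import vectorize

        out = make_segmentation(g).forward(vectorize(img, g))
        blocks = out.reshape(3, 2, 3)
        np.testing.assert_array_equal(blocks[1], [[2, 3, 4], [20, 30, 40]])


class TestDCRemoval:
    def test_mean_subtraction(self):
        g = ScanGeometry((2,), 2, 1, 1)
        D = make_dc_removal(g)
        np.testing.assert_allclose(D.forward([3.0, 5.0]), [-1.0, 1.0])

    def test_constant_line_in_nullspace(self, fig_geometry):
        D = make_dc_removal(fig_geometry)
        out = D.forward(np.full(D.n_cols, 7.3))
        assert np.abs(out).max() < 1e-14

    def test_matches_fft_zero_frequency_oracle(self):
        g = ScanGeometry((8,), 8, 0, 1)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8)
        spec = np.fft.fft(x)
        spec[0] = 0.0
        expected = np.real(np.fft.ifft(spec))
        np.testing.assert_allclose(make_dc_removal(g).forward(x), expected,
                                   atol=1e-12)

    def test_symmetric_idempotent(self, tiny_geometry):
        Dd = materialize(make_dc_removal(tiny_geometry))
        np.testing.assert_allclose(Dd, Dd.T, atol=1e-15)
        np.testing.assert_allclose(Dd @ Dd, Dd, atol=1e-12)

    def test_dense_r_p2(self):
        g = ScanGeometry((2,), 2, 1, 1)
        np.testing.assert_allclose(materialize(make_dc_removal(g)),
                                   [[0.5, -0.5], [-0.5, 0.5]])


class TestForwardModel:
    def test_constant_image_maps_to_zero(self):
        for geom in (ScanGeometry((5,), 3, 2, 3), ScanGeometry((95,), 20, 15, 16),
                     ScanGeometry((4, 11), 5, 2, 3, drive_axis=1)):
            A = make_forward(geom)
            assert np.abs(A.forward(np.ones(A.n_cols))).max() < 1e-14

    def test_shape_1d(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        assert A.shape == (9, 5)

    def test_matches_dense_composition_oracle(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        Dd = materialize(make_dc_removal(tiny_geometry))
        Sd = materialize(make_segmentation(tiny_geometry))
        dense = Dd @ Sd
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal(5)
            np.testing.assert_allclose(A.forward(x), dense @ x, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(geometries_1d(max_p=15, max_n_pfov=8))
    def test_function_form_agrees_with_dense(self, geom):
        A = make_forward(geom)
        Ad = materialize(A)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(A.n_cols)
        y = rng.standard_normal(A.n_rows)
        np.testing.assert_allclose(A.forward(x), Ad @ x, atol=1e-12 * max(1, abs(x).max()))
        np.testing.assert_allclose(A.adjoint(y), Ad.T @ y, atol=1e-12 * max(1, abs(y).max()))


class TestGradient:
    def test_constant_maps_to_zero(self):
        G = make_gradient(0, (7,))
        assert np.abs(G.forward(np.full(7, 4.2))).max() == 0.0

    def test_ramp_forward_difference(self):
        G = make_gradient(0, (4,))
        np.testing.assert_array_equal(G.forward([0.0, 1, 2, 3]), [1, 1, 1, 0])

    def test_axis_out_of_range(self):
        with pytest.raises(ValueError):
            make_gradient(2, (4, 4))

    @pytest.mark.parametrize("shape,axis", [((9,), 0), ((4, 6), 0), ((4, 6), 1),
                                            ((3, 4, 5), 2)])
    def test_adjoint_dot_product(self, shape, axis):
        G = make_gradient(axis, shape)
        assert dot_product_test(G, n_trials=50, seed=0) < 1e-12


class TestStackedSystem:
    def test_zero_weights_reduce_to_forward(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        b = np.arange(9.0)
        sys_ = stack_operators(A, 0.0, 0.0, b)
        assert sys_.T.shape == A.shape
        np.testing.assert_array_equal(sys_.w, b)

    def test_w_structure(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        b = np.arange(1.0, 10.0)
        sys_ = stack_operators(A, 0.1, 0.2, b)
        np.testing.assert_array_equal(sys_.w[:9], b)
        assert np.all(sys_.w[9:] == 0.0)

    def test_stacked_norm_equals_objective(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        rng = np.random.default_rng(4)
        rho = rng.standard_normal(5)
        b = rng.standard_normal(9)
        sys_ = stack_operators(A, 0.15, 0.04, b)
        r = sys_.T.forward(rho) - sys_.w
        stacked = float(r @ r)
        direct = objective_value(rho, A, b, 0.15, 0.04)
        assert abs(stacked - direct) <= 1e-12 * max(direct, 1.0)

    def test_negative_weights_rejected(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        b = np.zeros(9)
        with pytest.raises(ValueError):
            stack_operators(A, -0.1, 0.0, b)
        with pytest.raises(ValueError):
            stack_operators(A, 0.0, -0.1, b)


class TestMaterializeAndDotProduct:
    def test_identity(self):
        from mpirecon.operators import identity_map

        np.testing.assert_array_equal(materialize(identity_map(4)), np.eye(4))

    def test_size_guard(self):
        from mpirecon.operators import identity_map

        with pytest.raises(ValueError):
            materialize(identity_map(10), max_entries=50)

    def test_forward_row_sums_zero_for_constants(self, fig_geometry):
        A = make_forward(fig_geometry)
        Ad = materialize(A)
        np.testing.assert_allclose(Ad @ np.ones(A.n_cols), 0.0, atol=1e-12)

    def test_all_shipped_operators_pass_dot_product(self, fig_geometry):
        A = make_forward(fig_geometry)
        sys_ = stack_operators(A, 0.15, 0.04, np.zeros(A.n_rows))
        ops = [
            make_segmentation(fig_geometry),
            make_dc_removal(fig_geometry),
            A,
            make_gradient(0, fig_geometry.working_shape),
            sys_.T,
        ]
        for op in ops:
            assert dot_product_test(op, n_trials=100, seed=0) < 1e-10, op.label

    def test_self_adjoint_projection_at_roundoff(self, fig_geometry):
        D = make_dc_removal(fig_geometry)
        assert dot_product_test(D, n_trials=100, seed=1) < 1e-12

    def test_corrupted_adjoint_detected(self, tiny_geometry):
        S = make_segmentation(tiny_geometry)

        def bad_adjoint(y):
            # overwrite instead of accumulate: drops overlap contributions
            blocks = y.reshape(3, 1, 3)
            out = np.zeros(5)
            for k in range(3):
                out[k : k + 3] = blocks[k, 0]
            return out

        bad = LinearMap(S.n_rows, S.n_cols, S.forward, bad_adjoint, label="S-bad")
        assert dot_product_test(bad, n_trials=50, seed=0) > 1e-6
        with pytest.raises(AssertionError):
            materialize(bad)

    def test_deterministic_given_seed(self, tiny_geometry):
        A = make_forward(tiny_geometry)
        assert dot_product_test(A, 10, seed=7) == dot_product_test(A, 10, seed=7)
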