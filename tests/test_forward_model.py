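"""Polychromatic data model, linearization H, and nonlinearity residual."""
import numpy as np
import pytest

import polybasis as pb
from polybasis.forward_model import PolyForwardModel


def _dense_H(model, w):
    H = np.zeros((model.J, model.N_b))
    for c in range(model.N_b):
        e = np.zeros(model.N_b)
        e[c] = 1.0
        H[:, c] = model.H_apply(e, w)
    return H


def _dense_H_elementwise(model, bbar):
    """Explicit element-by-element materialization of the Jacobian:
    h_{j,(l,k,i')} = w_jk(bbar) * sum_i a_ji r'_{l,i,i'}."""
    A = model.system.matrix.toarray()
    part = model.partition
    t = model.path_lengths(bbar)
    s = model._line_integrals(t)
    N = model.spectrum.q * np.exp(-(s - s.min(axis=1, keepdims=True)))
    w = (N @ model.mus.mu.T) / N.sum(axis=1, keepdims=True)
    H = np.zeros((model.J, model.N_b))
    for l, k, sl in part.blocks():
        cols = part.region_pixels[l]
        H[:, sl] = w[:, [k]] * A[:, cols]
    return H


class TestPolyProject:
    def test_scalar_monochromatic_value(self, tiny_op, tiny_partition):
        # q=(1), mu = 0.2 cm^2/g, t = 5 g/cm^2  ->  g = 1 exactly
        grid = pb.EnergyGrid([60.0])
        mat = pb.Material("toy", 1.0, np.array([10.0, 150.0]), np.array([0.2, 0.2]))
        mus = pb.MaterialSet((mat,), grid)
        labels = np.ones((8, 8), dtype=np.int32)
        part = pb.validate_partition(labels, [(0,)], [], K=1)
        spec = pb.normalize_spectrum([1.0], grid)
        model = PolyForwardModel(tiny_op, part, spec, mus)
        t = np.full((model.J, 1), 5.0)
        np.testing.assert_allclose(model.g_from_t(t), 1.0, rtol=1e-14)

    def test_scalar_two_bin_oracle(self, tiny_op):
        # independent scalar evaluation: -ln(0.5 e^-2 + 0.5 e^-1)
        grid = pb.EnergyGrid([40.0, 80.0])
        mat = pb.Material("toy", 1.0, np.array([10.0, 40.0, 80.0, 150.0]),
                          np.array([0.2, 0.2, 0.1, 0.1]))
        mus = pb.MaterialSet((mat,), grid)
        part = pb.validate_partition(np.ones((8, 8), np.int32), [(0,)], [], K=1)
        spec = pb.normalize_spectrum([1.0, 1.0], grid)
        model = PolyForwardModel(tiny_op, part, spec, mus)
        t = np.full((model.J, 1), 10.0)
        expected = -np.log(0.5 * np.exp(-2.0) + 0.5 * np.exp(-1.0))
        np.testing.assert_allclose(model.g_from_t(t), expected, rtol=1e-14)
        assert expected == pytest.approx(1.3799, abs=1e-4)

    def test_zero_bprime_gives_zero_data(self, tiny_model):
        g = tiny_model.project(np.zeros(tiny_model.N_b))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_nonnegative_for_nonnegative_bprime(self, tiny_model):
        rng = np.random.default_rng(0)
        g = tiny_model.project(rng.uniform(0, 0.5, tiny_model.N_b))
        assert np.all(g >= -1e-12)

    def test_underflow_guard_long_metal_paths(self, tiny_op, tiny_partition):
        grid = pb.EnergyGrid([40.0, 80.0])
        mats = tuple(
            pb.load_fixture_material(n)
            for n in ("water", "steel", "titanium")
        )
        mus = pb.MaterialSet(mats, grid)
        spec = pb.normalize_spectrum([1.0, 1.0], grid)
        model = PolyForwardModel(tiny_op, tiny_partition, spec, mus)
        t = np.full((model.J, 3), 500.0)  # would underflow exp(-mu*t) naively
        g = model.g_from_t(t)
        assert np.all(np.isfinite(g))

    def test_equals_full_array_model(self, tiny_model):
        """g'(b') = g(b): the basis-region model equals the full-array model
        on assembled images, for random b'."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            b = rng.uniform(0, 1, tiny_model.N_b)
            imgs = pb.assemble_basis_images(b, tiny_model.partition)
            t = np.stack(
                [tiny_model.system.project(imgs[k]) for k in range(tiny_model.K)],
                axis=1,
            )
            s = t @ tiny_model.mus.mu
            g_full = -np.log(np.sum(tiny_model.spectrum.q * np.exp(-s), axis=1))
            g_region = tiny_model.project(b)
            np.testing.assert_allclose(g_region, g_full, rtol=1e-12, atol=1e-14)


class TestEffectiveWeights:
    def test_monochromatic_weights_equal_mu(self, tiny_op, tiny_partition):
        grid = pb.EnergyGrid([60.0])
        mats = tuple(
            pb.load_fixture_material(n)
            for n in ("water", "bone_cortical", "iodine_solution_20mgml")
        )
        mus = pb.MaterialSet(mats, grid)
        spec = pb.normalize_spectrum([1.0], grid)
        model = PolyForwardModel(tiny_op, tiny_partition, spec, mus)
        rng = np.random.default_rng(0)
        w = model.weights(rng.uniform(0, 1, model.N_b))
        np.testing.assert_array_equal(w, np.broadcast_to(mus.mu[:, 0], w.shape))

    def test_at_zero_weights_are_spectrum_average(self, tiny_model):
        w = tiny_model.weights(np.zeros(tiny_model.N_b))
        expected = tiny_model.spectrum.q @ tiny_model.mus.mu.T
        np.testing.assert_allclose(w, np.broadcast_to(expected, w.shape), rtol=1e-13)

    def test_bounded_by_mu_range(self, tiny_model):
        rng = np.random.default_rng(1)
        w = tiny_model.weights(rng.uniform(0, 2, tiny_model.N_b))
        lo = tiny_model.mus.mu.min(axis=1)
        hi = tiny_model.mus.mu.max(axis=1)
        assert np.all(w >= lo[np.newaxis, :] - 1e-12)
        assert np.all(w <= hi[np.newaxis, :] + 1e-12)

    def test_large_paths_approach_least_attenuating_bin(self, tiny_model):
        # direct-summation oracle in the hard-beam limit
        t = np.full((tiny_model.J, tiny_model.K), 50.0)
        w = tiny_model.weights_from_t(t)
        s = tiny_model._line_integrals(t)
        m_star = np.argmin(s, axis=1)
        target = tiny_model.mus.mu[:, m_star].T
        np.testing.assert_allclose(w, target, rtol=0.05)


class TestLinearization:
    def test_adjoint_dot_test(self, tiny_model):
        rng = np.random.default_rng(2)
        w = tiny_model.weights(rng.uniform(0, 1, tiny_model.N_b))
        for _ in range(20):
            x = rng.standard_normal(tiny_model.N_b)
            y = rng.standard_normal(tiny_model.J)
            lhs = np.dot(tiny_model.H_apply(x, w), y)
            rhs = np.dot(x, tiny_model.H_adjoint(y, w))
            assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1e-30)

    def test_dense_matches_elementwise_definition(self, tiny_model):
        rng = np.random.default_rng(3)
        bbar = rng.uniform(0, 0.5, tiny_model.N_b)
        w = tiny_model.weights(bbar)
        np.testing.assert_allclose(
            _dense_H(tiny_model, w),
            _dense_H_elementwise(tiny_model, bbar),
            rtol=1e-12, atol=1e-14,
        )

    def test_reconstruction_identity(self, tiny_model):
        """g' = H(bbar') b' + Delta g holds to machine precision for random
        pairs (b', bbar')."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            b = rng.uniform(0, 1, tiny_model.N_b)
            bbar = rng.uniform(0, 1, tiny_model.N_b)
            w = tiny_model.weights(bbar)
            lhs = tiny_model.H_apply(b, w) + tiny_model.delta_g(b, w)
            g = tiny_model.project(b)
            np.testing.assert_allclose(lhs, g, rtol=1e-12, atol=1e-14)

    def test_monochromatic_delta_g_identically_zero(self, tiny_op, tiny_partition):
        grid = pb.EnergyGrid([60.0])
        mats = tuple(
            pb.load_fixture_material(n)
            for n in ("water", "bone_cortical", "iodine_solution_20mgml")
        )
        mus = pb.MaterialSet(mats, grid)
        spec = pb.normalize_spectrum([1.0], grid)
        model = PolyForwardModel(tiny_op, tiny_partition, spec, mus)
        rng = np.random.default_rng(5)
        w = model.weights(rng.uniform(0, 1, model.N_b))
        dg = model.delta_g(rng.uniform(0, 1, model.N_b), w)
        assert np.all(dg == 0.0)

    def test_frechet_derivative_step_halving(self, tiny_model):
        """H(bbar) is the Frechet derivative of the data model: the
        finite-difference error of directional derivatives halves with the
        step (first-order convergence)."""
        rng = np.random.default_rng(6)
        bbar = rng.uniform(0.1, 0.5, tiny_model.N_b)
        d = rng.standard_normal(tiny_model.N_b)
        w = tiny_model.weights(bbar)
        Hd = tiny_model.H_apply(d, w)
        errs = []
        for h in (1e-3, 5e-4, 2.5e-4):
            fd = (tiny_model.project(bbar + h * d) - tiny_model.project(bbar - h * d)) / (2 * h)
            errs.append(np.linalg.norm(fd - Hd) / np.linalg.norm(Hd))
        # central differences: error ~ h^2, certainly shrinking ~>= factor 2
        assert errs[1] < 0.6 * errs[0]
        assert errs[2] < 0.6 * errs[1]


class TestHRowColSums:
    def test_match_dense(self, tiny_model):
        rng = np.random.default_rng(7)
        w = tiny_model.weights(rng.uniform(0, 0.5, tiny_model.N_b))
        H = _dense_H(tiny_model, w)
        np.testing.assert_allclose(
            tiny_model.h_row_sums(w), np.abs(H).sum(axis=1), rtol=1e-12, atol=1e-14
        )
        np.testing.assert_allclose(
            tiny_model.h_col_sums(w), np.abs(H).sum(axis=0), rtol=1e-12, atol=1e-14
        )

    def test_nonnegative(self, tiny_model):
        w = tiny_model.weights(np.zeros(tiny_model.N_b))
        assert np.all(tiny_model.h_row_sums(w) >= 0)
        assert np.all(tiny_model.h_col_sums(w) >= 0)

    def test_combined_adjoint_matches_separate(self, tiny_model):
        rng = np.random.default_rng(8)
        w = tiny_model.weights(rng.uniform(0, 1, tiny_model.N_b))
        y = rng.standard_normal(tiny_model.J)
        hty, cs = tiny_model.H_adjoint_with_colsums(y, w)
        np.testing.assert_array_equal(hty, tiny_model.H_adjoint(y, w))
        np.testing.assert_array_equal(cs, tiny_model.h_col_sums(w))
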