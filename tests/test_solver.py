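"""Prox operators, preconditioners, and PD/dNCPD iteration properties."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polybasis as pb
from _oracles import pol1b_qp as _pol1b_qp
from polybasis import solver as S
from polybasis.forward_model import PolyForwardModel
from polybasis.tv import grad




class TestPol1b:
    def test_inside_ball_unchanged(self):
        x = np.array([0.3, 0.2])
        np.testing.assert_array_equal(S.pol1b(x, 1.0), x)

    def test_two_variable_oracle(self):
        # QP oracle on (3, 1) with r = 2 gives (2, 0)
        np.testing.assert_allclose(S.pol1b(np.array([3.0, 1.0]), 2.0), [2.0, 0.0])
        np.testing.assert_allclose(
            _pol1b_qp(np.array([3.0, 1.0]), 2.0), [2.0, 0.0], atol=1e-8
        )

    def test_zero_radius(self):
        assert np.all(S.pol1b(np.array([1.0, 2.0]), 0.0) == 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            S.pol1b(np.array([-0.1, 1.0]), 1.0)

    def test_matches_qp_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 7)
            x = rng.uniform(0, 3, n)
            r = rng.uniform(0.1, 4.0)
            np.testing.assert_allclose(S.pol1b(x, r), _pol1b_qp(x, r), atol=2e-6)

    @given(
        st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=12),
        st.floats(min_value=0, max_value=20),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_feasibility_invariant(self, xs, r):
        y = S.pol1b(np.array(xs), r)
        assert np.all(y >= 0)
        assert y.sum() <= r + 1e-12


class TestNeg:
    def test_mixed_signs(self):
        np.testing.assert_array_equal(S.neg(np.array([-1.0, 2.0])), [-1.0, 0.0])

    def test_negative_unchanged_and_zeros(self):
        x = np.array([-3.0, -0.5])
        np.testing.assert_array_equal(S.neg(x), x)
        assert np.all(S.neg(np.zeros(4)) == 0)


class TestTvDualStep:
    def test_constant_image_zero_gradient_fixed_point(self):
        v = np.zeros((2, 6, 6))
        d = grad(np.full((6, 6), 2.0))
        out = S.tv_dual_step(v, d, np.full((6, 6), 0.5), 1.3, 10.0)
        assert np.all(out == 0.0)

    def test_slack_constraint_gives_zero_dual(self):
        rng = np.random.default_rng(1)
        d = grad(rng.standard_normal((6, 6)))
        out = S.tv_dual_step(np.zeros((2, 6, 6)), d, np.full((6, 6), 0.5), 1.0, 1e9)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_moreau_decomposition_oracle(self):
        """With uniform sigma the update is prox of the conjugate of the
        TV-ball indicator; check v_next = v' - sigma * proj_ball(v'/sigma)
        against an independent dense projection onto the l1-ball of
        per-pixel magnitudes."""
        rng = np.random.default_rng(2)
        sigma0 = 0.7
        alpha, gamma = 1.4, 2.0
        v = rng.standard_normal((2, 5, 5))
        d = grad(rng.standard_normal((5, 5)))
        sigma = np.full((5, 5), sigma0)
        out = S.tv_dual_step(v, d, sigma, alpha, gamma)
        vp = v + sigma0 * alpha * d
        y = vp / sigma0
        mag = np.sqrt((y**2).sum(axis=0))
        mproj = _pol1b_qp(mag.ravel(), alpha * gamma).reshape(mag.shape)
        scale = np.where(mag > 0, mproj / np.where(mag > 0, mag, 1), 0.0)
        oracle = vp - sigma0 * (y * scale[np.newaxis])
        np.testing.assert_allclose(out, oracle, atol=5e-6)


@pytest.fixture(scope="module")
def small_problem():
    """A 16x16 reconstruction problem with 2 regions and 3 materials."""
    nx = ny = 16
    geo = pb.FanBeamGeometry(
        sor=20.0, sod=30.0, detector_kind="linear",
        n_bins=24, bin_size=0.45, n_views=24, nx=nx, ny=ny, pixel_size=0.4,
    )
    op = pb.build_projector(geo)
    grid = pb.EnergyGrid([45.0, 60.0, 75.0])
    spec = pb.normalize_spectrum([1.0, 2.0, 1.0], grid)
    mats = tuple(
        pb.load_fixture_material(n) for n in ("air", "water", "bone_cortical")
    )
    mus = pb.MaterialSet(mats, grid)
    labels = np.ones((ny, nx), dtype=np.int32)
    labels[4:12, 4:12] = 2
    part = pb.validate_partition(labels, [(0, 1), (1, 2)], [0, 1], K=3)
    rho = mus.densities
    b = np.zeros(part.N_b)
    yy, xx = np.mgrid[0:ny, 0:nx]
    core = ((xx - 7.5) ** 2 + (yy - 7.5) ** 2 <= 9).ravel()
    b[part.block(0, 1)] = rho[1] * (
        ((xx - 7.5) ** 2 + (yy - 7.5) ** 2 <= 36).ravel()[part.region_pixels[0]]
    )
    b[part.block(0, 0)] = rho[0] * (1.0 - b[part.block(0, 1)] / rho[1])
    b[part.block(1, 2)] = rho[2] * core[part.region_pixels[1]]
    b[part.block(1, 1)] = rho[1] * (1.0 - core[part.region_pixels[1]])
    model = PolyForwardModel(op, part, spec, mus)
    data = model.project(b)
    return model, b, data


class TestInitScaling:
    def test_rho_homogeneity(self, small_problem):
        model, b, data = small_problem
        cfg1 = S.SolverConfig(gamma_m1=1.0, gamma_m2=1.0, m1=0, m2=2, rho_pc=1.0)
        cfg2 = S.SolverConfig(gamma_m1=1.0, gamma_m2=1.0, m1=0, m2=2, rho_pc=3.0)
        p1 = S.init_scaling(model, cfg1)
        p2 = S.init_scaling(model, cfg2)
        np.testing.assert_allclose(p2.sigma_u, 3.0 * p1.sigma_u, rtol=1e-12)
        np.testing.assert_allclose(p2.sigma_v, 3.0 * p1.sigma_v, rtol=1e-12)
        np.testing.assert_allclose(p2.tau, p1.tau / 3.0, rtol=1e-12)

    def test_nu_equals_norm_H0(self, small_problem):
        model, _, _ = small_problem
        cfg = S.SolverConfig(gamma_m1=1.0, gamma_m2=1.0, m1=0, m2=2)
        p = S.init_scaling(model, cfg)
        assert p.nu == p.norm_H0  # ||I||_2 = 1

    def test_sigma_u_matches_dense_row_sums(self, small_problem):
        model, _, _ = small_problem
        cfg = S.SolverConfig(gamma_m1=1.0, gamma_m2=1.0, m1=0, m2=2)
        p = S.init_scaling(model, cfg)
        w0 = model.weights_from_t(np.zeros((model.J, model.K)))
        H = np.zeros((model.J, model.N_b))
        for c in range(model.N_b):
            e = np.zeros(model.N_b)
            e[c] = 1.0
            H[:, c] = model.H_apply(e, w0)
        rs = np.abs(H).sum(axis=1)
        expected = np.where(rs > 0, 1.0 / np.where(rs > 0, rs, 1), 0.0)
        np.testing.assert_allclose(p.sigma_u, expected, rtol=1e-10)

    def test_zero_rows_get_zero_sigma(self, small_problem):
        model, _, _ = small_problem
        cfg = S.SolverConfig(gamma_m1=1.0, gamma_m2=1.0, m1=0, m2=2)
        p = S.init_scaling(model, cfg)
        rows = model.h_row_sums(model.weights_from_t(np.zeros((model.J, model.K))))
        assert np.all((p.sigma_u == 0) == (rows == 0))


class TestIterate:
    def test_zero_data_zero_gamma_no_vc_fixed_point(self):
        nx = ny = 8
        geo = pb.FanBeamGeometry(
            sor=10.0, sod=15.0, detector_kind="linear",
            n_bins=12, bin_size=0.6, n_views=8, nx=nx, ny=ny, pixel_size=0.5,
        )
        op = pb.build_projector(geo)
        grid = pb.EnergyGrid([60.0])
        mats = (pb.load_fixture_material("water"),)
        mus = pb.MaterialSet(mats, grid)
        part = pb.validate_partition(np.ones((ny, nx), np.int32), [(0,)], [], K=1)
        spec = pb.normalize_spectrum([1.0], grid)
        model = PolyForwardModel(op, part, spec, mus)
        cfg = S.SolverConfig(gamma_m1=0.0, gamma_m2=0.0, m1=0, m2=0, max_iters=5)
        pre = S.init_scaling(model, cfg)
        state = S.init_state(model, pre)
        data = np.zeros(model.J)
        for _ in range(5):
            state = S.iterate(state, data, pre, model, cfg)
        assert np.all(state.b == 0.0)

    def test_monochromatic_dncpd_equals_pd_bitwise(self, small_problem):
        """With M = 1 the data model is linear: dNCPD and PD must produce
        bit-identical iterates and Delta g = 0 at every iteration."""
        model_poly, b_truth, _ = small_problem
        grid = pb.EnergyGrid([60.0])
        mats = tuple(
            pb.load_fixture_material(n) for n in ("air", "water", "bone_cortical")
        )
        mus = pb.MaterialSet(mats, grid)
        spec = pb.normalize_spectrum([1.0], grid)
        model = PolyForwardModel(
            model_poly.system, model_poly.partition, spec, mus
        )
        data = model.project(b_truth)
        g1 = 50.0
        g2 = 30.0
        states = {}
        for alg in ("pd", "dncpd"):
            cfg = S.SolverConfig(
                gamma_m1=g1, gamma_m2=g2, m1=0, m2=0, algorithm=alg, max_iters=50
            )
            pre = S.init_scaling(model, cfg)
            st_ = S.init_state(model, pre)
            for _ in range(50):
                st_ = S.iterate(st_, data, pre, model, cfg)
                if alg == "dncpd":
                    assert np.all(st_.dg == 0.0)
            states[alg] = st_
        np.testing.assert_array_equal(states["pd"].b, states["dncpd"].b)
        np.testing.assert_array_equal(states["pd"].u, states["dncpd"].u)
        np.testing.assert_array_equal(states["pd"].v, states["dncpd"].v)

    def test_determinism(self, small_problem):
        model, b, data = small_problem
        g1, g2 = 100.0, 60.0
        cfg = S.SolverConfig(gamma_m1=g1, gamma_m2=g2, m1=0, m2=2, max_iters=30)
        out1, h1 = S.solve(
            data, model.system, model.partition, model.spectrum, model.mus, cfg
        )
        out2, h2 = S.solve(
            data, model.system, model.partition, model.spectrum, model.mus, cfg
        )
        np.testing.assert_array_equal(out1, out2)
        assert [r.data for r in h1] == [r.data for r in h2]


class TestConvergenceMetrics:
    def test_truth_with_noiseless_data_near_zero(self, small_problem):
        model, b, data = small_problem
        from polybasis.tv import isotropic_tv

        g1 = isotropic_tv(pb.compute_vmi(b, model.partition, model.mus, 0))
        g2 = isotropic_tv(pb.compute_vmi(b, model.partition, model.mus, 2))
        cfg = S.SolverConfig(gamma_m1=g1, gamma_m2=g2, m1=0, m2=2)
        pre = S.init_scaling(model, cfg)
        state = S.init_state(model, pre)
        # place the state at the truth with a consistent linearization
        state.b = b.copy()
        state.b_prev = b.copy()
        state.t_b = model.path_lengths(b)
        state.weights = model.weights_from_t(state.t_b)
        state.dg = model.delta_g_from_t(state.t_b, state.weights)
        rec = S.convergence_metrics(state, data, model, cfg, truth_bprime=b)
        assert rec.data <= 1e-10
        assert rec.tv1 <= 1e-10 and rec.tv2 <= 1e-10
        assert rec.max_vc() <= 1e-10
        assert rec.nonneg == 0.0
        assert rec.nrmse == 0.0

    def test_nrmse_zero_iff_truth(self, small_problem):
        model, b, data = small_problem
        cfg = S.SolverConfig(gamma_m1=1.0, gamma_m2=1.0, m1=0, m2=2)
        pre = S.init_scaling(model, cfg)
        state = S.init_state(model, pre)
        state.b = b * 1.01
        rec = S.convergence_metrics(state, data, model, cfg, truth_bprime=b)
        assert rec.nrmse > 0


class TestSolveSmall:
    def test_pd_primal_change_contracts(self):
        """On a tiny well-posed instance the Chambolle-Pock-type contraction
        drives the relative primal change below 1e-8."""
        nx = ny = 8
        geo = pb.FanBeamGeometry(
            sor=10.0, sod=15.0, detector_kind="linear",
            n_bins=16, bin_size=0.5, n_views=16, nx=nx, ny=ny, pixel_size=0.5,
        )
        op = pb.build_projector(geo)
        grid = pb.EnergyGrid([50.0, 70.0])
        spec = pb.normalize_spectrum([1.0, 1.0], grid)
        mus = pb.MaterialSet((pb.load_fixture_material("water"),), grid)
        part = pb.validate_partition(np.ones((ny, nx), np.int32), [(0,)], [], K=1)
        model = PolyForwardModel(op, part, spec, mus)
        rng = np.random.default_rng(0)
        b = rng.uniform(0.2, 1.0, part.N_b)
        data = model.project(b)
        from polybasis.tv import isotropic_tv

        g1 = 1.5 * isotropic_tv(pb.compute_vmi(b, part, mus, 0))
        g2 = 1.5 * isotropic_tv(pb.compute_vmi(b, part, mus, 1))
        cfg = S.SolverConfig(
            gamma_m1=g1, gamma_m2=g2, m1=0, m2=1, algorithm="pd",
            max_iters=20000, tolerances={"primal_change": 1e-8},
        )
        _, hist = S.solve(data, op, part, spec, mus, cfg, metrics_every=100)
        assert hist[-1].primal_change < 1e-8
        assert hist[-1].n < 20000  # stopped by the tolerance, not the cap
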