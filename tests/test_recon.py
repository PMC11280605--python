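"""CGLS, ADMM sub-problem updates, denoising, and the reconstruction drivers."""

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from cestrecon import (
    FrequencyGrid,
    ReconConfig,
    add_noise,
    cgls_solve,
    conventional_reconstruct,
    estimate_lambda,
    fft_recon,
    get_denoiser,
    joint_reconstruct,
    register_denoiser,
)
from cestrecon.phantom import KSpaceSeries, cfft2, icfft2
from cestrecon.recon import (
    ADMMState,
    denoise_v,
    update_duals,
    update_T,
    update_Z,
)
from cestrecon.zspectrum import ZParamsMap

from conftest import WATER_A, WATER_GAMMA


def _tiny_state(shape=(1, 1), n_offsets=3, rho=0.5, rng=None):
    """A minimal ADMM state on an (n_offsets, ny, nx) stack for unit tests."""
    rng = rng or np.random.default_rng(0)
    grid = FrequencyGrid(np.linspace(-100.0, 100.0, n_offsets), 0, 0.0, ())
    ny, nx = shape
    sh = (n_offsets, ny, nx)
    f = rng.uniform(0.5, 1.5, sh)
    Zs = rng.uniform(0.5, 1.0, sh)
    T = rng.uniform(0.5, 1.0, sh)
    Zs[0] = 1.0  # the reference sample is 1 by definition
    T[0] = 1.0
    zmap = ZParamsMap(np.zeros(shape), np.full(shape, 1e4),
                      np.zeros((0,) + shape), np.zeros((0,) + shape),
                      (), "LG", -1.0, 0.0, np.ones(shape, bool))
    return ADMMState(f=f, phase=np.zeros(sh), v=f.copy(), T=T,
                     Zs=Zs, zmap=zmap, y=rng.normal(0, 0.1, sh),
                     z=rng.normal(0, 0.1, sh), t=rng.normal(0, 0.1, sh),
                     grid=grid, mask=np.ones(shape, bool), rho=rho)


class TestCGLS:
    def test_identity_system_one_iteration(self):
        r = np.arange(8.0)
        x, info = cgls_solve(lambda v: (v,), lambda t: t[0], (r,), np.zeros(8))
        assert np.allclose(x, r)
        assert info["iters"] == 1

    def test_dense_oracle(self):
        """An 8×8 least-squares system solved by CGLS matches the dense
        normal-equations solution."""
        rng = np.random.default_rng(1)
        A = rng.normal(size=(12, 8)) + 1j * rng.normal(size=(12, 8))
        b = rng.normal(size=12) + 1j * rng.normal(size=12)
        x, _ = cgls_solve(lambda v: (A @ v,), lambda t: A.conj().T @ t[0],
                          (b,), np.zeros(8, complex), tol=1e-12, max_iters=200)
        x_ref = np.linalg.solve(A.conj().T @ A, A.conj().T @ b)
        assert np.max(np.abs(x - x_ref)) < 1e-8

    def test_exact_init_returns_immediately(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(8, 8))
        x_true = rng.normal(size=8)
        x, info = cgls_solve(lambda v: (A @ v,), lambda t: A.T @ t[0],
                             (A @ x_true,), x_true)
        assert info["iters"] == 0
        assert np.array_equal(x, x_true)

    @pytest.mark.parametrize("seed", range(10))
    def test_adjoint_pair(self, seed):
        """⟨forward(u), w⟩ = ⟨u, adjoint(w)⟩ for the f-update operator."""
        rng = np.random.default_rng(seed)
        sh = (4, 16, 16)
        A = np.exp(1j * rng.uniform(-np.pi, np.pi, sh))
        sr = np.sqrt(0.5)

        def forward(x):
            return (cfft2(A * x), sr * x, sr * x)

        def adjoint(r):
            return np.conj(A) * icfft2(r[0]) + sr * (r[1] + r[2])

        u = rng.normal(size=sh) + 1j * rng.normal(size=sh)
        w = tuple(rng.normal(size=sh) + 1j * rng.normal(size=sh) for _ in range(3))
        lhs = sum(np.vdot(wi, fi) for wi, fi in zip(w, forward(u)))
        rhs = np.vdot(adjoint(w), u)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10


class TestFFTRecon:
    def test_noiseless_magnitudes_exact(self, brain64):
        images, _ = fft_recon(brain64.ks)
        err = np.abs(images.data - brain64.images.data).max()
        assert err / brain64.images.data.max() < 1e-12

    def test_zero_kspace_gives_zero_images(self, brain64):
        ks = KSpaceSeries(np.zeros_like(brain64.ks.data), brain64.grid)
        images, _ = fft_recon(ks)
        assert np.all(images.data == 0.0)

    def test_dc_delta_gives_constant(self, grid51):
        n = 16
        data = np.zeros((51, n, n), complex)
        data[:, n // 2, n // 2] = 2.0
        images, _ = fft_recon(KSpaceSeries(data, grid51))
        assert np.allclose(images.data, 2.0 / n)


class TestUpdateT:
    def test_consistent_point_is_fixed(self):
        st = _tiny_state()
        st.y[:] = 0.0
        st.t[:] = 0.0
        st.f = st.f0[None] * st.Zs
        update_T(st)
        assert np.allclose(st.T, st.Zs, atol=1e-14)

    def test_unit_reference_averages(self):
        st = _tiny_state()
        st.y[:] = 0.0
        st.t[:] = 0.0
        st.f[st.grid.ref_index] = 1.0
        update_T(st)
        expected = (st.Zs + st.f) / 2.0
        assert np.allclose(st.T, expected, atol=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_numeric_scalar_minimizer(self, seed):
        """The closed form agrees with brute 1-D minimization of the scalar
        T objective y(f−f0T) + ρ/2(f−f0T)² + t(T−Z) + ρ/2(T−Z)²."""
        rng = np.random.default_rng(seed)
        f, f0, Z, y, t = rng.uniform(0.2, 1.5, 5)
        rho = 0.5

        def obj(T):
            return (y * (f - f0 * T) + rho / 2 * (f - f0 * T) ** 2
                    + t * (T - Z) + rho / 2 * (T - Z) ** 2)

        closed = (rho * Z - t + f0 * y + rho * f * f0) / (rho * f0**2 + rho)
        # locate the minimum as the zero crossing of the numeric gradient
        # (central differences), which resolves beyond the ~sqrt(eps) floor
        # of direct 1-D function minimization
        h = 1e-4
        num = brentq(lambda T: (obj(T + h) - obj(T - h)) / (2 * h), -10, 10,
                     xtol=1e-12)
        assert abs(closed - num) < 1e-8
        coarse = minimize_scalar(obj, method="brent", options={"xtol": 1e-10}).x
        assert abs(closed - coarse) < 1e-6


class TestUpdateZ:
    def test_target_is_calculus_solution(self):
        """The unconstrained minimizer of t(T−Z) + ρ/2|T−Z|² over free Z is
        T + t/ρ — checked against numeric 1-D minimization."""
        rng = np.random.default_rng(4)
        T, t = rng.uniform(0.2, 1.0), rng.normal(0, 0.2)
        rho = 0.5
        num = minimize_scalar(lambda Z: t * (T - Z) + rho / 2 * (T - Z) ** 2,
                              method="brent", options={"xtol": 1e-12}).x
        assert abs(num - (T + t / rho)) < 1e-8

    def test_model_family_target_recovered(self, brain64):
        """With t = 0 and T exactly in the model family, the fitted Z equals
        T and the parameters are recovered."""
        rng = np.random.default_rng(5)
        grid = brain64.grid
        truth = brain64.images.data / np.where(brain64.scene.s0_map > 0,
                                               brain64.scene.s0_map, 1.0)[None]
        mask = brain64.scene.label_map > 0
        zmap = ZParamsMap(np.zeros(mask.shape), np.full(mask.shape, 1e4),
                          np.zeros((1,) + mask.shape), np.full((1,) + mask.shape, 150.0),
                          (450.0,), "LG", -1.0, 0.0, mask)
        st = ADMMState(f=brain64.images.data.copy(), phase=np.zeros_like(truth),
                       v=brain64.images.data.copy(), T=truth.copy(), Zs=truth.copy(),
                       zmap=zmap, y=np.zeros_like(truth), z=np.zeros_like(truth),
                       t=np.zeros_like(truth), grid=grid, mask=mask, rho=0.5)
        update_Z(st, [450.0], "LG", ReconConfig(fit_warm_max_iter=80))
        assert np.abs(st.Zs[:, mask] - truth[:, mask]).max() < 1e-6
        assert np.abs(st.zmap.a[mask] / WATER_A - 1).max() < 1e-6
        assert np.abs(st.zmap.gamma[mask] / WATER_GAMMA - 1).max() < 1e-6


class TestEstimateLambda:
    def test_constant_image_zero(self):
        assert estimate_lambda(np.full((32, 32), 1.7)) == 0.0

    def test_gaussian_field_calibration(self):
        """On a pure σ=0.1 noise field the estimate lands within 25% of
        0.5·σ² (the patch-variance mode sits slightly below σ²)."""
        rng = np.random.default_rng(6)
        img = rng.normal(0.0, 0.1, (128, 128))
        lam = estimate_lambda(img)
        assert abs(lam / (0.5 * 0.01) - 1) < 0.25

    def test_noise_monotonicity(self):
        rng = np.random.default_rng(7)
        clean = np.tile(np.linspace(0, 1, 64), (64, 1))
        noisy = clean + rng.normal(0, 0.1, clean.shape)
        assert estimate_lambda(noisy) >= estimate_lambda(clean)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_lambda(np.zeros((4, 4)), patch_size=5)


class TestDenoiseV:
    def test_identity_denoiser_passes_through(self):
        st = _tiny_state(shape=(16, 16))
        cfg = ReconConfig(denoiser="identity")
        denoise_v(st, cfg)
        assert np.allclose(st.v, st.f - st.z / st.rho)

    def test_unknown_denoiser_rejected(self):
        with pytest.raises(KeyError, match="unknown denoiser"):
            get_denoiser("no_such_filter")

    def test_nlm_reduces_mse_on_noisy_phantom(self, brain64):
        rng = np.random.default_rng(8)
        clean = brain64.images.data[10]
        noisy = clean + rng.normal(0, 0.05, clean.shape)
        dn = get_denoiser("nlm")
        lam = estimate_lambda(noisy)
        out = dn(noisy, lam)
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_pluggable_custom_denoiser(self):
        calls = []

        def blur(image, lam):
            calls.append(lam)
            return image * 0.5

        register_denoiser("halve", blur)
        st = _tiny_state(shape=(16, 16))
        denoise_v(st, ReconConfig(denoiser="halve"))
        assert len(calls) == st.grid.n_offsets
        assert np.allclose(st.v, (st.f - st.z / st.rho) * 0.5)


class TestUpdateDuals:
    def test_satisfied_constraints_leave_duals(self):
        st = _tiny_state()
        st.f = st.f0[None] * st.Zs
        st.v = st.f.copy()
        st.T = st.Zs.copy()
        y0, z0, t0 = st.y.copy(), st.z.copy(), st.t.copy()
        update_duals(st, ReconConfig())
        assert np.allclose(st.y, y0) and np.allclose(st.z, z0) and np.allclose(st.t, t0)

    def test_linear_increment_and_additivity(self):
        st = _tiny_state()
        r = st.f - st.f0[None] * st.Zs
        y0 = st.y.copy()
        update_duals(st, ReconConfig())
        assert np.allclose(st.y, y0 + st.rho * r)
        update_duals(st, ReconConfig())
        assert np.allclose(st.y, y0 + 2 * st.rho * r)

    def test_dual_y_form_switch_uses_T(self):
        st = _tiny_state()
        y0 = st.y.copy()
        rT = st.f - st.f0[None] * st.T
        update_duals(st, ReconConfig(dual_y_form="T"))
        assert np.allclose(st.y, y0 + st.rho * rT)


class TestConventionalReconstruct:
    def test_noiseless_parameter_recovery(self, brain64):
        res = conventional_reconstruct(brain64.ks, [450.0])
        m = brain64.scene.label_map > 0
        insert = brain64.scene.label_map == 2
        assert np.abs(res.zparams.a[m] / WATER_A - 1).max() < 1e-4
        assert np.abs(res.zparams.gamma[m] / WATER_GAMMA - 1).max() < 1e-4
        assert np.abs(res.zparams.pool_amplitude[0][insert] / 0.12 - 1).max() < 1e-4

    def test_background_not_fitted(self, brain64):
        res = conventional_reconstruct(brain64.ks, [450.0])
        bg = brain64.scene.label_map == 0
        assert not res.zparams.mask[bg].any()
        assert np.all(res.zparams.a[bg] == 0.0)

    def test_noisy_deterministic(self, brain64):
        ks = add_noise(brain64.ks, 0.105, seed=13)
        r1 = conventional_reconstruct(ks, [450.0])
        r2 = conventional_reconstruct(ks, [450.0])
        assert np.array_equal(r1.images.data, r2.images.data)
        assert np.array_equal(r1.zparams.a, r2.zparams.a)


class TestJointReconstruct:
    def test_epsilon_infinity_single_iteration(self, brain64):
        ks = add_noise(brain64.ks, 0.105, seed=2)
        res = joint_reconstruct(ks, [450.0],
                                cfg=ReconConfig(epsilon=np.inf, max_outer_iters=5))
        assert res.converged
        assert len(res.history) == 1

    def test_history_schema_and_phase_modulus(self, brain64):
        ks = add_noise(brain64.ks, 0.105, seed=2)
        res = joint_reconstruct(ks, [450.0], cfg=ReconConfig(max_outer_iters=3))
        assert len(res.history) <= 3
        for h in res.history:
            for key in ("rel_change_f", "rel_change_Z", "fidelity_residual",
                        "constraint_violation"):
                assert np.isfinite(h[key])
        assert np.allclose(np.abs(np.exp(1j * res.phase.phase)), 1.0)
        assert np.all(res.images.data >= 0.0)
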