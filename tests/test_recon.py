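"""Phase subspace, CGLS, and the three reconstructions."""

import warnings

import numpy as np
import pytest

from mpbnssfp.dictionary import (build_dictionary, compute_subspace,
                                 make_param_grid)
from mpbnssfp.pipeline import band_delta_range
from mpbnssfp.recon import (cgls, compose_contrasts, density_weights,
                            phase_subspace, scr, scr_b0, sense_b0)
from mpbnssfp.recon import _contrast_adjoint, _contrast_forward, \
    _joint_adjoint, _joint_forward
from mpbnssfp.sampling import build_operator, design_spiral, schedule_arms
from mpbnssfp.synth import (ParamMap, make_coilmaps, make_phantom,
                            simulate_map_signals, synthesize_kspace)


class TestPhaseSubspace:
    def test_zero_delta_is_rank_one(self):
        tau = np.linspace(0, 22, 30)
        ps = phase_subspace(np.zeros((8, 8)), tau, d2=1)
        assert np.isclose(ps.energy_fraction(1), 1.0)
        E = ps.u_tilde @ (ps.s_tilde[:, None]
                          * ps.v_tilde.conj().T)
        assert np.allclose(E, 1.0, atol=1e-10)

    def test_full_rank_exact(self, rng):
        delta = rng.uniform(-80, 80, (4, 4))
        tau = np.linspace(0, 22, 10)
        ps = phase_subspace(delta, tau, d2=10)
        E_true = np.exp(-2j * np.pi * tau[:, None] * 1e-3
                        * delta.ravel()[None, :])
        E_rec = ps.u_tilde @ (ps.s_tilde[:, None] * ps.v_tilde.conj().T)
        assert np.allclose(E_rec, E_true, atol=1e-10)

    def test_eckart_young_tail(self, rng):
        # truncation Frobenius error^2 equals the tail singular energy
        delta = rng.uniform(-100, 100, 64).reshape(8, 8)
        tau = np.linspace(0, 22, 24)
        E = np.exp(-2j * np.pi * tau[:, None] * 1e-3
                   * delta.ravel()[None, :])
        s_all = np.linalg.svd(E, compute_uv=False)
        d2 = 5
        ps = phase_subspace(delta, tau, d2=d2)
        E_rec = ps.u_tilde @ (ps.s_tilde[:, None] * ps.v_tilde.conj().T)
        err2 = np.linalg.norm(E - E_rec) ** 2
        assert np.isclose(err2, (s_all[d2:] ** 2).sum(), rtol=1e-6)

    def test_automatic_d2_selection(self):
        yy, xx = np.meshgrid(np.arange(16), np.arange(16))
        delta = 3.0 * (xx - 8)  # up to +-24 Hz
        tau = np.linspace(0, 22, 40)
        ps = phase_subspace(delta, tau, d2=None, energy=0.999)
        assert 1 <= ps.d2 <= 16
        assert ps.energy_fraction() >= 0.999


class TestCgls:
    def test_residual_monotone_nonincreasing(self, rng):
        A = rng.standard_normal((30, 12)) + 1j * rng.standard_normal((30, 12))
        y = rng.standard_normal(30) + 1j * rng.standard_normal(30)
        x, info = cgls(lambda x: A @ x, lambda r: A.conj().T @ r, y,
                       np.zeros(12, complex), max_iter=30, tol=1e-14)
        r = np.array(info.residual_norms)
        assert np.all(np.diff(r) <= 1e-10)

    def test_solves_least_squares(self, rng):
        A = rng.standard_normal((30, 12)) + 1j * rng.standard_normal((30, 12))
        y = rng.standard_normal(30) + 1j * rng.standard_normal(30)
        x, _ = cgls(lambda x: A @ x, lambda r: A.conj().T @ r, y,
                    np.zeros(12, complex), max_iter=100, tol=1e-14)
        x_ref = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(x, x_ref, atol=1e-8)

    def test_warns_when_not_converged(self, rng):
        A = rng.standard_normal((30, 12)) + 1j * rng.standard_normal((30, 12))
        y = rng.standard_normal(30) + 1j * rng.standard_normal(30)
        with pytest.warns(UserWarning):
            cgls(lambda x: A @ x, lambda r: A.conj().T @ r, y,
                 np.zeros(12, complex), max_iter=1, tol=1e-16)


@pytest.fixture(scope="module")
def smooth_setup(train2):
    """Band-limited phantom + full-sampling operator on a 16x16 grid."""
    N = 16
    yy, xx = np.meshgrid(np.arange(N), np.arange(N))
    blob = np.exp(-(((xx - N / 2) / 2.5) ** 2
                    + ((yy - N / 2) / 2.5) ** 2) / 2)
    i0 = blob * np.exp(1j * 0.3 * (xx - yy) / N)
    u, v = (xx - N / 2) / (N / 2), (yy - N / 2) / (N / 2)
    pm = ParamMap(t1=np.full((N, N), 800.0), t2=np.full((N, N), 80.0),
                  delta=12 * u + 8 * u * v, b1=np.ones((N, N)),
                  i0=i0, mask=np.ones((N, N), bool))
    traj = design_spiral(N, n_arms=6, readout_ms=22.0, n_samples=240)
    sched = schedule_arms(train2.n_contrasts, 6, 1.0)
    op = build_operator(traj, sched, (N, N))
    M = simulate_map_signals(pm, train2)
    truth = M.reshape(train2.n_contrasts, N, N)
    return pm, op, truth


@pytest.fixture(scope="module")
def complete_subspace(train2):
    g = make_param_grid(delta_range=band_delta_range(30.0, 5),
                        t1_steps=6, t2_steps=6, delta_steps=5, b1_steps=3)
    d = build_dictionary(g, train2)
    return compute_subspace(d, train2.n_contrasts)


class TestSense:
    def test_identity_limit(self, train2, smooth_setup):
        # single coil of ones, full sampling, Delta = 0
        pm, op, _ = smooth_setup
        N = 16
        pm0 = ParamMap(t1=pm.t1, t2=pm.t2, delta=np.zeros((N, N)),
                       b1=pm.b1, i0=pm.i0, mask=pm.mask)
        cm = make_coilmaps(1, (N, N))
        kd = synthesize_kspace(pm0, train2, op, cm)
        truth = simulate_map_signals(pm0, train2).reshape(-1, N, N)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            I = sense_b0(kd, cm, op, None, max_iter=300, tol=1e-12).images
        assert (np.linalg.norm(I - truth)
                / np.linalg.norm(truth)) < 1e-4

    def test_matches_dense_pseudo_inverse(self, train2, rng):
        N = 8
        traj = design_spiral(N, n_arms=4, readout_ms=4.0, n_samples=40)
        op = build_operator(traj, schedule_arms(1, 4, 1.0), (N, N))
        cm = make_coilmaps(2, (N, N))
        sw = np.sqrt(density_weights(op, 0))
        A = np.zeros((2 * op.n_samples_per_contrast, N * N), complex)
        for j in range(N * N):
            e = np.zeros(N * N)
            e[j] = 1.0
            A[:, j] = (_contrast_forward(e.reshape(N, N) + 0j, 0, cm, op,
                                         None) * sw[None, :]).ravel()
        y = rng.standard_normal((2, op.n_samples_per_contrast)) \
            + 1j * rng.standard_normal((2, op.n_samples_per_contrast))
        x_pinv = (np.linalg.pinv(A) @ (y * sw[None, :]).ravel()
                  ).reshape(N, N)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x_cg, _ = cgls(
                lambda x: _contrast_forward(x, 0, cm, op, None) * sw,
                lambda r: _contrast_adjoint(r * sw, 0, cm, op, None),
                y * sw, np.zeros((N, N), complex),
                max_iter=400, tol=1e-15)
        assert (np.linalg.norm(x_cg - x_pinv)
                / np.linalg.norm(x_pinv)) < 1e-6

    def test_b0_compensation_reduces_error(self, train2, smooth_setup):
        pm, op, truth = smooth_setup
        N = 16
        # strong smooth field, 22 ms readouts
        yy, xx = np.meshgrid(np.arange(N), np.arange(N))
        u, v = (xx - N / 2) / (N / 2), (yy - N / 2) / (N / 2)
        delta = 60 * u + 30 * v
        pm2 = ParamMap(t1=pm.t1, t2=pm.t2, delta=delta, b1=pm.b1,
                       i0=pm.i0, mask=pm.mask)
        cm = make_coilmaps(2, (N, N))
        kd = synthesize_kspace(pm2, train2, op, cm)
        truth2 = simulate_map_signals(pm2, train2).reshape(-1, N, N)
        ps = phase_subspace(delta, op.trajectory.tau)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            I_with = sense_b0(kd, cm, op, ps, max_iter=30).images
            I_wo = sense_b0(kd, cm, op, None, max_iter=30).images
        e_with = np.linalg.norm(I_with - truth2)
        e_wo = np.linalg.norm(I_wo - truth2)
        assert e_with < e_wo


class TestScr:
    def test_zero_data_gives_zero_components(self, train2,
                                             complete_subspace):
        N = 16
        traj = design_spiral(N, n_arms=4, readout_ms=22.0, n_samples=100)
        op = build_operator(traj,
                            schedule_arms(train2.n_contrasts, 4, 1.0),
                            (N, N))
        cm = make_coilmaps(2, (N, N))
        from mpbnssfp.synth import KSpaceData
        kd = KSpaceData(data=np.zeros(
            (train2.n_contrasts, 2, op.n_samples_per_contrast), complex))
        comp = scr(kd, cm, op, complete_subspace, max_iter=5)
        assert np.all(comp.coefficients == 0)

    def test_complete_basis_matches_sense(self, train2, smooth_setup,
                                          complete_subspace):
        pm, op, truth = smooth_setup
        cm = make_coilmaps(2, (16, 16))
        kd = synthesize_kspace(pm, train2, op, cm)
        ps = phase_subspace(pm.delta, op.trajectory.tau, d2=None,
                            energy=1 - 1e-12, d2_cap=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            I_sense = sense_b0(kd, cm, op, ps, max_iter=250,
                               tol=1e-13).images
            comp = scr_b0(kd, cm, op, complete_subspace, ps,
                          max_iter=250, tol=1e-13)
        I_scr = compose_contrasts(complete_subspace, comp).images
        assert (np.linalg.norm(I_scr - I_sense)
                / np.linalg.norm(I_sense)) < 1e-6

    def test_scr_b0_with_zero_delta_equals_scr(self, train2,
                                               complete_subspace):
        N = 16
        pm = make_phantom((N, N), b0_poly=(0, 0, 0, 0), background=None)
        traj = design_spiral(N, n_arms=4, readout_ms=22.0, n_samples=150)
        op = build_operator(traj,
                            schedule_arms(train2.n_contrasts, 4, 2.0),
                            (N, N))
        cm = make_coilmaps(2, (N, N))
        kd = synthesize_kspace(pm, train2, op, cm)
        ps = phase_subspace(np.zeros((N, N)), traj.tau, d2=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = scr(kd, cm, op, complete_subspace, max_iter=30)
            b = scr_b0(kd, cm, op, complete_subspace, ps, max_iter=30)
        assert (np.linalg.norm(a.coefficients - b.coefficients)
                / np.linalg.norm(a.coefficients)) < 1e-8

    def test_objective_at_truth_below_zero_solution(self, train2,
                                                    smooth_setup,
                                                    complete_subspace):
        pm, op, truth = smooth_setup
        cm = make_coilmaps(2, (16, 16))
        kd = synthesize_kspace(pm, train2, op, cm)
        ps = phase_subspace(pm.delta, op.trajectory.tau, d2=None,
                            energy=1 - 1e-12, d2_cap=40)
        sigma_true = np.einsum("qm,qxy->mxy",
                               np.conj(complete_subspace.basis), truth)
        y_hat = _joint_forward(sigma_true, complete_subspace, cm, op, ps)
        obj_true = np.linalg.norm(kd.data - y_hat) ** 2
        obj_zero = np.linalg.norm(kd.data) ** 2
        assert obj_true < obj_zero

    def test_full_operator_adjointness(self, train2, smooth_setup,
                                       complete_subspace, rng):
        pm, op, _ = smooth_setup
        cm = make_coilmaps(2, (16, 16))
        ps = phase_subspace(pm.delta, op.trajectory.tau, d2=4)
        d1 = complete_subspace.d1
        s0 = rng.standard_normal((d1, 16, 16)) \
            + 1j * rng.standard_normal((d1, 16, 16))
        shape = (train2.n_contrasts, 2, op.n_samples_per_contrast)
        y0 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = np.vdot(y0, _joint_forward(s0, complete_subspace, cm, op, ps))
        rhs = np.vdot(_joint_adjoint(y0, complete_subspace, cm, op, ps,
                                     (16, 16)), s0)
        assert abs(lhs - rhs) / (np.linalg.norm(s0)
                                 * np.linalg.norm(y0)) < 1e-6


class TestCompose:
    def test_zero_components(self, complete_subspace):
        I = compose_contrasts(complete_subspace,
                              np.zeros((complete_subspace.d1, 4, 4),
                                       complex))
        assert np.all(I.images == 0)

    def test_rank_one_constant(self, complete_subspace):
        sigma = np.zeros((complete_subspace.d1, 4, 4), complex)
        sigma[0] = 1.0
        I = compose_contrasts(complete_subspace, sigma)
        for q in range(I.n_contrasts):
            assert np.allclose(I.images[q],
                               complete_subspace.basis[q, 0])

    def test_projector_identity_on_span(self, complete_subspace, rng):
        U = complete_subspace.basis
        coeff = rng.standard_normal((U.shape[1], 6)) \
            + 1j * rng.standard_normal((U.shape[1], 6))
        I = U @ coeff
        assert np.allclose(U @ (U.conj().T @ I), I, atol=1e-10)
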