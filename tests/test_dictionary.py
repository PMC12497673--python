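"""Parameter grids, contrast subspace, dictionary matching and refinement."""

import numpy as np
import pytest

from mpbnssfp.bloch import SlabEnsemble, TissueParams, simulate_si
from mpbnssfp.dictionary import (SignalDictionary, _parabola_offset,
                                 build_dictionary, compute_subspace,
                                 interpolate_refine, load_dictionary_arrays,
                                 make_param_grid, match_dictionary,
                                 refine_descent, save_dictionary)
from mpbnssfp.pipeline import band_delta_range


def band_grid(delta_steps=7, **kw):
    """Small matching grid with Delta restricted to one wrap band."""
    defaults = dict(t1_steps=10, t2_steps=10, b1_steps=3)
    defaults.update(kw)
    return make_param_grid(delta_range=band_delta_range(30.0, delta_steps),
                           delta_steps=delta_steps, **defaults)


class TestParamGrid:
    def test_two_steps_give_endpoints(self):
        g = make_param_grid(t1_steps=2, t2_steps=2, delta_steps=2,
                            b1_steps=2)
        assert np.allclose(g.t1_values, [100, 2500])

    def test_log_midpoint(self):
        g = make_param_grid(t1_steps=3, t2_steps=2, delta_steps=2,
                            b1_steps=2)
        assert np.isclose(g.t1_values[1], 500.0)  # geometric mean

    def test_t2_exceeding_t1_excluded(self):
        g = make_param_grid(t1_range=(100, 400), t2_range=(50, 300),
                            t1_steps=4, t2_steps=4, delta_steps=2,
                            b1_steps=2)
        t1, t2, _, _ = g.thetas()
        assert np.all(t2 <= t1)
        assert g.n_atoms < 4 * 4 * 2 * 2

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            make_param_grid(t1_range=(2500, 100))


class TestBuildDictionary:
    def test_single_atom_equals_simulation(self, train12):
        g = make_param_grid(t1_range=(800, 801), t2_range=(80, 81),
                            delta_range=(0, 1), b1_range=(1, 1.01),
                            t1_steps=2, t2_steps=2, delta_steps=2,
                            b1_steps=2)
        d = build_dictionary(g, train12)
        t1, t2, dl, b1 = g.thetas()
        ref = simulate_si(TissueParams(1, 0, t1[0], t2[0], dl[0], b1[0]),
                          train12)
        assert np.allclose(d.atom_signals[:, 0], ref, atol=1e-6)

    def test_t1_distinguishability(self, train12):
        g = make_param_grid(t1_range=(500, 1000), t2_range=(80, 81),
                            delta_range=(0, 1), b1_range=(1, 1.01),
                            t1_steps=2, t2_steps=2, delta_steps=2,
                            b1_steps=2)
        d = build_dictionary(g, train12)
        cols = d.atom_signals / d.atom_norms
        i, j = 0, d.grid.atom_index[1, 0, 0, 0]
        corr = np.abs(np.vdot(cols[:, i], cols[:, j]))
        assert corr < 0.999

    def test_mu_interior_matches_si(self, train12):
        g = make_param_grid(t1_range=(600, 1200), t2_range=(60, 120),
                            delta_range=(0, 5), b1_range=(0.95, 1.05),
                            t1_steps=2, t2_steps=2, delta_steps=2,
                            b1_steps=2)
        ens = SlabEnsemble(n_subspins=32, n_zencodes=4)
        dmu = build_dictionary(g, train12, mode="mu", ensemble=ens)
        dsi = build_dictionary(g, train12, mode="si")
        rel = np.linalg.norm(dmu.atom_signals - dsi.atom_signals) \
            / np.linalg.norm(dsi.atom_signals)
        assert rel < 0.01

    def test_mu_requires_ensemble(self, train12):
        g = band_grid(t1_steps=2, t2_steps=2, b1_steps=2)
        with pytest.raises(ValueError):
            build_dictionary(g, train12, mode="mu")


class TestContrastSubspace:
    def test_single_atom_energy_is_one(self, train12):
        g = make_param_grid(t1_range=(800, 801), t2_range=(80, 81),
                            delta_range=(0, 1), b1_range=(1, 1.01),
                            t1_steps=2, t2_steps=2, delta_steps=2,
                            b1_steps=2)
        d = build_dictionary(g, train12)
        d.atom_signals = d.atom_signals[:, :1]
        d.atom_norms = d.atom_norms[:1]
        sub = compute_subspace(d, 1)
        assert np.isclose(sub.energy_fraction(1), 1.0)

    def test_known_singular_values(self, train12):
        # orthonormal columns scaled by 2 and 1: energy(1) = 4/5
        q, _ = np.linalg.qr(np.random.default_rng(0)
                            .standard_normal((48, 2)))
        d = SignalDictionary(atom_signals=(q * [2.0, 1.0]).astype(complex),
                             grid=None, train=train12)
        sub = compute_subspace(d, 2)
        assert np.allclose(sub.singular_values, [2.0, 1.0], atol=1e-10)
        assert np.isclose(sub.energy_fraction(1), 0.8)

    def test_energy_fraction_monotone_to_one(self, train12):
        g = band_grid(t1_steps=5, t2_steps=5, b1_steps=3)
        d = build_dictionary(g, train12)
        sub = compute_subspace(d, train12.n_contrasts)
        fr = [sub.energy_fraction(k)
              for k in range(1, train12.n_contrasts + 1)]
        assert np.all(np.diff(fr) >= -1e-12)
        assert np.isclose(fr[-1], 1.0, atol=1e-9)

    def test_orthonormal_basis(self, train12):
        g = band_grid(t1_steps=5, t2_steps=5, b1_steps=3)
        sub = compute_subspace(build_dictionary(g, train12), 12)
        G = sub.basis.conj().T @ sub.basis
        assert np.allclose(G, np.eye(12), atol=1e-8)
        assert np.all(np.diff(sub.singular_values) <= 1e-9)


class TestMatching:
    @pytest.fixture(scope="class")
    def dict_and_sub(self, train12):
        g = band_grid(t1_steps=10, t2_steps=10, delta_steps=7, b1_steps=3)
        d = build_dictionary(g, train12)
        return d, compute_subspace(d, 12)

    def test_grid_atom_round_trip(self, dict_and_sub, rng):
        # full-length metric: every atom matches itself exactly, and the
        # iterated refinement does not drift off the perfect-correlation
        # node
        d, _ = dict_and_sub
        cols = rng.integers(0, d.n_atoms, 25)
        y = d.atom_signals[:, cols].T.astype(complex) * (2 + 0j)
        res = match_dictionary(y, d, subspace=None, refine=True)
        assert np.array_equal(res["atom"], cols)
        t1g, t2g, _, _ = d.grid.thetas()
        assert np.allclose(res["t1"], t1g[cols], rtol=1e-9)
        assert np.allclose(res["t2"], t2g[cols], rtol=1e-9)
        assert np.allclose(res["i0"], 2.0, atol=1e-4)

    def test_compressed_search_stays_within_one_step(self, dict_and_sub,
                                                     rng):
        # the d1-compressed argmax may swap near-duplicate neighbors but
        # the returned parameters stay within one grid step
        d, sub = dict_and_sub
        cols = rng.integers(0, d.n_atoms, 25)
        y = d.atom_signals[:, cols].T.astype(complex)
        res = match_dictionary(y, d, subspace=sub, refine=False)
        t1g, t2g, _, _ = d.grid.thetas()
        step = np.log(d.grid.t1_values[1] / d.grid.t1_values[0])
        assert np.all(np.abs(np.log(res["t1"] / t1g[cols])) <= step + 1e-9)

    def test_scale_invariance(self, dict_and_sub, rng):
        d, sub = dict_and_sub
        y0 = d.atom_signals[:, 123].astype(complex)
        for alpha in (1.0, -2.5, 0.3 + 1.7j):
            res = match_dictionary((alpha * y0)[None], d, subspace=sub,
                                   refine=False)
            assert res["atom"][0] == 123
            assert np.isclose(res["i0"][0], alpha, atol=1e-4)

    def test_zero_voxel_flagged_invalid(self, dict_and_sub, train12):
        d, sub = dict_and_sub
        y = np.zeros((1, train12.n_contrasts), dtype=complex)
        res = match_dictionary(y, d, subspace=sub)
        assert not res["valid"][0]
        assert res["atom"][0] == -1
        assert np.isnan(res["t1"][0])

    def test_off_grid_recovery_within_quarter_step(self, train12):
        g = make_param_grid(
            delta_range=band_delta_range(30.0, 11), delta_steps=11,
            t1_steps=20, t2_steps=20, b1_steps=5)
        d = build_dictionary(g, train12)
        sub = compute_subspace(d, 12)
        # truth midway (log scale) between two t1 nodes
        t1_true = np.sqrt(g.t1_values[9] * g.t1_values[10])
        theta = TissueParams(1, 0, t1_true, 95.0, 4.0, 1.0)
        y = simulate_si(theta, train12)
        res = match_dictionary(y[None], d, subspace=sub)
        step = np.log(g.t1_values[10] / g.t1_values[9])
        err = abs(np.log(res["t1"][0] / t1_true))
        assert err < 0.25 * step

    def test_refinement_stays_in_grid_box(self, dict_and_sub, rng):
        d, _ = dict_and_sub
        g = d.grid
        y = (rng.standard_normal((5, 48))
             + 1j * rng.standard_normal((5, 48)))
        init = np.stack([np.full(5, g.t1_values[0]),
                         np.full(5, g.t2_values[0]),
                         np.full(5, g.delta_values[-1]),
                         np.full(5, g.b1_values[-1])], axis=1)
        out = refine_descent(d, y, init)
        assert np.all(out[:, 0] >= g.t1_values[0] - 1e-9)
        assert np.all(out[:, 0] <= g.t1_values[-1] + 1e-9)
        assert np.all(out[:, 3] >= g.b1_values[0] - 1e-9)
        assert np.all(out[:, 3] <= g.b1_values[-1] + 1e-9)


class TestInterpolateRefine:
    def test_symmetric_parabola_keeps_center(self):
        assert _parabola_offset(0.8, 1.0, 0.8) == 0.0

    def test_asymmetric_vertex_value(self):
        # closed form: 0.5 (sl - sr) / (sl - 2 sc + sr)
        off = _parabola_offset(0.6, 1.0, 0.9)
        assert np.isclose(off, 0.5 * (0.6 - 0.9) / (0.6 - 2.0 + 0.9))
        assert 0.0 < off < 0.5

    def test_degenerate_metric_keeps_grid_value(self):
        assert _parabola_offset(1.0, 1.0, 1.0) == 0.0

    def test_vertex_clamped_to_half_step(self):
        assert _parabola_offset(1.0, 1.0001, 1.0001 - 1e-9) <= 0.5

    def test_refine_on_exact_atom_stays_near_node(self, train12):
        # the single-pass parabola may shift the vertex slightly on a
        # coarse log grid (asymmetric neighbor metrics); it must stay
        # within the neighbor interval and preserve a near-perfect match
        g = make_param_grid(
            delta_range=band_delta_range(30.0, 7), delta_steps=7,
            t1_steps=8, t2_steps=8, b1_steps=3)
        d = build_dictionary(g, train12)
        atom = d.grid.atom_index[4, 4, 3, 1]
        y = d.atom_signals[:, atom].astype(complex)
        t1, t2, dl, b1, i0 = interpolate_refine(atom, d, y)
        assert g.t1_values[3] <= t1 <= g.t1_values[5]
        assert g.t2_values[3] <= t2 <= g.t2_values[5]
        assert np.isclose(abs(i0), 1.0, atol=0.1)


class TestStore:
    def test_h5_round_trip(self, train12, tmp_path):
        g = band_grid(t1_steps=3, t2_steps=3, b1_steps=2)
        d = build_dictionary(g, train12)
        path = tmp_path / "dict.h5"
        save_dictionary(path, d)
        back = load_dictionary_arrays(path)
        assert np.allclose(back["atom_signals"], d.atom_signals)
        assert np.allclose(back["t1_values"], g.t1_values)
        assert back["mode"] == "si"
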