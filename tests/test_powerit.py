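"""Power iteration, deflation, subspace collection, PCA, and perturbations."""

import numpy as np
import pytest
import scipy.linalg as sla

import kinmodes as km
from conftest import matrix_with_spectrum, random_stable_matrix


def leading_left_eigvec(J):
    w, V = sla.eig(J.T)
    i = int(np.argmax(np.abs(w)))
    v = V[:, i].real
    return w[i], v / np.linalg.norm(v)


class TestPowerIterate:
    def test_diagonal_closed_form(self):
        trace = km.power_iterate(np.diag([-5.0, -1.0]), u0=np.array([0.6, 0.8]))
        assert trace.converged
        assert np.abs(trace.final_vector) == pytest.approx([1.0, 0.0], abs=1e-6)
        assert trace.eigenvalue_magnitude == pytest.approx(5.0, rel=1e-9)
        assert trace.rayleigh == pytest.approx(-5.0, rel=1e-9)

    def test_matches_direct_solver_with_spectral_gap(self, rng):
        for _ in range(20):
            spectrum = -np.array([10.0, 4.0, *rng.uniform(0.1, 3.0, size=8)])
            J = matrix_with_spectrum(rng, spectrum)
            trace = km.power_iterate(J, seed=int(rng.integers(2**31)), max_iters=5000)
            lam, v = leading_left_eigvec(J)
            assert trace.converged
            assert abs(trace.final_vector @ v) >= 0.9999
            assert trace.eigenvalue_magnitude == pytest.approx(abs(lam), rel=1e-6)

    def test_dot_band_criterion_reported(self, rng):
        J = matrix_with_spectrum(rng, [-8.0, -2.0, -1.0])
        trace = km.power_iterate(J, seed=0)
        assert abs(abs(trace.final_dot) - 1.0) <= 1e-4
        assert trace.final_rel_change < 1e-12 * 10

    def test_null_space_start_reported_not_silent(self):
        J = np.array([[-1.0, 1.0], [1.0, -1.0]])
        trace = km.power_iterate(J, u0=np.array([1.0, 1.0]))
        assert trace.status == "null_vector"
        assert not trace.converged

    def test_complex_leading_pair_escalates_to_subspace(self):
        # rotation-dominated block: leading eigenpair is complex
        J = np.array(
            [[-1.0, 5.0, 0.0], [-5.0, -1.0, 0.0], [0.0, 0.0, -0.5]]
        )
        trace = km.power_iterate(J, seed=1, max_iters=200)
        assert trace.status == "complex_pair"
        lam = np.linalg.eigvals(J)
        want = lam[np.argmax(np.abs(lam))]
        got = trace.complex_pair[0]
        assert abs(abs(got) - abs(want)) <= 1e-6 * abs(want)

    def test_fixed_iteration_mode_runs_exactly_n(self, rng):
        J = random_stable_matrix(rng, m=5)
        trace = km.power_iterate(J, seed=3, n_iters=17)
        assert trace.n_iterations == 17
        assert trace.vectors.shape == (18, 5)


class TestHotellingDeflate:
    def test_diagonal_closed_form(self):
        J2 = km.hotelling_deflate(np.diag([-5.0, -1.0]), np.array([1.0, 0.0]))
        assert sorted(np.linalg.eigvals(J2).real) == pytest.approx([-1.0, 0.0])

    def test_exact_left_eigenvector_is_annihilated(self, rng):
        J = matrix_with_spectrum(rng, [-9.0, -3.0, -1.0, -0.5])
        lam, u = leading_left_eigvec(J)
        J2 = km.hotelling_deflate(J, u)
        assert np.linalg.norm(u @ J2) <= 1e-12 * np.linalg.norm(J)

    def test_remaining_spectrum_preserved(self, rng):
        for _ in range(10):
            spectrum = -np.array([12.0, *rng.uniform(0.2, 5.0, size=6)])
            J = matrix_with_spectrum(rng, spectrum)
            lam, u = leading_left_eigvec(J)
            J2 = km.hotelling_deflate(J, u)
            got = np.sort(np.linalg.eigvals(J2).real)
            want = np.sort(np.concatenate([spectrum[1:], [0.0]]))
            assert got == pytest.approx(want, abs=1e-6 * np.abs(spectrum).max())

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            km.hotelling_deflate(np.eye(2), np.zeros(2))


class TestDeflateUntilTimescale:
    def test_known_spectrum_walk(self):
        seq = km.deflate_until_timescale(
            np.diag([-100.0, -10.0, -1.0]), target_timescale=0.05, seed=0
        )
        assert seq.status == "reached"
        assert len(seq.steps) == 2
        assert seq.steps[-1].magnitude == pytest.approx(10.0, rel=1e-8)

    def test_fixture_walk_matches_direct_ordering(self, rng):
        spectrum = -np.array([50.0, 20.0, 8.0, 3.0, 1.0])
        J = matrix_with_spectrum(rng, spectrum)
        seq = km.deflate_until_timescale(J, target_timescale=1.0 / 3.0 * 0.999, seed=2)
        assert seq.status == "reached"
        got = np.array([s.eigenvalue for s in seq.steps])
        assert got == pytest.approx(spectrum[: len(got)], rel=1e-6)
        # every deflated vector is annihilated by its successor matrix
        assert all(s.annihilation_residual <= 1e-8 for s in seq.steps[:-1])

    def test_target_beyond_spectrum_exhausts_to_null_space(self):
        seq = km.deflate_until_timescale(
            np.diag([-4.0, -2.0]), target_timescale=1e6, seed=0
        )
        assert seq.status == "exhausted"
        assert len(seq.steps) == 2


class TestClusterSubspace:
    def test_near_degenerate_pair_spans_true_eigenspace(self, rng):
        """Two eigenvalues within 1% and the rest 10x smaller: the collected
        ending vectors span the true 2-dim left-eigenspace within 5 deg."""
        spectrum = -np.array([10.0, 9.95, *rng.uniform(0.2, 1.0, size=8)])
        J = matrix_with_spectrum(rng, spectrum)
        coll = km.cluster_subspace(J, n_starts=100, n_iters=100, seed=4)
        assert coll.dimension == 2
        w, V = sla.eig(J.T)
        order = np.argsort(-np.abs(w))
        truth = V[:, order[:2]].real.T
        angles = coll.principal_angles_to(truth)
        assert np.degrees(angles.max()) < 5.0

    def test_separated_leading_eigenvalue_collapses_to_one_direction(self, rng):
        J = matrix_with_spectrum(rng, [-10.0, -1.0, -0.8, -0.5])
        coll = km.cluster_subspace(J, n_starts=50, n_iters=100, seed=5)
        endings = coll.ending_vectors
        cos = np.abs(endings @ endings.T)
        assert cos.min() > 0.999

    def test_eigenvalue_estimates_settle_in_cluster_range(self, rng):
        spectrum = -np.array([10.0, 9.9, 9.8, *rng.uniform(0.2, 1.0, size=7)])
        J = matrix_with_spectrum(rng, spectrum)
        coll = km.cluster_subspace(J, n_starts=60, n_iters=100, seed=6)
        gap = 9.8 - 1.0
        lo, hi = 9.8 - gap * 0.5, 10.0 + gap * 0.5
        assert np.all(coll.eigenvalue_estimates >= lo)
        assert np.all(coll.eigenvalue_estimates <= hi)

    def test_collection_is_linearly_independent(self, rng):
        spectrum = -np.array([10.0, 9.9, 9.95, 1.0, 0.5, 0.2])
        J = matrix_with_spectrum(rng, spectrum)
        coll = km.cluster_subspace(J, n_starts=40, n_iters=100, seed=7)
        sv = np.linalg.svd(coll.basis, compute_uv=False)
        assert sv.min() > 1e-10 * sv.max()


class TestPCA:
    def test_identical_vectors_give_full_first_component(self):
        X = np.tile(np.array([0.6, 0.8]), (10, 1))
        pca = km.pca_iteration_vectors(X)
        assert pca.contributions[0] == pytest.approx(1.0)

    def test_isotropic_vectors_spread_contributions(self, rng):
        X = rng.standard_normal((4000, 5))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        pca = km.pca_iteration_vectors(X)
        assert pca.contributions.max() < 0.3  # near-uniform across 5 components

    def test_iteration_vectors_concentrate_on_leading_eigenvector(self, rng):
        J = matrix_with_spectrum(rng, [-10.0, -3.0, -1.0, -0.4])
        traces = [
            km.power_iterate(J, seed=s, max_iters=50) for s in range(40)
        ]
        pca = km.pca_iteration_vectors(traces)
        _, v = leading_left_eigvec(J)
        assert pca.contributions[0] > 0.5
        assert pca.alignment(v) > 0.99


class TestPerturbSubmatrix:
    def test_symmetric_block_has_equal_magnitude_entries(self):
        rep = km.perturb_submatrix(np.array([[-3.0, 1.0], [1.0, -3.0]]), edits=[])
        v = rep.vector_before
        assert abs(v[0]) == pytest.approx(abs(v[1]), abs=1e-12)

    def test_g6pdh_symmetrization_equalizes_mode_entries(self):
        """Copying (2,2) into (4,4) and symmetrizing (2,4)=(4,2) makes the
        leading eigenvector weights on the two forms equal to 1e-8, starting
        from an asymmetric regime with [NADPH] below K_d."""
        module = km.make_g6pdh_module(nadph=0.04)
        J = km.build_jacobian(module.network, module.state).J
        idx = [module.network.species_index(s) for s in km.G6PDH_KEY_FORMS]
        sub = J[np.ix_(idx, idx)]
        rep = km.perturb_submatrix(
            sub,
            edits=[(3, 3, sub[1, 1]), (1, 3, sub[3, 1])],
        )
        v = rep.vector_after
        assert abs(abs(v[1]) - abs(v[3])) <= 1e-8 * np.abs(v).max()

    def test_deepening_second_diagonal_shifts_weight_monotonically(self):
        """Moving (4,4) toward the deeper (2,2) diagonal monotonically
        decreases |v2|/|v4| ([NADPH] above K_d so (2,2) is the largest)."""
        module = km.make_g6pdh_module(nadph=0.09)
        J = km.build_jacobian(module.network, module.state).J
        idx = [module.network.species_index(s) for s in km.G6PDH_KEY_FORMS]
        sub = J[np.ix_(idx, idx)]
        ratios = []
        for frac in np.linspace(0.0, 1.0, 6):
            val = sub[3, 3] + frac * (sub[1, 1] - sub[3, 3])
            rep = km.perturb_submatrix(sub, edits=[(3, 3, val)])
            ratios.append(rep.element_ratio(1, 3))
        assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))
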