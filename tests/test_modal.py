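"""Modal decomposition: eigenvectors, timescales, truncation, classification."""

import math

import numpy as np
import pytest

import kinmodes as km
from conftest import random_stable_matrix


class TestEigendecompose:
    def test_conservation_pair(self):
        dec = km.eigendecompose(np.array([[-1.0, 1.0], [1.0, -1.0]]))
        assert sorted(dec.eigenvalues.real) == pytest.approx([-2.0, 0.0])
        assert dec.n_conservation == 1
        null_row = dec.modal_matrix[np.argmin(np.abs(dec.eigenvalues))]
        assert null_row.real == pytest.approx([1, 1] / np.sqrt(2))

    def test_diagonal_case_gives_unit_basis_rows(self):
        dec = km.eigendecompose(np.diag([-5.0, -1.0]))
        assert dec.eigenvalues.real == pytest.approx([-5.0, -1.0])
        assert np.abs(dec.modal_matrix) == pytest.approx(np.eye(2))

    def test_rowwise_residual_on_random_stable_matrices(self, rng):
        for _ in range(20):
            J = random_stable_matrix(rng, m=9)
            dec = km.eigendecompose(J)
            assert dec.residuals().max() <= 1e-8 * np.linalg.norm(J)

    def test_reconstruction_error_on_fixtures(self, pgi, g6pdh):
        for module in (pgi, g6pdh):
            J = km.build_jacobian(module.network, module.state).J
            dec = km.eigendecompose(J)
            assert dec.reconstruction_error() <= 1e-8

    def test_zero_modes_match_enzyme_moiety_count(self, pgi, g6pdh):
        """One zero eigenvalue per conserved pool (enzyme + closed metabolite)."""
        import scipy.linalg as sla

        for module in (pgi, g6pdh):
            J = km.build_jacobian(module.network, module.state).J
            dec = km.eigendecompose(J)
            assert dec.n_conservation == sla.null_space(J.T).shape[1]
            # the enzyme-total vector lies in the span of the null rows
            c = module.moiety_vector()
            null_rows = dec.modal_matrix[np.abs(dec.eigenvalues) == 0].real
            proj = null_rows.T @ np.linalg.lstsq(null_rows.T, c, rcond=None)[0]
            assert proj == pytest.approx(c, abs=1e-9 * np.abs(c).max())

    def test_sign_convention_largest_entry_positive(self, rng):
        J = random_stable_matrix(rng, m=6)
        dec = km.eigendecompose(J)
        for row in dec.modal_matrix:
            pivot = row[np.argmax(np.abs(row))]
            assert pivot.real > 0 and abs(pivot.imag) <= 1e-12 * abs(pivot)


class TestModeValue:
    def test_inner_product(self):
        u = np.array([1.0, 1.0]) / np.sqrt(2)
        assert km.mode_value(u, np.array([1.0, 2.0])) == pytest.approx(3 / np.sqrt(2))

    def test_orthogonal_deviation_gives_zero(self):
        assert km.mode_value(np.array([1.0, -1.0]), np.array([2.0, 2.0])) == 0.0

    def test_conservation_mode_constant_along_trajectory(self, pgi):
        J = km.build_jacobian(pgi.network, pgi.state).J
        dec = km.eigendecompose(J, species=pgi.network.species)
        traj = km.integrate(pgi.network, pgi.state, t_end=1e-4)
        null_idx = int(np.argmin(np.abs(dec.eigenvalues)))
        u = dec.modal_matrix[null_idx].real
        series = np.array([km.mode_value(u, x) for x in traj.X])
        assert np.abs(series - series[0]).max() <= 1e-6 * abs(series[0])


class TestTimescale:
    @pytest.mark.parametrize(
        "lam, expected",
        [(-2.0, 0.5), (-0.1, 10.0), (complex(-4, 3), 0.25)],
    )
    def test_negative_real_part(self, lam, expected):
        assert km.timescale(lam) == pytest.approx(expected)

    def test_zero_eigenvalue_is_infinite(self):
        assert math.isinf(km.timescale(0.0))

    def test_positive_eigenvalue_flags_instability(self):
        assert km.timescale(1.0) < 0


class TestTruncateMode:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [
            ((1.0, 0.04, 0.06), [0, 2]),
            ((1.0, 0.05), [0, 1]),  # tie at the threshold kept
            ((0.0, -2.0, 0.09), [1]),
        ],
    )
    def test_cutoff(self, coeffs, expected):
        assert km.truncate_mode(np.array(coeffs), cutoff=0.05) == expected

    def test_all_zero_mode_rejected(self):
        with pytest.raises(ValueError):
            km.truncate_mode(np.zeros(3))

    def test_g6pdh_complex_mode_support_lies_in_key_forms(self, g6pdh):
        """The fastest mode's support is contained in the four key enzyme
        forms, led by the release/bound pair tied by the near-equilibrium
        NADPH half reaction."""
        J = km.build_jacobian(g6pdh.network, g6pdh.state).J
        dec = km.eigendecompose(J, species=g6pdh.network.species)
        coeffs = dec.modal_matrix[0]
        support = {g6pdh.network.species[i] for i in km.truncate_mode(coeffs)}
        assert support <= set(km.G6PDH_KEY_FORMS)
        mags = np.abs(coeffs)
        top_two = {g6pdh.network.species[i] for i in np.argsort(mags)[-2:]}
        assert top_two == {"G6PDH&6PGL", "G6PDH&NADPH&6PGL"}


class TestClassification:
    def test_single_dominant_element_is_explained(self):
        # well-separated dominant rows: each mode truncates to one species
        J = np.array([[-100.0, 1.0, 0.0], [0.5, -10.0, 0.2], [0.0, 0.1, -1.0]])
        dec = km.eigendecompose(J)
        modes, summary = km.classify_dominance_modes(dec, J)
        assert summary.explained == 3 and summary.complex == 0
        assert all(len(m.support) == 1 for m in modes)

    def test_two_element_mode_failing_twice_rule_is_complex(self):
        """Coefficient ratio 1.5 between the top two elements fails the
        at-least-twice rule."""
        J = np.array([[-5.0, 4.9], [4.9, -5.0]])  # symmetric: modes (1,1),(1,-1)
        dec = km.eigendecompose(J)
        modes, summary = km.classify_dominance_modes(dec, J)
        assert all(m.classification == "complex" for m in modes)

    def test_shared_mode_with_dominant_leader_is_explained(self):
        # leader at least 2x the runner-up and most diagonally dominant
        J = np.array([[-10.0, 2.0], [0.5, -1.0]])
        dec = km.eigendecompose(J)
        modes, _ = km.classify_dominance_modes(dec, J)
        fast = min(modes, key=lambda m: m.eigenvalue.real)
        assert fast.classification == "explained"

    def test_conservation_modes_excluded_from_tally(self, pgi):
        J = km.build_jacobian(pgi.network, pgi.state).J
        dec = km.eigendecompose(J, species=pgi.network.species)
        modes, summary = km.classify_dominance_modes(dec, J)
        assert summary.conservation == 2  # enzyme pool + closed sugar pool
        assert summary.total_nonnull == 3
        assert summary.total == 5
        assert summary.explained_percentage_including_conservation < (
            summary.explained_percentage
        )

    def test_shared_mode_coefficient_ratio_tracks_dominant_row(self, rng):
        """For a weakly dominant row the coefficient ratio of the two shared
        species approximates the entry ratio in the dominant row of J."""
        a, b = 10.0, 4.0
        J = np.array([[-a, b], [0.05, -0.5]])
        dec = km.eigendecompose(J)
        fast = int(np.argmax(np.abs(dec.eigenvalues.real)))
        u = dec.modal_matrix[fast].real
        ratio_mode = abs(u[1] / u[0])
        ratio_row = abs(J[0, 1] / J[0, 0])
        assert ratio_mode == pytest.approx(ratio_row, rel=0.2)

    def test_strongly_dominant_row_gives_single_species_mode(self, rng):
        for _ in range(5):
            J = random_stable_matrix(rng, m=6, diag_scale=2.0)
            i = 2
            J[i] = 0.0
            J[i, i] = -50.0 * np.abs(J).max()
            J[i, (i + 1) % 6] = 0.02 * abs(J[i, i])  # f < 0.1, disc isolated
            dec = km.eigendecompose(J)
            modes, _ = km.classify_dominance_modes(dec, J)
            target = min(modes, key=lambda m: m.eigenvalue.real)
            assert target.support == [i]
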