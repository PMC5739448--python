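"""Diagonal fractions, Gershgorin discs, attribution, half reactions."""

import math

import numpy as np
import pytest

import kinmodes as km
from conftest import random_stable_matrix


class TestDiagonalFraction:
    @pytest.mark.parametrize(
        "row_matrix, row, expected",
        [
            (np.array([[-10.0, 1.0, 0.0], [0, 1, 0], [0, 0, 1]]), 0, 0.1),
            (np.array([[-1.0, 2.0], [0.0, 1.0]]), 0, 2.0),
            (np.diag([-3.0, -4.0]), 1, 0.0),
        ],
    )
    def test_values(self, row_matrix, row, expected):
        assert km.diagonal_fraction(row_matrix, row) == pytest.approx(expected)

    def test_zero_diagonal_flags_infinite(self):
        J = np.array([[0.0, 1.0], [1.0, -1.0]])
        assert math.isinf(km.diagonal_fraction(J, 0))

    def test_scaling_off_diagonals_down_shrinks_f_and_disc(self, rng):
        J = random_stable_matrix(rng, m=5)
        i = 1
        f0 = km.diagonal_fraction(J, i)
        r0 = km.gershgorin_discs(J)[i].radius
        Js = J.copy()
        Js[i, np.arange(5) != i] *= 0.4
        assert km.diagonal_fraction(Js, i) <= f0
        assert km.gershgorin_discs(Js)[i].radius <= r0


class TestGershgorinDiscs:
    def test_diagonal_matrix_has_point_discs(self):
        discs = km.gershgorin_discs(np.diag([-3.0, -1.0]))
        assert [d.radius for d in discs] == [0.0, 0.0]
        assert [d.contained_eigenvalues for d in discs] == [[0], [1]]

    def test_two_by_two_union_contains_both_eigenvalues(self):
        J = np.array([[-10.0, 1.0], [1.0, -2.0]])
        discs = km.gershgorin_discs(J)
        assert (discs[0].center, discs[0].radius) == (-10.0, 1.0)
        assert (discs[1].center, discs[1].radius) == (-2.0, 1.0)
        assert km.dominance.eigenvalues_in_disc_union(J)

    def test_containment_on_random_matrices(self, rng):
        for _ in range(50):
            J = rng.standard_normal((7, 7)) * 10 ** rng.uniform(-2, 2)
            assert km.dominance.eigenvalues_in_disc_union(J)

    def test_strong_row_disc_pins_an_eigenvalue(self, rng):
        """An isolated row with f < 0.1 localizes an eigenvalue within its
        disc radius of the diagonal element."""
        for _ in range(10):
            J = random_stable_matrix(rng, m=6)
            i = 3
            J[i] = 0.0
            J[i, i] = -40.0 * np.abs(J).max()
            J[i, 0] = 0.05 * abs(J[i, i])
            lam = np.linalg.eigvals(J)
            disc = km.gershgorin_discs(J, lam)[i]
            assert disc.strong
            assert disc.contained_eigenvalues  # at least one eigenvalue inside


class TestAttributeDiagonal:
    def test_bound_form_dominant_term_share(self, pgi):
        """k-_PGI1 dwarfs k+_PGI2 in the PGI&G6P diagonal at the fixture
        parameters, so the binding reaction carries >50% of the entry."""
        lin = km.build_jacobian(pgi.network, pgi.state)
        att = km.attribute_diagonal(lin, "PGI&G6P")
        assert att.reaction_id == "PGI1"
        assert att.share > 0.5

    def test_single_reaction_species_has_share_one(self, pgi):
        lin = km.build_jacobian(pgi.network, pgi.state)
        att = km.attribute_diagonal(lin, "PGI&F6P")
        # PGI&F6P participates in PGI2 and PGI3; with k-3 >> k-2 release wins
        assert att.share <= 1.0 + 1e-12
        net = km.ReactionNetwork(
            species=["A", "B"],
            reactions=[km.Reaction("iso", {"A": 1}, {"B": 1}, 2.0, 1.0)],
        )
        lin2 = km.build_jacobian(net, np.array([1.0, 1.0]))
        att2 = km.attribute_diagonal(lin2, "B")
        assert att2.reaction_id == "iso" and att2.share == pytest.approx(1.0)

    def test_tense_state_transition_dominates_its_diagonal(self):
        """An enzyme-state transition E <-> E_T with a huge reverse constant
        puts the transition's k- at the top of the E_T diagonal."""
        net = km.ReactionNetwork(
            species=["E", "E_T", "X", "E_T&X"],
            reactions=[
                km.Reaction("transition", {"E": 1}, {"E_T": 1}, 1.0e3, 1.0e8),
                km.Reaction("bind", {"E_T": 1, "X": 1}, {"E_T&X": 1}, 1.0e4, 1.0e2),
            ],
        )
        x = net.state_vector({"E": 1e-5, "E_T": 1e-7, "X": 1e-2, "E_T&X": 1e-8})
        lin = km.build_jacobian(net, x)
        att = km.attribute_diagonal(lin, "E_T")
        assert att.reaction_id == "transition"
        assert att.g_value == pytest.approx(-1.0e8)
        assert att.share > 0.99


class TestStabilityProbe:
    def test_diagonal_matrix_releases_zero_eigenvalue(self):
        probes = km.stability_probe(np.diag([-5.0, -1.0]))
        assert probes[0].largest_real_eigenvalue == pytest.approx(0.0)
        assert probes[0].replaced_diagonal == -5.0

    def test_dominant_row_releases_comparable_positive_eigenvalue(self, pgi):
        """Zeroing the dominant bound-form diagonal frees a positive
        eigenvalue within an order of magnitude of the removed entry: the
        mass-action column structure mirrors the diagonal's loss monomials
        as gains elsewhere in the column."""
        J = km.build_jacobian(pgi.network, pgi.state).J
        i = pgi.network.species_index("PGI&G6P")
        assert km.diagonal_fraction(J, i) < 1.0
        probe = km.stability_probe(J, species=pgi.network.species)[i]
        assert probe.largest_real_eigenvalue > 0
        assert 0.1 <= probe.magnitude_ratio <= 10.0

    def test_weak_row_zeroing_perturbs_spectrum_little(self, pgi):
        """Zeroing a non-dominant metabolite diagonal barely moves the
        spectrum on the scale of the fast eigenvalues."""
        J = km.build_jacobian(pgi.network, pgi.state).J
        i = pgi.network.species_index("G6P")
        assert km.diagonal_fraction(J, i) > 1.0
        probe = km.stability_probe(J)[i]
        fast = np.abs(np.linalg.eigvals(J)).max()
        assert abs(probe.largest_real_eigenvalue) <= 1e-3 * fast


class TestHalfReactions:
    def test_bilinear_at_kd_is_near_equilibrium(self):
        net = km.ReactionNetwork(
            species=["A", "E", "EA"],
            reactions=[km.Reaction("bind", {"A": 1, "E": 1}, {"EA": 1}, 2.0, 1.0)],
        )
        state = km.KineticState.at(net, {"A": 0.5, "E": 1e-4, "EA": 1e-4})
        halves = {h.fixed_species: h for h in km.half_reaction_ratios(net, state)}
        assert halves["A"].k_d == pytest.approx(0.5)
        assert halves["A"].ratio == pytest.approx(1.0)
        assert halves["A"].classification == "near"
        assert halves["E"].classification == "far"  # tiny enzyme pool

    def test_unimolecular_ratio_is_kplus_over_kminus(self):
        net = km.ReactionNetwork(
            species=["A", "B"],
            reactions=[km.Reaction("iso", {"A": 1}, {"B": 1}, 100.0, 1.0)],
        )
        (h,) = km.half_reaction_ratios(net, np.array([1.0, 1.0]))
        assert h.fixed_species is None
        assert h.ratio == pytest.approx(100.0)
        assert h.classification == "far"

    def test_irreversible_reaction_is_always_far(self):
        net = km.ReactionNetwork(
            species=["A", "B"],
            reactions=[km.Reaction("iso", {"A": 1}, {"B": 1}, 5.0, 0.0)],
        )
        (h,) = km.half_reaction_ratios(net, np.array([1.0, 1.0]))
        assert math.isinf(h.ratio) and h.classification == "far"

    def test_nadph_release_near_equilibrium_links_to_shared_mode(self, g6pdh):
        """At [NADPH] = K_eq of the release step, the NADPH half reaction is
        near equilibrium and the fastest mode shares the release/bound pair."""
        halves = km.half_reaction_ratios(g6pdh.network, g6pdh.state)
        nadph = [
            h for h in halves if h.reaction_id == "R6" and h.fixed_species == "NADPH"
        ][0]
        assert nadph.ratio == pytest.approx(1.0)
        assert nadph.classification == "near"
        J = km.build_jacobian(g6pdh.network, g6pdh.state).J
        dec = km.eigendecompose(J, species=g6pdh.network.species)
        support = {
            g6pdh.network.species[i] for i in km.truncate_mode(dec.modal_matrix[0])
        }
        assert {"G6PDH&6PGL", "G6PDH&NADPH&6PGL"} <= support

    def test_pgi_sweep_flips_mode_support_around_kd(self):
        """Sweeping [G6P] across K_d of the binding step moves the bound-form
        mode from single-species to shared support at the 5% cutoff; the
        flip happens within an order of magnitude of equilibrium."""
        module = km.make_pgi_module()
        net = module.network
        kd = 1.0e9 / 2.5e9
        target = net.species_index("PGI&G6P")
        supports = {}
        for ratio in 10.0 ** np.arange(-3.0, 2.0, 0.5):
            conc = dict(module.concentrations)
            conc["G6P"] = ratio * kd
            J = km.build_jacobian(net, net.state_vector(conc)).J
            dec = km.eigendecompose(J)
            candidates = [
                k
                for k in range(dec.n_modes)
                if dec.eigenvalues[k] != 0
                and np.argmax(np.abs(dec.modal_matrix[k])) == target
            ]
            k = max(candidates, key=lambda k: abs(dec.eigenvalues[k]))
            supports[ratio] = len(km.truncate_mode(dec.modal_matrix[k]))
        ratios = sorted(supports)
        assert supports[ratios[0]] == 1  # far below K_d: single species
        assert supports[ratios[-1]] >= 2  # at/above K_d: shared
        flip = next(r for r in ratios if supports[r] >= 2)
        assert 0.1 <= flip <= 10.0

    def test_g6pdh_release_form_mode_single_far_above_kd(self):
        """Raising [NADPH] well above K_d makes the release form strongly
        dominant: its mode collapses to a single species."""
        r6_kd = 6.0e6 / 1.0e8
        module = km.make_g6pdh_module(nadph=100.0 * r6_kd)
        net = module.network
        e2 = net.species_index("G6PDH&6PGL")
        J = km.build_jacobian(net, module.state).J
        dec = km.eigendecompose(J)
        k = max(
            (
                k
                for k in range(dec.n_modes)
                if dec.eigenvalues[k] != 0
                and np.argmax(np.abs(dec.modal_matrix[k])) == e2
            ),
            key=lambda k: abs(dec.eigenvalues[k]),
        )
        assert km.truncate_mode(dec.modal_matrix[k]) == [e2]
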