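"""Diagonal dominance, Gershgorin discs, and half-reaction equilibrium ratios.

The diagonal fraction of row i,

    f_i = sum_{k != i} |J_ik| / |J_ii|,

quantifies row diagonal dominance: f < 1 is dominant, f < 0.1 strongly so.
Each row also defines a Gershgorin disc centered at J_ii with radius equal
to the off-diagonal absolute sum; every eigenvalue of J lies in the union
of the discs, and an isolated disc from a strongly dominant row pins its
eigenvalue near the diagonal entry.

Only row dominance is computed: column dominance cannot occur in a
mass-action concentration Jacobian, because every diagonal entry's
monomials reappear with the same magnitude in the off-diagonal entries of
the same column (each consumed species' loss term is some other species'
gain term).

Half reactions arise from differentiating a bilinear mass-action rate law:
holding one reactant of A + E <-> EA constant splits the reaction into a
binding/release sub-process whose distance from equilibrium is the
concentration of the held species over its dissociation constant
K_d = k-/k+.  Rows whose dominant half reactions are far from equilibrium
produce simple (single-species) modes; half reactions near equilibrium tie
species together into shared modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import KineticState, Linearization, ReactionNetwork

STRONG_DOMINANCE_THRESHOLD = 0.1
DOMINANCE_THRESHOLD = 1.0
NEAR_EQUILIBRIUM_BAND = 10.0


def diagonal_fraction(J: np.ndarray, row: int) -> float:
    """Off-diagonal absolute row sum over |diagonal|; inf on a zero diagonal."""
    J = np.asarray(J)
    r = np.abs(J[row])
    off = r.sum() - r[row]
    if r[row] == 0.0:
        return math.inf if off > 0 else 0.0
    return float(off / r[row])


def all_diagonal_fractions(J: np.ndarray) -> np.ndarray:
    return np.array([diagonal_fraction(J, i) for i in range(np.asarray(J).shape[0])])


@dataclass
class GershgorinDisc:
    """Row disc |z - center| <= radius with its eigenvalue containments."""

    row: int
    center: float
    radius: float
    diagonal_fraction: float
    strong: bool
    contained_eigenvalues: list[int]
    species: str | None = None

    def contains(self, z: complex) -> bool:
        return abs(complex(z) - self.center) <= self.radius * (1 + 1e-12) + 1e-300


def gershgorin_discs(
    J: np.ndarray,
    eigenvalues: np.ndarray | None = None,
    species: list[str] | None = None,
    strong_threshold: float = STRONG_DOMINANCE_THRESHOLD,
) -> list[GershgorinDisc]:
    """One disc per row, with eigenvalue membership computed per disc.

    The circle theorem guarantees every eigenvalue lies in the union of the
    discs; individual membership is informative for isolated, strongly
    dominant rows where the disc pins a unique eigenvalue.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    if eigenvalues is None:
        eigenvalues = np.linalg.eigvals(J)
    discs = []
    for i in range(J.shape[0]):
        center = float(J[i, i])
        radius = float(np.abs(J[i]).sum() - abs(center))
        f = diagonal_fraction(J, i)
        contained = [
            int(k)
            for k, lam in enumerate(eigenvalues)
            if abs(lam - center) <= radius * (1 + 1e-12) + 1e-300
        ]
        discs.append(
            GershgorinDisc(
                row=i,
                center=center,
                radius=radius,
                diagonal_fraction=f,
                strong=f < strong_threshold,
                contained_eigenvalues=contained,
                species=species[i] if species is not None else None,
            )
        )
    return discs


def eigenvalues_in_disc_union(
    J: np.ndarray, eigenvalues: np.ndarray | None = None
) -> bool:
    """True iff every eigenvalue lies in the union of row discs (always, by theorem)."""
    if eigenvalues is None:
        eigenvalues = np.linalg.eigvals(np.asarray(J, float))
    discs = gershgorin_discs(J, eigenvalues)
    covered = set()
    for d in discs:
        covered.update(d.contained_eigenvalues)
    return len(covered) == len(eigenvalues)


@dataclass
class DiagonalAttribution:
    """The single G sensitivity that dominates a diagonal entry of J."""

    row: int
    species: str
    reaction_id: str
    g_value: float
    contribution: float  # S[i, r] * G[r, i]
    share: float  # |contribution| / |J_ii|
    found: bool = True


def attribute_diagonal(lin: Linearization, row: int | str) -> DiagonalAttribution:
    """Largest single-reaction contribution S[i,r] G[r,i] to J_ii.

    In mass-action Jacobians of real networks one sensitivity in G usually
    dominates the diagonal, tying the row's eigenvalue to one reaction.
    """
    net = lin.network
    i = net.species_index(row) if isinstance(row, str) else int(row)
    S = net.stoichiometric_matrix
    best_r, best_c = None, 0.0
    for r in range(net.n_reactions):
        c = S[i, r] * lin.G[r, i]
        if abs(c) > abs(best_c):
            best_r, best_c = r, c
    sp = net.species[i]
    if best_r is None or lin.J[i, i] == 0.0:
        return DiagonalAttribution(
            row=i, species=sp, reaction_id="", g_value=0.0, contribution=0.0,
            share=0.0, found=False,
        )
    return DiagonalAttribution(
        row=i,
        species=sp,
        reaction_id=net.reactions[best_r].id,
        g_value=float(lin.G[best_r, i]),
        contribution=float(best_c),
        share=float(abs(best_c) / abs(lin.J[i, i])),
    )


@dataclass
class StabilityProbeResult:
    """Spectral effect of zeroing one diagonal entry of J."""

    row: int
    replaced_diagonal: float
    largest_real_eigenvalue: float
    magnitude_ratio: float  # |largest positive eigenvalue| / |J_ii|
    species: str | None = None


def stability_probe(
    J: np.ndarray, species: list[str] | None = None
) -> list[StabilityProbeResult]:
    """Zero each diagonal entry in turn and record the largest Re(eigenvalue).

    Negative diagonals underpin the stability of mass-action steady states;
    for strongly dominant rows, removing the diagonal releases a positive
    eigenvalue on the order of the removed entry.
    """
    J = np.asarray(J, dtype=float)
    out = []
    for i in range(J.shape[0]):
        Jm = J.copy()
        Jm[i, i] = 0.0
        lam = np.linalg.eigvals(Jm)
        top = float(np.max(lam.real))
        diag = float(J[i, i])
        ratio = abs(top) / abs(diag) if diag != 0 else math.inf
        out.append(
            StabilityProbeResult(
                row=i,
                replaced_diagonal=diag,
                largest_real_eigenvalue=top,
                magnitude_ratio=ratio,
                species=species[i] if species is not None else None,
            )
        )
    return out


@dataclass
class HalfReaction:
    """A binding/release sub-process and its distance from equilibrium.

    ``fixed_species`` is the reactant held constant under differentiation
    (``None`` for single-reactant-each-side reactions, where the ratio is
    just k+/k-).  ``ratio`` is [fixed]/K_d; within ``NEAR_EQUILIBRIUM_BAND``
    of 1 the half reaction is classified near equilibrium.  ``gamma`` and
    ``k_eq`` describe the *full* reaction's mass-action ratio and
    equilibrium constant, reported for context.
    """

    reaction_id: str
    fixed_species: str | None
    varying_species: tuple[str, ...]
    k_d: float
    ratio: float
    classification: str  # "near" | "far"
    gamma: float
    k_eq: float


def _classify(ratio: float, theta: float) -> str:
    if theta <= 1:
        raise ValueError("near-equilibrium band must exceed 1")
    return "near" if (1.0 / theta) <= ratio <= theta else "far"


def half_reaction_ratios(
    network: ReactionNetwork,
    state: KineticState | np.ndarray,
    theta: float = NEAR_EQUILIBRIUM_BAND,
) -> list[HalfReaction]:
    """Distance from equilibrium of every half reaction at the given state.

    For each reaction side carrying at least two molecules, each species s
    on that side can be held fixed; its dissociation constant is
    k_release/k_bind (k-/k+ when s is bound in the forward direction, k+/k-
    when s is released forward) and the distance ratio is [s]/K_d.  A
    reaction with a single reactant on both sides yields one entry with
    ratio k+/k-.  Irreversible reactions (k- = 0) give infinite ratios:
    permanently far from equilibrium.
    """
    x = state.x if isinstance(state, KineticState) else np.asarray(state, float)
    out: list[HalfReaction] = []
    for rxn in network.reactions:
        conc = {sp: float(x[network.species_index(sp)]) for sp in rxn.species}
        num = math.prod(conc[s] ** p for s, p in rxn.products.items())
        den = math.prod(conc[s] ** p for s, p in rxn.substrates.items())
        gamma = num / den if den > 0 else math.inf
        k_eq = rxn.k_fwd / rxn.k_rev if rxn.k_rev > 0 else math.inf
        sub_count = sum(rxn.substrates.values())
        prod_count = sum(rxn.products.values())
        if sub_count <= 1 and prod_count <= 1:
            ratio = rxn.k_fwd / rxn.k_rev if rxn.k_rev > 0 else math.inf
            k_d = 1.0 / ratio if ratio not in (0.0, math.inf) else 0.0
            out.append(
                HalfReaction(
                    reaction_id=rxn.id,
                    fixed_species=None,
                    varying_species=tuple(sorted(rxn.species)),
                    k_d=k_d,
                    ratio=ratio,
                    classification=_classify(ratio, theta) if math.isfinite(ratio) else "far",
                    gamma=gamma,
                    k_eq=k_eq,
                )
            )
            continue
        for side, count, bind_k, release_k in (
            (rxn.substrates, sub_count, rxn.k_fwd, rxn.k_rev),
            (rxn.products, prod_count, rxn.k_rev, rxn.k_fwd),
        ):
            if count < 2:
                continue
            for sp in side:
                varying = tuple(sorted(rxn.species - {sp}))
                if bind_k > 0:
                    k_d = release_k / bind_k
                    ratio = conc[sp] / k_d if k_d > 0 else math.inf
                else:  # species only ever released: no binding direction
                    k_d, ratio = math.inf, 0.0
                out.append(
                    HalfReaction(
                        reaction_id=rxn.id,
                        fixed_species=sp,
                        varying_species=varying,
                        k_d=k_d,
                        ratio=ratio,
                        classification=(
                            _classify(ratio, theta) if math.isfinite(ratio) and ratio > 0 else "far"
                        ),
                        gamma=gamma,
                        k_eq=k_eq,
                    )
                )
    return out
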