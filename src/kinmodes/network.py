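"""Mass-action reaction networks and their linearization.

A network couples *m* species (metabolites and enzyme forms) through *n*
elementary mass-action reactions.  The concentration dynamics are

    dx/dt = S . v(x, k)

with ``S`` the m x n stoichiometric matrix and ``v`` the mass-action flux
vector.  Linearizing around a reference state ``x0`` gives the gradient
matrix ``G = dv/dx`` (the unscaled elasticity matrix) and the concentration
Jacobian ``J = S . G``, whose eigenstructure carries the timescale hierarchy
of the network.

Every nonzero entry of ``G`` and ``J`` is additionally attributed to the
symbolic monomials (rate constant times concentration factors) that sum to
it, so that dominance and half-reaction analyses can reason about *which*
kinetic term produced a matrix entry, not just its numeric value.

Units follow the red-blood-cell model convention: concentrations in mmol/L,
time in hours; rate constants carry the derived units (h^-1 per reaction
order in concentration).  Units are a convention here, not enforced
dimensional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class ModelDefinitionError(ValueError):
    """The model refers to species or parameters that are not defined."""


class ConcentrationError(ValueError):
    """A concentration is negative or otherwise outside the model domain."""


@dataclass(frozen=True)
class Reaction:
    """One reversible elementary mass-action reaction.

    ``substrates`` and ``products`` map species identifiers to positive
    integer stoichiometries.  ``k_fwd`` and ``k_rev`` are the forward and
    reverse rate constants; an irreversible step has ``k_rev == 0``.
    """

    id: str
    substrates: Mapping[str, int]
    products: Mapping[str, int]
    k_fwd: float
    k_rev: float = 0.0

    def __post_init__(self) -> None:
        if self.k_fwd < 0 or self.k_rev < 0:
            raise ModelDefinitionError(
                f"reaction {self.id!r}: rate constants must be nonnegative"
            )
        for side, name in ((self.substrates, "substrate"), (self.products, "product")):
            for sp, st in side.items():
                if int(st) != st or st <= 0:
                    raise ModelDefinitionError(
                        f"reaction {self.id!r}: {name} stoichiometry of {sp!r} "
                        f"must be a positive integer, got {st!r}"
                    )
        object.__setattr__(self, "substrates", dict(self.substrates))
        object.__setattr__(self, "products", dict(self.products))

    @property
    def species(self) -> set[str]:
        return set(self.substrates) | set(self.products)

    def net_stoichiometry(self, sp: str) -> int:
        return self.products.get(sp, 0) - self.substrates.get(sp, 0)


@dataclass
class ReactionNetwork:
    """An ordered species list plus an ordered list of mass-action reactions.

    Species order is the model-file order; every matrix and vector in the
    package indexes by it.  ``units`` is metadata only.
    """

    species: list[str]
    reactions: list[Reaction]
    name: str = "network"
    units: dict = field(
        default_factory=lambda: {"concentration": "mmol/L", "time": "h"}
    )

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ModelDefinitionError("duplicate species identifiers")
        known = set(self.species)
        for rxn in self.reactions:
            missing = rxn.species - known
            if missing:
                raise ModelDefinitionError(
                    f"reaction {rxn.id!r} references unknown species {sorted(missing)}"
                )
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ModelDefinitionError("duplicate reaction identifiers")
        self._index = {sp: i for i, sp in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, sp: str) -> int:
        try:
            return self._index[sp]
        except KeyError:
            raise ModelDefinitionError(f"unknown species {sp!r}") from None

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """Integer m x n matrix; column r is products minus substrates of r."""
        S = np.zeros((self.n_species, self.n_reactions), dtype=int)
        for r, rxn in enumerate(self.reactions):
            for sp, st in rxn.substrates.items():
                S[self._index[sp], r] -= st
            for sp, st in rxn.products.items():
                S[self._index[sp], r] += st
        return S

    def state_vector(self, concentrations: Mapping[str, float]) -> np.ndarray:
        """Order a species->concentration mapping into the model's vector."""
        missing = set(self.species) - set(concentrations)
        if missing:
            raise ModelDefinitionError(f"missing concentrations for {sorted(missing)}")
        return np.array([float(concentrations[sp]) for sp in self.species])

    def fluxes(self, x: Sequence[float]) -> np.ndarray:
        x = _as_concentrations(x, self.n_species)
        conc = {sp: x[i] for sp, i in self._index.items()}
        return np.array([mass_action_flux(r, conc) for r in self.reactions])

    def time_derivatives(self, x: Sequence[float]) -> np.ndarray:
        """Right-hand side S . v(x) of the mass balances."""
        return self.stoichiometric_matrix @ self.fluxes(x)

    def jacobian_values(self, x: Sequence[float]) -> np.ndarray:
        """Numeric J = S . G at ``x`` without term attribution (fast path)."""
        return self.stoichiometric_matrix.astype(float) @ gradient_values(self, x)


@dataclass
class KineticState:
    """A reference concentration vector together with its mass-balance residual.

    ``is_steady`` is set when ``||S . v(x)||`` does not exceed ``tolerance``.
    """

    x: np.ndarray
    residual: float
    is_steady: bool
    tolerance: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < 0):
            raise ConcentrationError("concentrations must be nonnegative")

    @classmethod
    def at(
        cls,
        network: ReactionNetwork,
        x: Sequence[float] | Mapping[str, float],
        tolerance: float | None = None,
    ) -> "KineticState":
        """Build a state for ``network``, computing the residual on the spot."""
        if isinstance(x, Mapping):
            x = network.state_vector(x)
        x = _as_concentrations(x, network.n_species)
        res = steady_state_residual(network, x)
        if tolerance is None:
            vmax = float(np.max(np.abs(network.fluxes(x)), initial=0.0))
            tolerance = 1e-9 * max(vmax, 1.0)
        return cls(x=x, residual=res, is_steady=res <= tolerance, tolerance=tolerance)

    def concentration(self, network: ReactionNetwork, sp: str) -> float:
        return float(self.x[network.species_index(sp)])


@dataclass(frozen=True)
class Term:
    """One monomial of a gradient or Jacobian entry.

    ``value == coefficient * k * prod(conc[sp] ** p for sp, p in factors)``
    where ``k`` is the rate constant named ``constant``.  ``coefficient``
    carries the sign (reverse-direction monomials are negative) and any
    stoichiometric multipliers.
    """

    constant: str
    reaction_id: str
    coefficient: float
    factors: tuple[tuple[str, int], ...]
    value: float

    def describe(self) -> str:
        parts = [f"{self.coefficient:g}*{self.constant}"]
        parts += [f"[{sp}]^{p}" if p != 1 else f"[{sp}]" for sp, p in self.factors]
        return "*".join(parts)


def _as_concentrations(x: Sequence[float], m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (m,):
        raise ModelDefinitionError(f"expected concentration vector of length {m}")
    if np.any(x < 0):
        raise ConcentrationError("concentrations must be nonnegative")
    return x


def _monomial(conc: Mapping[str, float], side: Mapping[str, int]) -> float:
    out = 1.0
    for sp, st in side.items():
        out *= conc[sp] ** st
    return out


def mass_action_flux(reaction: Reaction, concentrations: Mapping[str, float]) -> float:
    """Net mass-action flux k+ . prod(subs^stoich) - k- . prod(prods^stoich)."""
    for sp in reaction.species:
        if sp not in concentrations:
            raise ModelDefinitionError(
                f"reaction {reaction.id!r}: no concentration for species {sp!r}"
            )
        if concentrations[sp] < 0:
            raise ConcentrationError(
                f"negative concentration for {sp!r} in reaction {reaction.id!r}"
            )
    fwd = reaction.k_fwd * _monomial(concentrations, reaction.substrates)
    rev = reaction.k_rev * _monomial(concentrations, reaction.products)
    return fwd - rev


def steady_state_residual(network: ReactionNetwork, x: Sequence[float]) -> float:
    """Euclidean norm of S . v(x); zero exactly at a steady state."""
    return float(np.linalg.norm(network.time_derivatives(x)))


def _derivative_terms(
    rxn: Reaction, conc: Mapping[str, float], sp: str
) -> list[Term]:
    """Monomials of d(flux)/d[sp] for one reaction (0, 1, or 2 of them)."""
    terms: list[Term] = []
    if sp in rxn.substrates and rxn.k_fwd != 0.0:
        st = rxn.substrates[sp]
        factors = tuple(
            sorted(
                (s, p - (1 if s == sp else 0))
                for s, p in rxn.substrates.items()
                if p - (1 if s == sp else 0) > 0
            )
        )
        value = rxn.k_fwd * st
        for s, p in factors:
            value *= conc[s] ** p
        terms.append(
            Term(
                constant=f"k+_{rxn.id}",
                reaction_id=rxn.id,
                coefficient=float(st),
                factors=factors,
                value=value,
            )
        )
    if sp in rxn.products and rxn.k_rev != 0.0:
        st = rxn.products[sp]
        factors = tuple(
            sorted(
                (s, p - (1 if s == sp else 0))
                for s, p in rxn.products.items()
                if p - (1 if s == sp else 0) > 0
            )
        )
        value = -rxn.k_rev * st
        for s, p in factors:
            value *= conc[s] ** p
        terms.append(
            Term(
                constant=f"k-_{rxn.id}",
                reaction_id=rxn.id,
                coefficient=-float(st),
                factors=factors,
                value=value,
            )
        )
    return terms


def gradient_values(network: ReactionNetwork, x: Sequence[float]) -> np.ndarray:
    """Numeric n x m gradient matrix dv/dx without term bookkeeping."""
    x = _as_concentrations(x, network.n_species)
    conc = {sp: x[network.species_index(sp)] for sp in network.species}
    G = np.zeros((network.n_reactions, network.n_species))
    for r, rxn in enumerate(network.reactions):
        for sp in rxn.species:
            j = network.species_index(sp)
            G[r, j] = sum(t.value for t in _derivative_terms(rxn, conc, sp))
    return G


@dataclass
class Gradient:
    """The n x m flux-sensitivity matrix with per-entry monomial attribution."""

    network: ReactionNetwork
    x: np.ndarray
    G: np.ndarray
    terms: dict[tuple[int, int], list[Term]]

    def entry_terms(self, reaction_id: str, sp: str) -> list[Term]:
        r = [rx.id for rx in self.network.reactions].index(reaction_id)
        return self.terms.get((r, self.network.species_index(sp)), [])


@dataclass
class Linearization:
    """G, J = S . G, and the symbolic monomials behind every nonzero entry."""

    network: ReactionNetwork
    state: KineticState
    G: np.ndarray
    J: np.ndarray
    g_terms: dict[tuple[int, int], list[Term]]
    j_terms: dict[tuple[int, int], list[Term]]

    def jacobian_entry_terms(self, row_sp: str, col_sp: str) -> list[Term]:
        i = self.network.species_index(row_sp)
        j = self.network.species_index(col_sp)
        return self.j_terms.get((i, j), [])


def build_gradient(
    network: ReactionNetwork, state: KineticState | Sequence[float]
) -> Gradient:
    """Differentiate every mass-action rate law at the reference state.

    Each entry G[r, j] = dv_r/dx_j is the sum of at most two monomials: the
    forward-direction term (rate constant times the remaining substrate
    concentrations) and the negated reverse-direction term.  Entries for
    species not participating in reaction r are exactly zero.
    """
    x = state.x if isinstance(state, KineticState) else np.asarray(state, float)
    x = _as_concentrations(x, network.n_species)
    conc = {sp: x[network.species_index(sp)] for sp in network.species}
    G = np.zeros((network.n_reactions, network.n_species))
    terms: dict[tuple[int, int], list[Term]] = {}
    for r, rxn in enumerate(network.reactions):
        for sp in rxn.species:
            j = network.species_index(sp)
            ts = _derivative_terms(rxn, conc, sp)
            if ts:
                terms[(r, j)] = ts
                G[r, j] = sum(t.value for t in ts)
    return Gradient(network=network, x=x, G=G, terms=terms)


def build_jacobian(
    network: ReactionNetwork, state: KineticState | Sequence[float]
) -> Linearization:
    """Assemble J = S . G with stoichiometry-weighted term attribution.

    The monomials of J[i, j] are the union over reactions r of the G[r, j]
    monomials scaled by the (integer) stoichiometric coefficient S[i, r].
    """
    if not isinstance(state, KineticState):
        state = KineticState.at(network, state)
    grad = build_gradient(network, state)
    S = network.stoichiometric_matrix
    J = S.astype(float) @ grad.G
    j_terms: dict[tuple[int, int], list[Term]] = {}
    for (r, j), ts in grad.terms.items():
        col = S[:, r]
        for i in np.nonzero(col)[0]:
            w = int(col[i])
            scaled = [
                Term(
                    constant=t.constant,
                    reaction_id=t.reaction_id,
                    coefficient=w * t.coefficient,
                    factors=t.factors,
                    value=w * t.value,
                )
                for t in ts
            ]
            j_terms.setdefault((int(i), j), []).extend(scaled)
    return Linearization(
        network=network, state=state, G=grad.G, J=J, g_terms=grad.terms, j_terms=j_terms
    )


def conserved_moieties(network: ReactionNetwork) -> np.ndarray:
    """Integer-friendly basis of the left null space of S (moiety vectors).

    Rows are vectors ``c`` with ``c . S == 0``; for enzyme modules these are
    the total-enzyme conservation sums.  Computed exactly over the rationals.
    """
    import sympy

    S = sympy.Matrix(network.stoichiometric_matrix)
    null = S.T.nullspace()
    if not null:
        return np.zeros((0, network.n_species))
    rows = []
    for vec in null:
        denom = sympy.lcm([sympy.fraction(v)[1] for v in vec])
        vec = vec * denom
        g = sympy.gcd([v for v in vec if v != 0])
        if g not in (0, 1):
            vec = vec / g
        if sum(vec) < 0:
            vec = -vec
        rows.append([float(v) for v in vec])
    return np.array(rows)


def finite_difference_gradient(
    network: ReactionNetwork,
    x: Sequence[float],
    rel_step: float = 1e-6,
    abs_floor: float = 1e-12,
) -> np.ndarray:
    """Central-difference dv/dx oracle (step 1e-6 relative, floor 1e-12)."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    G = np.zeros((network.n_reactions, m))
    for j in range(m):
        h = max(rel_step * abs(x[j]), abs_floor)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        G[:, j] = (network.fluxes(xp) - network.fluxes(xm)) / (xp[j] - xm[j])
    return G


def finite_difference_jacobian(
    network: ReactionNetwork,
    x: Sequence[float],
    rel_step: float = 1e-6,
    abs_floor: float = 1e-12,
) -> np.ndarray:
    """Central-difference Jacobian of S . v, the oracle for ``build_jacobian``."""
    return network.stoichiometric_matrix.astype(float) @ finite_difference_gradient(
        network, x, rel_step, abs_floor
    )
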