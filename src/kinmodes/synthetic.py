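"""Synthetic enzyme-module networks with realistic kinetic scaling.

Enzyme modules represent one catalytic cycle as explicit elementary steps
(substrate binding, catalytic conversion, product release), each an
elementary mass-action reaction, with the total enzyme concentration
conserved as a moiety.  The generators here emulate the statistical
structure of whole-cell kinetic models of erythrocyte metabolism:
metabolite concentrations and rate constants spanning many orders of
magnitude, and enzyme totals several orders of magnitude below metabolite
pools.  Two named fixtures reproduce the glucose-6-phosphate isomerase
(PGI) and glucose-6-phosphate dehydrogenase (G6PDH) module topologies used
throughout the analysis modules.

Units: mmol/L and hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    KineticState,
    ModelDefinitionError,
    Reaction,
    ReactionNetwork,
    _monomial,
    steady_state_residual,
)


class SteadyStateError(RuntimeError):
    """The integrator did not reach the steady-state tolerance in budget."""


@dataclass
class EnzymeModule:
    """A mass-action enzyme mechanism plus its reference concentrations.

    ``enzyme_forms`` lists the free and bound forms whose sum is the
    conserved enzyme total; ``step_kinds`` labels each reaction as binding /
    catalysis / release / regulatory.
    """

    name: str
    network: ReactionNetwork
    concentrations: dict[str, float]
    enzyme_forms: list[str]
    metabolites: list[str]
    step_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def state(self) -> KineticState:
        return KineticState.at(self.network, self.concentrations)

    @property
    def total_enzyme(self) -> float:
        return float(sum(self.concentrations[f] for f in self.enzyme_forms))

    def moiety_vector(self) -> np.ndarray:
        """Indicator vector of the enzyme moiety (1 on each enzyme form)."""
        v = np.zeros(self.network.n_species)
        for f in self.enzyme_forms:
            v[self.network.species_index(f)] = 1.0
        return v


def make_pgi_module(
    g6p: float = 0.05,
    f6p: float = 0.02,
    enzyme_total: float = 1e-5,
    k_binding: tuple[float, float] = (2.5e9, 1.0e9),
    k_catalysis: tuple[float, float] = (1.0e6, 1.0e5),
    k_release: tuple[float, float] = (1.0e8, 1.0e9),
) -> EnzymeModule:
    """Three-step glucose-6-phosphate isomerase module.

    PGI1 binds G6P (G6P + PGI <-> PGI&G6P), PGI2 isomerizes the bound sugar
    (PGI&G6P <-> PGI&F6P), PGI3 releases F6P (PGI&F6P <-> PGI + F6P).  The
    defaults put the G6P binding half reaction below its dissociation
    constant (K_d = 0.4 mmol/L) and make the catalytic step strongly
    forward, which is the regime in which the bound-form row of J is
    diagonally dominant.  Enzyme forms sit several orders of magnitude
    below the sugar pools.
    """
    for v in (g6p, f6p, enzyme_total, *k_binding, *k_catalysis, *k_release):
        if v < 0:
            raise ModelDefinitionError("module parameters must be nonnegative")
    species = ["G6P", "F6P", "PGI", "PGI&G6P", "PGI&F6P"]
    reactions = [
        Reaction("PGI1", {"G6P": 1, "PGI": 1}, {"PGI&G6P": 1}, *k_binding),
        Reaction("PGI2", {"PGI&G6P": 1}, {"PGI&F6P": 1}, *k_catalysis),
        Reaction("PGI3", {"PGI&F6P": 1}, {"PGI": 1, "F6P": 1}, *k_release),
    ]
    network = ReactionNetwork(species=species, reactions=reactions, name="PGI_module")
    conc = {
        "G6P": g6p,
        "F6P": f6p,
        "PGI": 0.60 * enzyme_total,
        "PGI&G6P": 0.25 * enzyme_total,
        "PGI&F6P": 0.15 * enzyme_total,
    }
    return EnzymeModule(
        name="PGI",
        network=network,
        concentrations=conc,
        enzyme_forms=["PGI", "PGI&G6P", "PGI&F6P"],
        metabolites=["G6P", "F6P"],
        step_kinds={"PGI1": "binding", "PGI2": "catalysis", "PGI3": "release"},
    )


#: Fig-5 ordering of the four G6PDH enzyme forms spanning the complex mode.
G6PDH_KEY_FORMS = [
    "G6PDH",
    "G6PDH&6PGL",
    "G6PDH&NADP&G6P",
    "G6PDH&NADPH&6PGL",
]


def make_g6pdh_module(
    nadph: float = 0.06,
    g6p: float = 0.05,
    nadp: float = 0.002,
    pgl: float = 0.002,
    enzyme_total: float = 1e-5,
) -> EnzymeModule:
    """Seven-step glucose-6-phosphate dehydrogenase module.

    The catalytic cycle is ordered binding of NADP (R1) then G6P (R2),
    essentially irreversible oxidation R7 (G6PDH&NADP&G6P -> G6PDH&NADPH&6PGL),
    NADPH release R6 (G6PDH&NADPH&6PGL <-> G6PDH&6PGL + NADPH), and 6PGL
    release R4 back to free enzyme.  R3 and R5 are dead-end regulatory
    bindings of G6P and NADPH to the free enzyme.

    The default NADPH concentration equals the dissociation constant of the
    NADPH release half reaction (K_d,R6 = k+6/k-6 = 0.06 mmol/L), the
    near-equilibrium regime in which the release (G6PDH&6PGL) and bound
    (G6PDH&NADPH&6PGL) forms share a mode: the four largest Jacobian
    entries over the key enzyme forms sit at the symmetric (2,2), (2,4),
    (4,2), (4,4) block.
    """
    for v in (nadph, g6p, nadp, pgl, enzyme_total):
        if v < 0:
            raise ModelDefinitionError("module parameters must be nonnegative")
    species = [
        "G6P",
        "NADP",
        "NADPH",
        "6PGL",
        "G6PDH",
        "G6PDH&6PGL",
        "G6PDH&NADP&G6P",
        "G6PDH&NADPH&6PGL",
        "G6PDH&NADP",
        "G6PDH&G6P",
        "G6PDH&NADPH",
    ]
    reactions = [
        Reaction("R1", {"G6PDH": 1, "NADP": 1}, {"G6PDH&NADP": 1}, 1.0e9, 1.0e6),
        Reaction("R2", {"G6PDH&NADP": 1, "G6P": 1}, {"G6PDH&NADP&G6P": 1}, 2.0e7, 1.0e6),
        Reaction("R3", {"G6PDH": 1, "G6P": 1}, {"G6PDH&G6P": 1}, 1.0e7, 1.0e6),
        Reaction("R4", {"G6PDH&6PGL": 1}, {"G6PDH": 1, "6PGL": 1}, 5.0e1, 1.0e6),
        Reaction("R5", {"G6PDH": 1, "NADPH": 1}, {"G6PDH&NADPH": 1}, 1.0e7, 1.0e6),
        Reaction(
            "R6", {"G6PDH&NADPH&6PGL": 1}, {"G6PDH&6PGL": 1, "NADPH": 1}, 6.0e6, 1.0e8
        ),
        Reaction(
            "R7", {"G6PDH&NADP&G6P": 1}, {"G6PDH&NADPH&6PGL": 1}, 2.0e6, 1.0e-2
        ),
    ]
    network = ReactionNetwork(species=species, reactions=reactions, name="G6PDH_module")
    conc = {
        "G6P": g6p,
        "NADP": nadp,
        "NADPH": nadph,
        "6PGL": pgl,
        "G6PDH": 0.20 * enzyme_total,
        "G6PDH&6PGL": 0.30 * enzyme_total,
        "G6PDH&NADP&G6P": 0.20 * enzyme_total,
        "G6PDH&NADPH&6PGL": 0.20 * enzyme_total,
        "G6PDH&NADP": 0.04 * enzyme_total,
        "G6PDH&G6P": 0.03 * enzyme_total,
        "G6PDH&NADPH": 0.03 * enzyme_total,
    }
    return EnzymeModule(
        name="G6PDH",
        network=network,
        concentrations=conc,
        enzyme_forms=[
            "G6PDH",
            "G6PDH&6PGL",
            "G6PDH&NADP&G6P",
            "G6PDH&NADPH&6PGL",
            "G6PDH&NADP",
            "G6PDH&G6P",
            "G6PDH&NADPH",
        ],
        metabolites=["G6P", "NADP", "NADPH", "6PGL"],
        step_kinds={
            "R1": "binding",
            "R2": "binding",
            "R3": "regulatory",
            "R4": "release",
            "R5": "regulatory",
            "R6": "release",
            "R7": "catalysis",
        },
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random enzyme-network generator.

    Ranges are (low, high) and sampled log-uniformly.  ``fraction_near``
    controls the share of binding/conversion half reactions whose distance
    ratio is forced to within half a decade of equilibrium; the remainder
    are forced 1-4 decades away (the direction that favors diagonal
    dominance of the bound-form rows).  Identical seeds reproduce identical
    networks bit-for-bit.
    """

    seed: int = 0
    n_modules: int = 6
    metabolite_range: tuple[float, float] = (1e-5, 1e1)
    enzyme_total_range: tuple[float, float] = (1e-7, 1e-4)
    rate_exponent_range: tuple[float, float] = (6.0, 10.0)
    fraction_near: float = 0.25
    include_atp: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (
            self.metabolite_range,
            self.enzyme_total_range,
        ):
            if not (0 < lo < hi):
                raise ModelDefinitionError("ranges must be positive and ordered")
        if self.rate_exponent_range[0] >= self.rate_exponent_range[1]:
            raise ModelDefinitionError("rate exponent range must be ordered")
        if not 0 <= self.fraction_near <= 1:
            raise ModelDefinitionError("fraction_near must lie in [0, 1]")
        if self.n_modules < 1:
            raise ModelDefinitionError("need at least one module")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def random_enzyme_network(
    config: GeneratorConfig,
) -> tuple[ReactionNetwork, KineticState]:
    """Connected set of three-step enzyme modules over shared metabolite pools.

    Module i converts pool M{i mod p} to M{(i+1) mod p} (p about half the
    module count) through binding, catalysis and release steps, so several
    enzymes compete for each pool and the network is connected.  Binding
    dissociation constants are placed near or far from the pool
    concentration according to ``fraction_near``, which is what makes
    diagonal fractions of the generated Jacobians span many orders of
    magnitude.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_modules
    n_pools = max(2, round(n / 2))  # shared pools keep enzyme-form rows in the majority
    metabolites = [f"M{i}" for i in range(n_pools)]
    met_conc = {
        m: _log_uniform(rng, *config.metabolite_range) for m in metabolites
    }
    species: list[str] = list(metabolites)
    reactions: list[Reaction] = []
    conc: dict[str, float] = dict(met_conc)
    elo, ehi = config.rate_exponent_range

    def draw_distance() -> float:
        """10^delta placing a half reaction near (|delta| < 0.5) or far
        (1-4 decades, the dominance-favoring direction) from equilibrium."""
        if rng.uniform() < config.fraction_near:
            return 10.0 ** rng.uniform(-0.5, 0.5)
        return 10.0 ** rng.uniform(1.0, 4.0)

    for i in range(n):
        enz = f"E{i}"
        sub, prod = metabolites[i % n_pools], metabolites[(i + 1) % n_pools]
        bound_s, bound_p = f"{enz}&{sub}", f"{enz}&{prod}"
        species += [enz, bound_s, bound_p]
        total = _log_uniform(rng, *config.enzyme_total_range)
        fracs = rng.dirichlet(np.ones(3))
        conc[enz], conc[bound_s], conc[bound_p] = (float(f * total) for f in fracs)

        # unbinding rates drawn directly (fast, diffusion-limited scale);
        # binding rates follow from the targeted K_d distance.
        k_off = 10 ** rng.uniform(elo, ehi)
        k_on = k_off / (met_conc[sub] * draw_distance())
        reactions.append(
            Reaction(f"{enz}_bind", {sub: 1, enz: 1}, {bound_s: 1}, k_on, k_off)
        )
        k_cat = 10 ** rng.uniform(elo - 3.0, ehi - 3.0)
        if rng.uniform() < config.fraction_near:
            k_cat_rev = k_cat * 10 ** rng.uniform(-0.5, 0.5)
        else:
            k_cat_rev = k_cat * 10 ** rng.uniform(-4.0, -1.0)
        reactions.append(
            Reaction(f"{enz}_cat", {bound_s: 1}, {bound_p: 1}, k_cat, k_cat_rev)
        )
        k_rel = 10 ** rng.uniform(elo, ehi)
        k_rel_rev = k_rel / (met_conc[prod] * draw_distance())
        reactions.append(
            Reaction(f"{enz}_rel", {bound_p: 1}, {enz: 1, prod: 1}, k_rel, k_rel_rev)
        )

    if config.include_atp:
        species += ["ATP", "ADP", "Pi"]
        conc.update({"ATP": 1.6, "ADP": 0.3, "Pi": 2.5})
        reactions.append(
            Reaction("ATP_hydrolysis", {"ATP": 1}, {"ADP": 1, "Pi": 1}, 1e2, 1e0)
        )

    network = ReactionNetwork(
        species=species, reactions=reactions, name=f"synthetic_{config.seed}"
    )
    return network, KineticState.at(network, conc)


def find_steady_state(
    network: ReactionNetwork,
    x_init: np.ndarray | KineticState,
    tol_factor: float = 1e-9,
    t_max: float = 1e6,
    rtol: float = 1e-10,
) -> KineticState:
    """Relax the stiff mass-balance ODEs to steady state.

    Integrates ``dx/dt = S v`` with a BDF method (analytic Jacobian supplied)
    over geometrically growing horizons up to ``t_max`` time units, stopping
    as soon as ``||S v||`` falls below ``tol_factor`` times the gross
    (one-way) flux scale — the net fluxes cancel at equilibrium, so the
    one-way scale is the meaningful yardstick.  The returned state
    conserves every moiety of the initial condition (a property of the exact
    dynamics that the integrator preserves to its tolerance).  Raises
    :class:`SteadyStateError` with the final residual on failure.
    """
    x = x_init.x.copy() if isinstance(x_init, KineticState) else np.array(x_init, float)
    if np.any(x < 0):
        raise ModelDefinitionError("initial concentrations must be nonnegative")

    def tol_of(xv: np.ndarray) -> float:
        # gross (one-way) flux scale: stays finite at equilibrium, where the
        # net fluxes the residual measures cancel to zero
        conc = {sp: xv[network.species_index(sp)] for sp in network.species}
        gross = max(
            (
                rxn.k_fwd * _monomial(conc, rxn.substrates)
                + rxn.k_rev * _monomial(conc, rxn.products)
                for rxn in network.reactions
            ),
            default=0.0,
        )
        return tol_factor * max(gross, 1e-300)

    res = steady_state_residual(network, x)
    if res <= tol_of(x):
        return KineticState(x=x, residual=res, is_steady=True, tolerance=tol_of(x))

    rhs = lambda t, xv: network.time_derivatives(np.maximum(xv, 0.0))
    jac = lambda t, xv: network.jacobian_values(np.maximum(xv, 0.0))
    atol = max(1e-14 * float(np.max(x, initial=1.0)), 1e-300)
    t_reached = 0.0
    for t_end in np.geomspace(1e-8, t_max, 15):
        if t_end <= t_reached:
            continue
        sol = solve_ivp(
            rhs,
            (t_reached, t_end),
            x,
            method="BDF",
            jac=jac,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SteadyStateError(
                f"integration failed at t={t_reached:g}: {sol.message}"
            )
        x = np.maximum(sol.y[:, -1], 0.0)
        t_reached = t_end
        res = steady_state_residual(network, x)
        if res <= tol_of(x):
            return KineticState(
                x=x, residual=res, is_steady=True, tolerance=tol_of(x)
            )
    raise SteadyStateError(
        f"no steady state within t={t_max:g}; final residual {res:.3e} "
        f"(tolerance {tol_of(x):.3e})"
    )
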