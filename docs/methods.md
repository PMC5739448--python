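# Methods

## Model class and linearization

The package treats strictly elementary mass-action networks: each reaction
is a reversible pair with rate constants k⁺/k⁻ (irreversible means
k⁻ = 0), flux v = k⁺·∏[substrates]^σ − k⁻·∏[products]^π.  Approximate rate
laws are out of scope; the SBML reader accepts only kinetic laws that are a
single difference (or single product) of rate-constant-times-concentration
monomials whose powers match the declared stoichiometry, and rejects
anything else rather than approximating it.  Units follow the
red-blood-cell modeling convention — concentrations in mmol/L, time in
hours, rate constants in the derived units — and are metadata, not
enforced dimensional analysis.  The SBML reader records the file's declared
time unit and defaults to hours when none is declared.

The gradient matrix G = dv/dx is assembled analytically, one or two
monomials per entry.  Every monomial is stored symbolically (rate-constant
name, concentration factors, signed coefficient), and J = S·G inherits the
stoichiometry-weighted union of those monomials, so dominance and
half-reaction analyses can name the kinetic term behind any matrix entry.
The finite-difference oracle used in tests steps 1e−6 relative with an
absolute floor of 1e−12.

## Modal decomposition

Left eigenvectors are computed by a dense eigensolve of Jᵀ.  Eigenvalues
whose magnitude falls below 1e−10·‖J‖ are identified with the left null
space: those rows are replaced by an orthonormal basis of null(Jᵀ)
(moiety-conservation sums) and assigned exactly zero eigenvalues, making
the modal matrix full rank.  Rows are normalized to unit Euclidean norm
with the largest-magnitude entry rotated positive real — the underlying
convention is arbitrary, so one is fixed for reproducible reports.
Defective inputs are flagged through the modal-matrix condition number
(threshold 1e12) but still returned.  Near-degenerate eigenvalues
(relative gap below 1e−6) are tagged with a shared cluster id rather than
individually interpreted.

Mode truncation keeps coefficients with |c| ≥ 5% of the mode's maximum
(ties kept).  A non-conservation mode is *explained by diagonal dominance*
when (a) a single species survives truncation and its row has diagonal
fraction f < 1, or (b) several survive but the largest coefficient is at
least twice the runner-up and belongs to the support's most dominant
(smallest-f) species, itself with f < 1.  Conservation modes are excluded
from the explained/complex tally; because that counting convention is a
choice, summaries report the tally both with and without the λ = 0 rows.
Complex eigenvalues are classified through coefficient magnitudes.

## Dominance and half reactions

Only row dominance is computed: in a mass-action concentration Jacobian the
monomials of each diagonal entry reappear with equal magnitude elsewhere in
the same column (one species' loss is another's gain), so strict column
dominance cannot occur.  The dominance thresholds (f < 1 dominant,
f < 0.1 strong) are configurable constants.  Eigenvalue–disc containment
uses the complex modulus |λ − J_ii| ≤ radius.

Half-reaction entries are generated for every species sitting on a
reaction side carrying at least two molecules: the dissociation constant
is k_release/k_bind for that species (k⁻/k⁺ for a forward-bound substrate,
k⁺/k⁻ for a forward-released product), and the distance ratio is
[species]/K_d.  Reactions with one reactant on each side get a single
entry with ratio k⁺/k⁻.  The near-equilibrium band is one order of
magnitude (ratio within [0.1, 10]); the band is a documented, configurable
choice — "similar in magnitude" has no canonical number.  The full
reaction's mass-action ratio Γ and K_eq are reported alongside for
context.

## Power iteration and deflation

Iteration is on the left: u ← u·J/‖u·J‖, with ‖u·J‖ as the eigenvalue
magnitude estimate and a Rayleigh quotient for the sign.  Two stopping
criteria exist in the literature of this construction — norm convergence
and a successive-dot-product band (|⟨u_{i+1}, u_i⟩| within 1e−4 of 1) —
and both are implemented, AND-combined by default, each selectable.  The
absolute value of the dot product is used because a negative leading
eigenvalue flips the iterate's sign each step.  A run that lands in the
null space is reported as such; persistent non-convergence of the dot
product triggers escalation to a two-dimensional real invariant-subspace
estimate (QR of the last two iterates, projected 2×2 eigenproblem) for
complex leading pairs.

Hotelling deflation uses the projector form J − uᵀ(u·J)/(u·uᵀ), which
annihilates u exactly even when u is only approximate; the classical
λ-form is available as an option.  The deflation walk records each
converged eigenpair and stops once the magnitude timescale 1/|λ| of the
current leading estimate reaches the target.  Deflation error is tracked
two ways: the residual of each recorded pair against the *original* J
(which grows for later steps, because deflation removes each left
eigenvector's component along its predecessors) and the annihilation
residual ‖u·J_{t+1}‖/‖J‖ against the successor matrix (which must stay at
solver precision).  Exhaustion of the spectrum is declared structurally —
when as many eigenpairs as J's numerical rank (singular values above
1e−10 of the largest) have been recorded — because residual deflation
error of order √tol·‖J‖ makes a norm test unable to distinguish a spent
matrix from a genuinely small trailing eigenvalue.

For clustered eigenvalues, 100 random starts are each run exactly 100
iterations (no early stop) and the ending vectors are swept in order,
keeping a vector only if it raises the numerical rank of the collection at
tolerance 1e−10; the collected span is compared to the true eigenspace by
principal angles.  The PCA over iteration vectors is an *uncentered* SVD
with squared-singular-value fractions as "contribution": the iterates
alternate sign under a negative leading eigenvalue, so the mean direction
is meaningless, and the uncentered form also gives the degenerate
all-identical-vectors case its natural 100% first component.

## Synthetic networks

An enzyme module is an explicit elementary-step mechanism with a conserved
total-enzyme moiety.  Two named fixtures carry the worked analyses:

- **PGI** (glucose-6-phosphate isomerase): binding (PGI1), isomerization
  (PGI2), release (PGI3) over {G6P, F6P, PGI, PGI&G6P, PGI&F6P}.  Defaults:
  [G6P] = 0.05, [F6P] = 0.02, enzyme total 1e−5 mmol/L; k⁺/k⁻ =
  2.5e9/1e9 (binding, K_d = 0.4 mmol/L), 1e6/1e5 (catalysis), 1e8/1e9
  (release, K_d = 0.1).  The binding half reaction sits below its K_d and
  the catalytic step is strongly forward, which makes the bound-form row
  diagonally dominant — the regime in which that form is a mode by itself.
  A low-sugar variant (G6P = 0.005) deepens dominance to f ≈ 0.005 for the
  strong-dominance demonstrations.
- **G6PDH** (glucose-6-phosphate dehydrogenase): seven steps.  The
  text-constrained steps are NADPH release
  (R6: G6PDH&NADPH&6PGL ↔ G6PDH&6PGL + NADPH) and the essentially
  irreversible oxidation (R7: G6PDH&NADP&G6P → G6PDH&NADPH&6PGL,
  k⁻ = 0.01 h⁻¹); R4 releases 6PGL back to free enzyme.  The remaining
  steps are a package design choice, documented as such: ordered binding of
  NADP (R1) then G6P (R2), plus two dead-end regulatory bindings of G6P
  (R3) and NADPH (R5) to the free enzyme — product inhibition by NADPH is
  the textbook behavior of this enzyme.  Default [NADPH] = 0.06 mmol/L
  equals K_d of R6 (6e6/1e8), the near-equilibrium regime in which the
  release and bound forms share the fastest mode and the four largest
  Jacobian entries over the key forms sit in the symmetric
  (2,2)/(2,4)/(4,2)/(4,4) block.  Free-enzyme couplings (k⁺₄ = 50 h⁻¹,
  slow 6PGL release) are kept small so the shared mode stays on the bound
  forms, matching the observation that the free form is not prominently
  featured; variants with [NADPH] at 0.04 and 0.09 mmol/L provide the
  asymmetric regimes for the entry-editing experiments.

The random generator draws, per module, a metabolite pool conversion over
a shared pool set (about one pool per two modules, so enzyme-form rows
outnumber metabolite rows and the network is connected), log-uniform
metabolite concentrations (1e−5–1e1 mmol/L), enzyme totals (1e−7–1e−4
mmol/L, several orders below the pools), and unbinding/release rates
(10^6–10^10 h⁻¹); binding rates follow from a targeted half-reaction
distance, placed within half a decade of equilibrium with probability
`fraction_near` (default 0.25) and 1–4 decades away otherwise, on the side
that favors diagonal dominance of the bound-form rows.  Catalytic
constants sit three decades below the binding scale.  All draws come from
one seeded generator; identical seeds reproduce identical networks
bit-for-bit.

What the generator emulates: the order-of-magnitude spread of rate
constants, concentrations and timescales, enzyme totals far below
metabolite pools, moiety conservation, and mixed near/far half-reaction
equilibria — the features that produce the dominance statistics and mode
sparsity the analyses target.  What it does not emulate: real pathway
topology (it builds pool-conversion cycles, not glycolysis), regulatory
and allosteric interactions, measured parameter values, open-system
boundary fluxes, and flux-carrying non-equilibrium steady states
(closed-system steady states are thermodynamic equilibria).  Passing tests
therefore certify the mathematical machinery and the parameter-scaling
regimes, not any specific organism's numbers.

## Numerics

Steady states are found by staged stiff integration (BDF, analytic
Jacobian, relative tolerance 1e−10) over geometrically growing horizons up
to 1e6 time units, accepting when ‖S·v‖ falls below 1e−9 times the gross
(one-way) flux scale — the net fluxes the residual measures cancel at
equilibrium, so the one-way scale is the meaningful yardstick.
Trajectory integration defaults to rtol 1e−9 with a near-zero absolute
tolerance and a log-spaced output grid spanning nine decades below the
horizon.  The linear-regime comparisons perturb each concentration by
1e−3 relative, small enough that quadratic terms sit three decades below
the linear response.  Mode-versus-species comparisons normalize both
curves by their initial values and compare over one decade below to three
times the mode's timescale; the perturbation is applied to the mode's own
species, since a generic kick excites slow modes whose weighted
contributions obscure the single-species reading.

Problem sizes in the test suite and acceptance script (100 random networks
for the gradient oracle, 1000 matrices for Gershgorin containment, 200
gapped spectra for power iteration, 100×100 cluster probes) were chosen to
exercise each property across its parameter range while keeping the whole
suite in the seconds-to-minutes range on one CPU.

## Known limitations

- Dense linear algebra throughout: fine for module-scale and
  generator-scale networks (tens to low hundreds of species), not tuned
  for genome-scale models.
- The closed-system steady states of the fixtures are equilibria; analyses
  that specifically need flux-carrying reference states should supply one
  (any reference state, steady or not, is accepted for linearization).
- Power iteration on a real matrix cannot converge to a genuinely complex
  leading eigenvector; the 2-dimensional escalation estimates the pair but
  the deflation walk stops rather than deflating a complex pair.
- The SBML layer is deliberately minimal (elementary mass action only); it
  is a serialization format for this package's model class, not a general
  SBML consumer.
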