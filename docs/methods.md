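# Methods

## Model

A chemical reaction network is a set of species `Xj` and reactions
`Σ a_jm Xj → Σ b_jm Xj` with rate constants `γ_m`. Under deterministic
mass-action kinetics each concentration obeys

    dx_j/dt = Σ_m γ_m (b_jm − a_jm) Π_j x_j^{a_jm}.

Units are fixed package-wide: nM for concentrations, seconds for time,
s⁻¹ for unimolecular and (nM·s)⁻¹ for bimolecular rate constants. With
non-negative initial conditions the dynamics are non-negative; the solver's
small negative excursions are clipped on output and flagged if they exceed
100×atol.

A signed signal `p` is represented dual-rail as `p = x⁺ − x⁻` over two
non-negative species. The rotated coordinates

    bar = x⁺ − x⁻,   hat = x⁺ + x⁻

split the dynamics into the *represented* input–output system (bar) and the
*internal positive* dynamics (hat). For a rate-symmetric construction the
bimolecular annihilation fluxes are identical on both rails, so they cancel
in every bar equation: the represented system is exactly linear even though
the network itself is nonlinear. `io_cancellation_check` verifies this
symbolically: the mass-action field is built with exact rational images of
the rate constants (equal rates cancel exactly, no floating-point false
negatives), the per-pair difference dynamics are rewritten in rotated
coordinates, and any surviving bimolecular monomial or hat-coordinate
dependence is reported as a residual. Dependence on a hat coordinate is the
signature of a mismatched unimolecular pair: the internal positive dynamics
then feed back into the represented system.

## The two circuits

*Integral control* of a first-order plant: plant pole `a`, plant gain `b`,
integral gain `ki` (all s⁻¹, defaults 2.5×10⁻³, 10⁻³, 5×10⁻², the values the
default strand-displacement scheme realises as `Cmax·c·kt`). The error
subtraction is folded into the integrator by cross-wiring the output
catalysis to the opposite integrator rail (`Y± → Y± + V∓`), so no separate
subtraction module is needed. Reaction census: 6 catalysis, 2 degradation,
2 annihilation (the output annihilation can be omitted for the reduced
implementation, since the output rails stay at low concentrations).

*State feedback* around a double integrator: stage gain `q` (s⁻¹, default
8×10⁻³), dimensionless gains `k1` (damping) and `k2` (tracking). `k2 = 1` is
required for zero steady-state error (DC gain is `1/k2`), and `k1 = 2√k2`
is the critical-damping boundary. The self-damping gain `q·k1` is realised
either as cross-rail autocatalysis `X± → X± + X∓` backed by fast
annihilation (catalytic-degradation variant, 8 catalysis + 2 annihilations)
or directly as degradation `X± → Ø` (6 catalysis + 2 degradations +
annihilations); both variants have identical bar dynamics.

Reference species are modelled as constant catalytic inputs: they appear
only as catalysts and carry no production, degradation or annihilation.
The default reference is a constant 10 nM step on the plus rail (a
round-number amplitude well below the fuel concentrations; the closed-loop
responses are linear in the step, so its exact value only scales the
trajectories). Default annihilation rate η = 10⁻³ (nM·s)⁻¹, chosen so that
η×(operating concentrations) is large against every unimolecular rate in
the default parametrisations; all signal species start at 0 nM.

## Strand-displacement compilation

Each abstract reaction expands into a toehold-mediated scheme:

- **Catalysis** `Xi → Xi + Xj`: a Join template captures the input strand
  (forward `c·kt`, the complementarity degree times the maximal signal
  toehold binding rate; backward `kt`), two auxiliary exchanges at
  `kbnd`/`kbnd` hand an intermediate strand to a Fork template, the Fork
  re-releases the input (forward `kbnd`, backward `kt`) and releases the
  product (at `kt`/`kt`), and an irreversible cleanup at `kt` ends the
  cascade — 5 reversible steps and 1 irreversible one, 11 mass-action
  records, two double-stranded templates.
- **Degradation** `Y → Ø`: one irreversible capture `JoinY + Y →
  JoinY_1 + dY` at `c·kt`; both products are inert waste. A finite leak
  unbinding rate `kleak > 0` makes the capture reversible.
- **Annihilation** `X⁺ + X⁻ → Ø`: cooperative hybridisation — a single
  template binds either input reversibly (forward `c·kt`, backward `kubnd`)
  and completes irreversibly into waste only when the partner strand is also
  present.

Templates and fuel strands are supplied at `Cmax` (default 10⁴ nM), so each
capture approximates a unimolecular reaction of rate `k_eff = Cmax·c·kt`;
`effective_rates` reports these products, and the cooperative annihilation
is reported as binding-limited with effective bimolecular rate `c·kt`. With
fuels clamped at `Cmax`, the simulated release rate constant of a single
catalysis cascade is within 10% of `k_eff`; the dominant deviation is the
Join stage returning a fraction `kt/(kt + kbnd)` ≈ 1/11 of captures through
its backward branch.

Census conventions (isolated in `census`): double-stranded supplied count is
2 per catalysis + 1 per degradation + 1 per annihilation. The single-stranded
supplied count is 3 fuel strands per catalysis cascade plus the reference
input strands; the strand released by the Join stage and taken back by the
Fork stage is supplied at `Cmax` like the other fuels (if it started at
zero, the cascade would stall on a bimolecular handoff between two
low-concentration species) but is counted as recycled rather than supplied.
Each catalysis gets its own Fork template; template sharing between cascades
is not modelled structurally, the census convention above absorbing the
difference. Strand names are deterministic and collision-checked; the minus
rail is rendered with a `p` suffix in the expanded network (`Y− → Yp`) and
with a trailing prime in the text file format.

## Unforced equilibria and internal instability

With the input removed, the bar dynamics decay to zero, and the hat dynamics
of the integral circuit satisfy

    0 = ki·ŷ − (η/2)·v̂²,   0 = b·v̂ − a·ŷ − (η/2)·ŷ².

Eliminating `v̂` and factoring the trivial root leaves the cubic

    (η³/8b²)·ŷ³ + (aη²/2b²)·ŷ² + (ηa²/2b²)·ŷ − ki = 0,

whose single sign change gives exactly one strictly positive root for any
positive parameters, with `v̂* = √(2·ki·ŷ*/η)`. The linear part of the hat
dynamics has eigenvalues `(−a ± √(a² + 4·ki·b))/2` (integral) and
`(q/2)(k1 ± √(k1² + 4k2))` (state feedback); the larger one is positive for
all positive parameters — a Frobenius eigenvalue pushing the unforced
dynamics away from the origin, so the network settles at the positive
equilibrium and, at the strand level, keeps consuming fuel even at steady
state. The closed forms are verified in the tests against the long-time
limits of the full ODEs (relative gap below 10⁻³) and against numeric
eigendecompositions of the analytic Jacobian.

## Rail asymmetry

Writing independent rates `a±, b±, ki±` for the paired reactions and
decomposing each as `ābar = a⁺ − a⁻`, `âhat = a⁺ + a⁻`, the rotated dynamics
acquire cross terms between the bar and hat subsystems. The unforced
equilibrium then has non-zero represented signals,

    ȳ* = −(k̄i/k̂i)·ŷ*,
    v̄* = −(b̄/b̂)·v̂* + ŷ*·(−(â/b̂)(k̄i/k̂i) + ā/b̂),

solved numerically (damped Newton from the symmetric closed form) and
cross-validated against the asymmetric ODE limit; the offset is first-order
linear in the rate mismatch for small mismatches. Asymmetric rates attach by
reactant rail: a reaction whose reactant is the `+` species carries the plus
rate.

## Leakage

Spurious output release is modelled at the abstract level as catalytic leak
sources `Z± → Z± + Y±` at rates `ρ±` (≈ `Cmax·kleak` when leak strands
interact with high-concentration auxiliaries), duplicated on both rails, and
at the strand level as reversal of the irreversible degradation captures at
`kleak`. For a symmetric leak (`ρ⁺ = ρ⁻`, equal source concentrations) the
leak terms cancel in the represented output — the bar trajectory is
unchanged to solver precision — while the hat (internal) concentrations
shift; an asymmetric leak biases the represented output itself, in
proportion to the rate mismatch. The differential structure of the dual-rail
representation therefore mitigates the *symmetric* part of leakage entirely.

## Numerics

`scipy.integrate.solve_ivp` with the BDF method and the analytic Jacobian is
the default integrator (expanded networks mix rates over four or more orders
of magnitude; rtol 10⁻⁸, atol 10⁻¹² nM, all overridable). Reversible steps
are stored as two irreversible records. Linear reference responses are
computed with the augmented matrix exponential, not numerical integration.
Polynomial roots come from the companion-matrix eigensolver; the critical
damping gain is found by bracketing root-finding on the damping coefficient.
Simulation is deterministic throughout — the package has no random component,
so runs are byte-reproducible for identical configurations.

Problem sizes used in the test suite: abstract circuits are 6-species /
9–10-reaction networks simulated over horizons of 3,000–20,000 s; expanded
networks are ≈90-species / ≈75-reaction systems over 2,000–8,000 s; the
large-excess convergence check compares `Cmax = 10⁴` against `10⁵` nM with
complementarities scaled to keep the effective rates fixed.

## Limitations

- Fuel pools are finite: with the default parametrisations the positive
  internal equilibrium drives template consumption that becomes significant
  after a few thousand seconds, after which the compiled circuit's tracking
  degrades and eventually fails. The consumption report therefore evaluates
  the depletion rate at the moment the output first reaches the commanded
  value. Experimental operation would need replenishment or shorter
  horizons, which is precisely the design tension the analysis quantifies.
- Cooperative annihilation sequesters a signal-dependent fraction of each
  rail in template-bound intermediates, which damps and slows the compiled
  dynamics relative to the abstract circuit; the effect does not vanish in
  the large-excess limit (the bound fraction depends on `c·kt·Cmax/kubnd`,
  which the limit holds fixed).
- Nucleotide sequence design, thermodynamic rate prediction from sequence,
  spatial localisation and stochastic (discrete-molecule) simulation are out
  of scope; rates are specified directly through the scheme parameters.
- The symbolic cancellation check covers networks built from the three
  elementary reaction types (plus abstract leak catalysis), not arbitrary
  strand-level networks.
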