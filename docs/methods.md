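# Methods

## What the package does

sbmlkit imports the dynamic core of SBML (Systems Biology Markup Language)
documents — Level 2 and Level 3 core, no packages — and compiles them into a
reaction-network intermediate representation with explicit, documented
semantics, which it then simulates either deterministically (as an ODE
system) or stochastically (Gillespie's direct method). SBML is
reaction-centric: a model is a set of species in compartments, reactions
with kinetic rate laws, parameters, and optional rules, events, function
definitions and initial assignments. Turning that into something a numerical
solver can integrate requires a series of semantic decisions; this note
records each of them.

## The conversion pipeline

1. **Read** (`sbmlkit.io`). The XML is mirrored into an in-memory `Model`.
   Kinetic laws, rules, triggers and assignments are parsed from content
   MathML into one shared immutable operator-tree type (`MathNode`).
   Simulation time is its own node type, so a model parameter named `t`
   cannot collide with time. Level 2 attribute defaults
   (`boundaryCondition=false`, species `constant=false`,
   `hasOnlySubstanceUnits=false`, parameter `constant=true`, reaction
   `reversible=true`) are materialized at read time; Level 3 documents must
   carry these attributes explicitly and fail to parse otherwise.
   Species declared by `initialConcentration` are converted to amounts
   (concentration × compartment size) as soon as the size is known.

2. **Support check** (`sbmlkit.normalize.check_support`). Constraints,
   delays (expression operator or event delay element), factorials,
   assignments targeting stoichiometries, and algebraic rules that do not
   determine exactly one variable are fatal. Events and non-integer
   stoichiometries are warnings: events because their firing rule deviates
   from the SBML standard (below), non-integer stoichiometries because they
   only block stochastic simulation.

3. **Normalization**. `expand_functions` inlines user-defined functions
   (recursion is rejected); `promote_local_parameters` lifts reaction-local
   parameters to globals named `<reaction>_<parameter>`, appending
   underscores on collision — any injective scheme preserves semantics, and
   this one keeps ids readable; `apply_initial_assignments` either
   hard-codes assignment values numerically (mode `hardcode`) or keeps them
   symbolic for compile-time resolution (mode `symbolic`). Two presets
   bundle these: `preset_simplify_math` (hardcode) and
   `preset_promotelocals_expandfuns` (symbolic). The symbolic preset is the
   default everywhere because hard-coding severs the dependence of the
   initial state on parameters, which matters whenever parameters will be
   re-estimated. Initial assignments are evaluated in topological order of
   their dependency graph; cycles are an error, as SBML declares them
   invalid.

4. **Compilation** (`sbmlkit.network.compile_network`).
   - *Entity classification.* An entity is a dynamic state iff its
     `constant` flag is false and it participates in a reaction as a
     non-boundary species, is the target of a rate rule, or is the target
     of an event assignment. Assignment-rule targets become observed
     (defined) variables; everything else with a value is a constant.
     A constant entity targeted by a rule or event, or a non-boundary
     species appearing in both reactions and rules, is a hard conflict.
   - *Reversible splitting.* A reversible reaction whose kinetic law is a
     literal two-argument subtraction `f − r` at the root becomes a forward
     channel with rate `f` and a sign-reversed channel with rate `r`. No
     algebraic rearrangement is attempted — only the syntactic form
     qualifies — because predictability beats cleverness here: a law like
     `k·(A − B/Keq)` is mathematically a difference but its "reverse rate"
     is not well defined without factoring choices. Such laws fall back to
     a single net-rate channel, which is flagged as unusable for
     stochastic simulation. Splitting never changes the ODE.
   - *Amounts convention.* State variables are absolute amounts. A species
     id inside math denotes a concentration when
     `hasOnlySubstanceUnits=false`, so such references are rewritten to
     `amount / compartment`, with the compartment left symbolic so
     time-varying volumes keep working. Automated amount/concentration
     output conversion is not attempted.
   - *Boundary species.* Species with `boundaryCondition=true` (and
     constant species) are excluded from every compiled net stoichiometry:
     rules override reactions for them.
   - *Events.* A relational trigger `a ≥ b` (or `a > b`) compiles to the
     numeric residual `a − b`; `a ≤ b` / `a < b` to `b − a`. The event
     fires whenever the residual crosses zero **in either direction**.
     This deviates from SBML's false-to-true rule, and every import of an
     event-bearing model emits exactly one warning saying so. Compound
     Boolean triggers (and/or/not/xor) and equality triggers are rejected
     rather than mis-handled.
   - *Initial state.* Precedence: declared `initialAmount`/Concentration
     < initial assignment < assignment rule evaluated at t=0.
   - *Algebraic rules.* Each algebraic rule must leave exactly one
     otherwise-undetermined non-constant variable; that variable is solved
     for numerically. Richer differential-algebraic structure is declared
     unsupported instead of silently mis-solved.

5. **Simulation** (`sbmlkit.simulate`).
   - `build_ode`: each state's derivative is the stoichiometry-weighted sum
     of its reaction rates, or its rate-rule expression. States with no
     flux, rule or event dependence are constant by construction and are
     demoted to constants with a warning rather than integrated.
   - `structural_simplify`: observed variables are substituted into the
     right-hand sides through chains to a fixed point (cycles are an
     error). This removes defined-variable indirection before integration;
     results are unchanged.
   - `integrate`: scipy's `solve_ivp` with LSODA (stiff-capable,
     adaptive), dense output on. Event residuals are evaluated at every
     accepted step; a sign change is refined by bisection on the dense
     output until the residual magnitude falls below 1e-9 of its local
     scale; assignments are applied with simultaneous-read /
     sequential-write semantics in document order, and integration
     restarts. Simultaneous candidates fire at the earliest located time,
     ties broken by document order (SBML's priority element is out of
     scope). Events are armed from the first step: a trigger already past
     threshold at t=0 does not fire until its residual actually crosses
     zero. More than `max_events` firings (default 1000) aborts with an
     error rather than looping forever. Algebraic variables are re-solved
     (secant iteration from the previous value) at every right-hand-side
     evaluation.
   - `gillespie`: exact direct-method SSA. Propensities are the compiled
     rate expressions evaluated on the current integer amounts — **no
     compartment-volume division is applied**, so models needing
     concentration-based propensities must use `hasOnlySubstanceUnits=true`
     or unit volumes. Preconditions enforced: integer initial amounts and
     stoichiometries, no rules, no events, and no net-rate fallback
     channels. Each path is fully reproducible from its seed
     (`numpy.random.default_rng`); ensembles derive independent per-path
     seeds from one master seed via `SeedSequence.spawn`.

   All rate laws, rules and residuals are compiled once into Python
   bytecode (a whitelisted-namespace `exec`), so integrator and SSA inner
   loops never walk expression trees; a property test pins the compiled
   form to the tree-walking evaluator.

## Numerical choices

- Default tolerances `rel_tol=1e-8`, `abs_tol=1e-10`: tight enough that the
  semantic assertions in the test suite (1e-6 to 1e-8) are never masked by
  integration error.
- Event localization by bisection on the dense output (not solver-internal
  root polishing): solver-agnostic and accurate to ~1e-9 residual scale,
  ample at the scale of these models.
- `log` without a base is base 10, `ln` is natural, unary `minus` is
  negation, `root` with one argument is the square root — content-MathML
  conventions.
- A piecewise with no matching branch and no `otherwise` raises an
  arithmetic error (SBML leaves the value undefined; failing loudly beats
  guessing).
- Stoichiometries are stored as reals; integrality is enforced only where
  it matters (SSA), not at parse time.

## The fixture generator

`sbmlkit.fixtures` builds small SBML documents with machine-checkable
reference behavior, chosen so the closed forms are trivial to verify:
exponential decay read off at `10·e⁻¹`; a reversible binding reaction whose
conservation laws (A+C, B+C) and equilibrium ratio `k1/k2` are exact; a
Michaelis–Menten model exercising function expansion and local-parameter
promotion; an exponential-growth sawtooth whose event fires with period
`ln 2`; a boundary species pinned by an assignment rule giving exactly
linear product growth; an immigration–death (M/M/∞) process with stationary
mean λ/μ = 10; and three single-feature unsupported models (factorial,
delay, constraint). Defaults are fixed and are the study conditions of the
test suite.

What these fixtures do **not** emulate: real curated models' scale
(hundreds of species), unit annotations, deeply nested piecewise kinetics,
SBML packages, and event priorities/persistence. Passing tests therefore
demonstrate semantic correctness of the conversion rules on models that
isolate each rule, not robustness across the full public model corpus —
extending validation to a curated repository would be the natural next
step, but this package deliberately ships with no download dependency.

## Problem sizes

The bundled test-suite and acceptance-script runs use desk-scale sizes
chosen to make every check sharp: 201 output points per ODE trajectory,
10,000 SSA paths for the ensemble-mean check (standard error ≈ 0.03 around
a mean of 10), and 200 paths for per-path conservation (which is exact, so
path count only adds coverage).

## Known limitations

- Events: no delays, priorities, persistence or `useValuesFromTriggerTime`
  semantics; triggers must be a single relational comparison; firing is
  direction-agnostic (warned).
- Only one scalar unknown per algebraic rule.
- Stoichiometries set by initial assignments are rejected.
- SSA propensities use amounts, never concentrations.
- No units, no annotations, no SBML packages (comp, fbc, layout, ...), no
  delay differential equations, no Level 1, no down-conversion to Level 2.
- Level/version conversion materializes Level 2 defaults; it does not run
  a general converter registry.
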