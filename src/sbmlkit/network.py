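"""Compile a normalized Model into a reaction-network intermediate form.

The compiler (a) splits reversible reactions whose kinetic law is a
top-level difference ``f - r`` into separate forward and reverse channels —
irrelevant for deterministic simulation but required for exact stochastic
simulation, where each channel needs its own non-negative propensity;
(b) classifies every entity as a dynamic state, a constant, or an observed
(assignment-rule-defined) variable; (c) rewrites species references to the
amounts convention (a species id in math means an absolute amount; where
``hasOnlySubstanceUnits`` is false the reference becomes amount / compartment
size); (d) converts Boolean event triggers into numeric residuals whose zero
crossings — in either direction — fire the event; and (e) resolves the
initial state with the precedence: declared initial value < initial
assignment < assignment rule at t=0.

Species flagged ``boundaryCondition`` (and constant species) never receive
reaction flux: they are excluded from every compiled net stoichiometry, so
rules win over reactions for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import optimize

from .errors import ConflictError, ResolutionError, UnsupportedFeatureError
from .expressions import (
    Apply, MathNode, Number, SymbolRef, TIME_ID,
    evaluate_math, free_symbols, to_string, transform,
)
from .model import AlgebraicRule, AssignmentRule, Model, RateRule
from .normalize import (
    EVENT_DIRECTIONALITY_NOTICE, algebraic_unknowns, check_support,
    evaluate_initial_assignments,
)


@dataclass
class CompiledReaction:
    id: str
    net_stoichiometry: dict[str, float]
    rate: MathNode  # amounts convention, concentration division applied
    source: tuple[str, str]  # (original reaction id, forward|reverse|irreversible)
    #: the kinetic law with species as bare amounts (no compartment
    #: division) — the form SSA propensities are evaluated on
    rate_amounts: MathNode | None = None
    #: False for the net-rate fallback of an unsplittable reversible law;
    #: such a channel cannot be simulated stochastically
    stochastic_ok: bool = True


@dataclass
class CompiledEvent:
    id: str
    residual: MathNode  # real-valued; zero at the trigger boundary
    assignments: list[tuple[str, MathNode]]


@dataclass
class ReactionNetwork:
    states: list[str]
    initial: dict[str, float]
    constants: dict[str, float]
    reactions: list[CompiledReaction]
    assignment_rules: dict[str, MathNode] = field(default_factory=dict)  # observed
    observed_order: list[str] = field(default_factory=list)
    observed_initial: dict[str, float] = field(default_factory=dict)
    rate_rules: dict[str, MathNode] = field(default_factory=dict)
    algebraic_rules: list[tuple[MathNode, str]] = field(default_factory=list)
    algebraic_initial: dict[str, float] = field(default_factory=dict)
    events: list[CompiledEvent] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# entity classification

def classify_entities(model: Model) -> tuple[list[str], dict[str, float], list[str]]:
    """Partition entities into (states, constants, observed).

    An entity is time-varying (a state) iff its constant flag is false and
    it is a non-boundary reaction participant, a rate-rule target, or an
    event-assignment target.  Assignment-rule targets are observed
    (defined, not integrated).  Everything else with a value is a constant.
    """
    assignment_targets = [r.variable for r in model.rules if isinstance(r, AssignmentRule)]
    rate_targets = {r.variable for r in model.rules if isinstance(r, RateRule)}
    event_targets = {var for ev in model.events.values() for var, _ in ev.assignments}
    rule_targets = set(assignment_targets) | rate_targets
    participants: set[str] = set()
    for r in model.reactions.values():
        for sp, _ in r.reactants + r.products:
            participants.add(sp)

    for eid in rule_targets | event_targets:
        ent = model.entity(eid)
        if ent is None:
            raise ResolutionError(f"rule or event targets unknown entity {eid!r}")
        if getattr(ent, "constant", False):
            raise ConflictError(
                f"constant entity {eid!r} is targeted by a rule or event assignment")

    for sid in rule_targets:
        sp = model.species.get(sid)
        if sp is not None and not sp.boundary_condition and sid in participants:
            raise ConflictError(
                f"non-boundary species {sid!r} appears in both reactions and rules")

    states: list[str] = []
    observed: list[str] = []
    constants: dict[str, float] = {}

    def initial_value(eid):
        ent = model.entity(eid)
        sp = model.species.get(eid)
        if sp is not None:
            if sp.initial_amount is not None:
                return sp.initial_amount
            if sp.initial_concentration is not None:
                comp = model.compartments[sp.compartment]
                if comp.size is not None:
                    return sp.initial_concentration * comp.size
            return None
        return ent.value if hasattr(ent, "value") else ent.size

    ordered = (list(model.species) + list(model.parameters) + list(model.compartments))
    for eid in ordered:
        ent = model.entity(eid)
        if eid in set(assignment_targets):
            observed.append(eid)
            continue
        is_const_flag = getattr(ent, "constant", True)
        sp = model.species.get(eid)
        dynamic = not is_const_flag and (
            (sp is not None and not sp.boundary_condition and eid in participants)
            or eid in rate_targets
            or eid in event_targets
        )
        if dynamic:
            states.append(eid)
        else:
            v = initial_value(eid)
            if v is not None:
                constants[eid] = v
    return states, constants, observed


# ---------------------------------------------------------------------------
# reversible splitting

def split_reversible(reaction, excluded: frozenset[str] | set[str] = frozenset()
                     ) -> tuple[list[CompiledReaction], list[str]]:
    """One reaction -> one or two compiled channels, plus warnings.

    Irreversible reactions map 1:1.  A reversible reaction whose kinetic
    law is a literal two-argument subtraction ``f - r`` at the root becomes
    a forward channel with rate ``f`` and a sign-reversed channel with rate
    ``r`` (no algebraic rearrangement is attempted).  Any other reversible
    law falls back to a single net-rate channel, which deterministic
    simulation handles identically but stochastic simulation must reject.
    Species in ``excluded`` (boundary/constant) get no stoichiometry.
    """
    net: dict[str, float] = {}
    for sp, st in reaction.products:
        net[sp] = net.get(sp, 0.0) + st
    for sp, st in reaction.reactants:
        net[sp] = net.get(sp, 0.0) - st
    net = {sp: v for sp, v in net.items() if v != 0.0 and sp not in excluded}
    law = reaction.kinetic_law
    if not reaction.reversible:
        return [CompiledReaction(reaction.id, net, law,
                                 (reaction.id, "irreversible"))], []
    if isinstance(law, Apply) and law.op == "minus" and len(law.args) == 2:
        fwd = CompiledReaction(f"{reaction.id}_fwd", dict(net), law.args[0],
                               (reaction.id, "forward"))
        rev = CompiledReaction(f"{reaction.id}_rev",
                               {sp: -v for sp, v in net.items()},
                               law.args[1], (reaction.id, "reverse"))
        return [fwd, rev], []
    warn = (f"reversible reaction {reaction.id!r}: kinetic law "
            f"{to_string(law)} is not a top-level difference; compiled as a "
            f"single net-rate channel (stochastic simulation disallowed)")
    return [CompiledReaction(reaction.id, net, law, (reaction.id, "irreversible"),
                             stochastic_ok=False)], [warn]


# ---------------------------------------------------------------------------
# amounts convention

def resolve_species_symbols(math: MathNode, model: Model) -> MathNode:
    """Rewrite species references to the amounts convention.

    A species with ``hasOnlySubstanceUnits=false`` denotes a concentration
    in SBML math, so its reference becomes amount / compartment size; the
    compartment stays symbolic so time-varying volumes work.  Species with
    ``hasOnlySubstanceUnits=true`` stay bare amounts.
    """
    def rewrite(n: MathNode):
        if isinstance(n, SymbolRef):
            sp = model.species.get(n.id)
            if sp is None or sp.has_only_substance_units:
                return None
            comp = model.compartments[sp.compartment]
            if comp.size is None and sp.compartment not in model.initial_assignments \
                    and not any(getattr(r, "variable", None) == sp.compartment
                                for r in model.rules):
                raise ResolutionError(
                    f"species {n.id!r} needs compartment {sp.compartment!r} size, "
                    f"but it has no size, rule or assignment")
            return Apply("divide", (n, SymbolRef(sp.compartment)))
        return None
    return transform(math, rewrite)


# ---------------------------------------------------------------------------
# events

_RESIDUAL_FORMS = {"geq", "gt", "leq", "lt"}
_BOOLEAN_OPS = {"and", "or", "not", "xor"}


def compile_events(model: Model) -> tuple[list[CompiledEvent], list[str]]:
    """Boolean triggers -> numeric residuals.

    ``a >= b`` / ``a > b`` become the residual ``a - b``; ``a <= b`` /
    ``a < b`` become ``b - a``.  The residual's zero crossing fires the
    event in either direction, which deviates from SBML's false-to-true
    rule; one warning per model states this.  Compound Boolean triggers are
    unsupported.
    """
    events: list[CompiledEvent] = []
    warnings: list[str] = []
    for ev in model.events.values():
        trig = ev.trigger
        if isinstance(trig, Apply) and trig.op in _BOOLEAN_OPS:
            raise UnsupportedFeatureError(
                f"event {ev.id!r}: compound Boolean trigger "
                f"({trig.op}) is not supported", feature="compound-trigger")
        if not (isinstance(trig, Apply) and trig.op in _RESIDUAL_FORMS):
            raise UnsupportedFeatureError(
                f"event {ev.id!r}: trigger must be a relational expression "
                f"(lt/leq/gt/geq), got {to_string(trig)}", feature="trigger-form")
        a, b = trig.args
        residual = Apply("minus", (a, b)) if trig.op in ("geq", "gt") \
            else Apply("minus", (b, a))
        events.append(CompiledEvent(ev.id, residual, list(ev.assignments)))
    if events:
        warnings.append(EVENT_DIRECTIONALITY_NOTICE)
    return events, warnings


# ---------------------------------------------------------------------------
# full compilation

def compile_network(model: Model) -> ReactionNetwork:
    """Normalize-checked Model -> ReactionNetwork.

    Requires a model whose functions are already expanded and whose support
    report has no fatal findings (both are re-checked here).
    """
    report = check_support(model)
    if not report.ok:
        raise UnsupportedFeatureError(
            "model has unsupported features:\n" + str(report),
            feature=report.fatal[0].feature)
    if model.function_definitions:
        raise ResolutionError(
            "model still contains function definitions; run expand_functions "
            "(or a preset) before compiling")
    for r in model.reactions.values():
        if r.local_parameters:
            raise ResolutionError(
                f"reaction {r.id!r} still has local parameters; run "
                f"promote_local_parameters (or a preset) before compiling")

    states, constants, observed = classify_entities(model)
    warnings: list[str] = []

    excluded = {
        s.id for s in model.species.values()
        if s.boundary_condition or s.constant
    } | set(observed)

    reactions: list[CompiledReaction] = []
    for rxn in model.reactions.values():
        channels, warns = split_reversible(rxn, excluded)
        warnings.extend(warns)
        for ch in channels:
            ch.rate_amounts = ch.rate
            ch.rate = resolve_species_symbols(ch.rate, model)
        reactions.extend(channels)

    assignment_rules: dict[str, MathNode] = {}
    rate_rules: dict[str, MathNode] = {}
    for rule in model.rules:
        if isinstance(rule, AssignmentRule):
            assignment_rules[rule.variable] = resolve_species_symbols(rule.math, model)
        elif isinstance(rule, RateRule):
            rate_rules[rule.variable] = resolve_species_symbols(rule.math, model)

    algebraic: list[tuple[MathNode, str]] = []
    for rule in model.rules:
        if isinstance(rule, AlgebraicRule):
            unknowns = algebraic_unknowns(model, rule)
            if len(unknowns) != 1:
                raise UnsupportedFeatureError(
                    f"algebraic rule must determine exactly one variable, "
                    f"found {sorted(unknowns)}", feature="algebraic-rule")
            var = unknowns.pop()
            constants.pop(var, None)
            algebraic.append((resolve_species_symbols(rule.math, model), var))

    events, ev_warnings = compile_events(model)
    warnings.extend(ev_warnings)
    for ev in events:
        ev.residual = resolve_species_symbols(ev.residual, model)
        ev.assignments = [(v, resolve_species_symbols(m, model))
                          for v, m in ev.assignments]

    initial, observed_initial, algebraic_initial = _resolve_initial_state(
        model, states, constants, assignment_rules, observed, algebraic)

    return ReactionNetwork(
        states=states, initial=initial, constants=constants,
        reactions=reactions, assignment_rules=assignment_rules,
        observed_order=observed, observed_initial=observed_initial,
        rate_rules=rate_rules, algebraic_rules=algebraic,
        algebraic_initial=algebraic_initial, events=events, warnings=warnings)


def _resolve_initial_state(model, states, constants, assignment_rules,
                           observed, algebraic):
    """Initial values with precedence: declared value < initialAssignment <
    assignmentRule at t=0."""
    # 1. declared values (amounts; leftover concentrations resolved below)
    initial: dict[str, float] = {}
    pending_conc: dict[str, str] = {}
    for sid in states:
        sp = model.species.get(sid)
        if sp is None:
            ent = model.entity(sid)
            v = ent.value if hasattr(ent, "value") else ent.size
            if v is not None:
                initial[sid] = v
            continue
        if sp.initial_amount is not None:
            initial[sid] = sp.initial_amount
        elif sp.initial_concentration is not None:
            comp = model.compartments[sp.compartment]
            if comp.size is not None:
                initial[sid] = sp.initial_concentration * comp.size
            else:
                pending_conc[sid] = sp.compartment

    # 2. initial assignments (symbolic mode keeps them on the model)
    if model.initial_assignments:
        values = evaluate_initial_assignments(model)
        for target, value in values.items():
            if target in constants:
                constants[target] = value
            elif target in states:
                initial[target] = value
        for sid, comp_id in list(pending_conc.items()):
            if comp_id in values:
                sp = model.species[sid]
                initial[sid] = sp.initial_concentration * values[comp_id]
                del pending_conc[sid]
    for sid in pending_conc:
        raise ResolutionError(
            f"species {sid!r}: cannot convert initialConcentration, "
            f"compartment size unknown at compile time")
    for sid in states:
        if sid not in initial:
            raise ResolutionError(f"state {sid!r} has no initial value")

    # 3. assignment rules at t=0 (override; may chain through observed)
    env: dict[str, float] = dict(constants)
    env.update(initial)
    observed_initial: dict[str, float] = {}
    remaining = list(observed)
    for _ in range(len(remaining) + 1):
        progressed = False
        for var in list(remaining):
            needed = free_symbols(assignment_rules[var]) - {TIME_ID}
            if needed <= set(env):
                value = float(evaluate_math(assignment_rules[var], env, t=0.0))
                observed_initial[var] = value
                env[var] = value
                remaining.remove(var)
                progressed = True
        if not remaining:
            break
        if not progressed:
            raise ResolutionError(
                f"cannot resolve assignment rules at t=0 for {remaining} "
                f"(cycle or missing values)")

    # 4. algebraic rules: solve each residual for its variable at t=0
    algebraic_initial: dict[str, float] = {}
    for residual, var in algebraic:
        ent = model.entity(var)
        guess = getattr(ent, "value", None)
        if guess is None and model.species.get(var) is not None:
            guess = model.species[var].initial_amount
        guess = 1.0 if guess is None else float(guess)

        def f(x, residual=residual, var=var):
            e = dict(env)
            e[var] = float(x)
            return float(evaluate_math(residual, e, t=0.0))

        sol = optimize.root_scalar(f, x0=guess, x1=guess + max(1.0, abs(guess)),
                                   method="secant", xtol=1e-12, maxiter=200)
        if not sol.converged:
            raise ResolutionError(
                f"could not solve algebraic rule for {var!r} at t=0")
        algebraic_initial[var] = float(sol.root)
        env[var] = algebraic_initial[var]

    return initial, observed_initial, algebraic_initial


# ---------------------------------------------------------------------------
# dump

def network_to_dict(net: ReactionNetwork) -> dict:
    """JSON-ready dump of a compiled network (CLI ``convert`` output)."""
    return {
        "states": [{"id": s, "initial": net.initial[s]} for s in net.states],
        "constants": dict(net.constants),
        "reactions": [
            {
                "id": r.id,
                "source": {"reaction": r.source[0], "direction": r.source[1]},
                "net_stoichiometry": dict(r.net_stoichiometry),
                "rate": to_string(r.rate),
                "stochastic_ok": r.stochastic_ok,
            }
            for r in net.reactions
        ],
        "assignment_rules": {v: to_string(m) for v, m in net.assignment_rules.items()},
        "rate_rules": {v: to_string(m) for v, m in net.rate_rules.items()},
        "algebraic_rules": [
            {"residual": to_string(m), "solved_variable": v}
            for m, v in net.algebraic_rules
        ],
        "events": [
            {
                "id": e.id,
                "residual": to_string(e.residual),
                "assignments": [{"variable": v, "math": to_string(m)}
                                for v, m in e.assignments],
            }
            for e in net.events
        ],
        "warnings": list(net.warnings),
    }
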