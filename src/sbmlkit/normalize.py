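"""Pre-compilation passes over a Model.

``check_support`` screens a model for features outside the supported dynamic
subset; ``set_level_and_version`` harmonizes Level 2 documents to Level 3
Version 2 semantics; ``expand_functions`` inlines user-defined functions;
``promote_local_parameters`` lifts reaction-local parameters into the global
namespace; ``apply_initial_assignments`` either hard-codes initial
assignments numerically or validates them for symbolic resolution at compile
time.

Two presets bundle these:

* :func:`preset_simplify_math` — expand functions, promote locals and
  hard-code initial assignments.  Simple, but a parameter that only enters
  through an initial assignment no longer influences the compiled initial
  state afterwards.
* :func:`preset_promotelocals_expandfuns` — the same but with initial
  assignments kept symbolic, so later parameter changes propagate into the
  initial state.  Recommended whenever parameters will be re-fitted.

All passes return a new Model; inputs are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ResolutionError, UnsupportedFeatureError
from .expressions import (
    Apply, MathNode, Number, SymbolRef, TIME_ID,
    contains_op, free_symbols, substitute, transform, evaluate_math,
)
from .model import AlgebraicRule, AssignmentRule, Model, Parameter, RateRule


@dataclass
class Finding:
    feature: str
    location: str
    severity: str  # "fatal" | "warning"
    message: str = ""


@dataclass
class SupportReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "fatal"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        if not self.findings:
            return "all features supported"
        return "\n".join(
            f"[{f.severity}] {f.feature} at {f.location}" +
            (f": {f.message}" if f.message else "")
            for f in self.findings)


EVENT_DIRECTIONALITY_NOTICE = (
    "events fire on zero crossings of the trigger residual in EITHER "
    "direction, not only on false-to-true transitions")


def check_support(model: Model) -> SupportReport:
    """Screen a model for unsupported features; never mutates the model.

    Fatal: constraints, delay operators, event delays, factorials,
    assignments targeting stoichiometries, algebraic rules that do not
    determine exactly one variable.  Warnings: events (directionality
    deviation) and non-integer stoichiometries (blocks SSA only).
    """
    rep = SupportReport()
    for i, _ in enumerate(model.constraints):
        rep.findings.append(Finding("constraint", f"constraint[{i}]", "fatal",
                                    "SBML constraints are not supported"))
    for loc, kind, node in model.iter_math():
        if kind == "constraint":
            continue
        if contains_op(node, "delay"):
            rep.findings.append(Finding("delay", loc, "fatal",
                                        "delay expressions are not supported"))
        if contains_op(node, "factorial"):
            rep.findings.append(Finding("factorial", loc, "fatal",
                                        "factorial expressions are not supported"))
    for ev in model.events.values():
        if ev.has_delay:
            rep.findings.append(Finding("event-delay", ev.id, "fatal",
                                        "event delays are not supported"))
    for target in model.initial_assignments:
        if target in model.stoichiometry_reference_ids:
            rep.findings.append(Finding(
                "stoichiometry-assignment", target, "fatal",
                "assignment to a stoichiometry is not supported"))
    for rule in model.rules:
        var = getattr(rule, "variable", None)
        if var is not None and var in model.stoichiometry_reference_ids:
            rep.findings.append(Finding(
                "stoichiometry-assignment", var, "fatal",
                "rule targeting a stoichiometry is not supported"))
    for i, rule in enumerate(model.rules):
        if isinstance(rule, AlgebraicRule):
            unknowns = algebraic_unknowns(model, rule)
            if len(unknowns) != 1:
                rep.findings.append(Finding(
                    "algebraic-rule", f"algebraic[{i}]", "fatal",
                    f"rule determines {len(unknowns)} variables, need exactly 1"))
    if model.events:
        rep.findings.append(Finding(
            "event-directionality", next(iter(model.events)), "warning",
            EVENT_DIRECTIONALITY_NOTICE))
    for r in model.reactions.values():
        if any(st != int(st) for _, st in r.reactants + r.products):
            rep.findings.append(Finding(
                "non-integer-stoichiometry", r.id, "warning",
                "non-integer stoichiometry blocks stochastic simulation"))
    return rep


def algebraic_unknowns(model: Model, rule: AlgebraicRule) -> set[str]:
    """Free symbols of an algebraic rule not determined by anything else.

    A symbol is already determined if it is constant, a reaction
    participant, or the target of any other rule; whatever remains is what
    the rule must be solved for.
    """
    determined: set[str] = set()
    for r in model.reactions.values():
        for sp, _ in r.reactants + r.products:
            if not model.species[sp].boundary_condition:
                determined.add(sp)
    for other in model.rules:
        var = getattr(other, "variable", None)
        if var is not None:
            determined.add(var)
    out = set()
    for sid in free_symbols(rule.math) - {TIME_ID}:
        ent = model.entity(sid)
        if ent is None or getattr(ent, "constant", True):
            continue
        if sid not in determined:
            out.add(sid)
    return out


def set_level_and_version(model: Model, level: int = 3, version: int = 2) -> Model:
    """Harmonize a Level 2/3 model to Level 3 Version 2 semantics.

    Attribute defaults are already materialized when a Level 2 document is
    read, so for L2 inputs this amounts to re-stamping the level/version
    (the in-memory representation always carries explicit flags); L3V1 to
    L3V2 is a version bump only.  Only the (3, 2) target exists.
    """
    if (level, version) != (3, 2):
        raise UnsupportedFeatureError(
            f"only conversion to Level 3 Version 2 is supported, not "
            f"({level}, {version})", feature="level-conversion")
    if model.level not in (2, 3):
        raise UnsupportedFeatureError(
            f"cannot convert from Level {model.level}", feature="level-conversion")
    out = model.copy()
    out.level, out.version = 3, 2
    return out


# ---------------------------------------------------------------------------
# function expansion

def _function_call_graph(model: Model) -> dict[str, set[str]]:
    fids = set(model.function_definitions)
    return {
        fid: {n.op for n in _calls(fd.body) if n.op in fids}
        for fid, fd in model.function_definitions.items()
    }


def _calls(node: MathNode):
    from .expressions import walk
    return [n for n in walk(node) if isinstance(n, Apply)]


def _check_no_recursion(model: Model) -> None:
    graph = _function_call_graph(model)
    state: dict[str, int] = {}

    def visit(fid: str, stack: list[str]):
        if state.get(fid) == 2:
            return
        if state.get(fid) == 1:
            cycle = " -> ".join(stack + [fid])
            raise UnsupportedFeatureError(
                f"recursive function definitions: {cycle}", feature="recursion")
        state[fid] = 1
        for callee in graph.get(fid, ()):
            visit(callee, stack + [fid])
        state[fid] = 2

    for fid in graph:
        visit(fid, [])


def _expand_calls(node: MathNode, defs) -> MathNode:
    """Replace every call to a defined function by its (already expanded)
    body with arguments substituted."""
    def rewrite(n: MathNode):
        if isinstance(n, Apply) and n.op in defs:
            fd = defs[n.op]
            if len(n.args) != len(fd.arguments):
                raise ResolutionError(
                    f"call to {n.op!r} with {len(n.args)} arguments, "
                    f"definition takes {len(fd.arguments)}")
            return substitute(fd.body, dict(zip(fd.arguments, n.args)))
        return None
    return transform(node, rewrite)


def expand_functions(model: Model) -> Model:
    """Inline every user-defined function call; empties listOfFunctions.

    Idempotent; raises on recursive definitions or arity mismatches.
    """
    out = model.copy()
    if not out.function_definitions:
        return out
    _check_no_recursion(out)
    # expand function bodies against each other first (nested definitions)
    defs = dict(out.function_definitions)
    changed = True
    while changed:
        changed = False
        for fid, fd in defs.items():
            new_body = _expand_calls(fd.body, {k: v for k, v in defs.items() if k != fid})
            if new_body != fd.body:
                fd.body = new_body
                changed = True
    out.map_math(lambda n: _expand_calls(n, defs))
    out.function_definitions = {}
    return out


# ---------------------------------------------------------------------------
# local parameter promotion

def promote_local_parameters(model: Model) -> Model:
    """Lift reaction-local parameters to global constant parameters.

    The promoted name is ``<reaction id>_<local id>``; on collision with any
    existing global id an underscore is appended until the name is unique.
    Only the owning reaction's kinetic law is rewritten, so identically
    named locals in different reactions stay independent.  Idempotent.
    """
    out = model.copy()
    taken = out.global_ids()
    for rxn in out.reactions.values():
        if not rxn.local_parameters:
            continue
        renames: dict[str, MathNode] = {}
        for pid, value in rxn.local_parameters.items():
            name = f"{rxn.id}_{pid}"
            while name in taken:
                name += "_"
            taken.add(name)
            out.parameters[name] = Parameter(id=name, value=value, constant=True)
            renames[pid] = SymbolRef(name)
        rxn.kinetic_law = substitute(rxn.kinetic_law, renames)
        rxn.local_parameters = {}
    return out


# ---------------------------------------------------------------------------
# initial assignments

def _toposort_assignments(model: Model) -> list[str]:
    targets = set(model.initial_assignments)
    deps = {
        t: free_symbols(ia.math) & targets
        for t, ia in model.initial_assignments.items()
    }
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(t: str, stack: list[str]):
        if state.get(t) == 2:
            return
        if state.get(t) == 1:
            raise ResolutionError(
                "cyclic initialAssignment dependency: " + " -> ".join(stack + [t]))
        state[t] = 1
        for d in sorted(deps[t]):
            visit(d, stack + [t])
        state[t] = 2
        order.append(t)

    for t in model.initial_assignments:
        visit(t, [])
    return order


def _assignment_env(model: Model) -> dict[str, float]:
    env: dict[str, float] = {}
    for c in model.compartments.values():
        if c.size is not None:
            env[c.id] = c.size
    for p in model.parameters.values():
        if p.value is not None:
            env[p.id] = p.value
    for s in model.species.values():
        if s.initial_amount is not None:
            env[s.id] = s.initial_amount
    return env


def _validate_assignment_symbols(model: Model) -> None:
    targets = set(model.initial_assignments)
    for t, ia in model.initial_assignments.items():
        for sid in free_symbols(ia.math) - {TIME_ID} - targets:
            ent = model.entity(sid)
            if ent is None:
                raise ResolutionError(
                    f"initialAssignment for {t!r} references unknown symbol {sid!r}")
            sp = model.species.get(sid)
            if sp is not None and not sp.constant and not sp.boundary_condition:
                raise ResolutionError(
                    f"initialAssignment for {t!r} references dynamic species {sid!r}")


def evaluate_initial_assignments(model: Model) -> dict[str, float]:
    """Numeric value of every initial-assignment target at t=0, evaluated in
    dependency (topological) order.  Function calls still present in the
    assignment math are expanded on the fly."""
    _validate_assignment_symbols(model)
    order = _toposort_assignments(model)
    env = _assignment_env(model)
    defs = model.function_definitions
    values: dict[str, float] = {}
    for t in order:
        node = model.initial_assignments[t].math
        if defs:
            node = _expand_calls(node, defs)
        values[t] = float(evaluate_math(node, env, t=0.0))
        env[t] = values[t]
    return values


def apply_initial_assignments(model: Model, mode: str = "symbolic") -> Model:
    """Handle initialAssignments, which override declared initial values.

    ``mode="hardcode"``: each target's initial value is replaced by the
    numeric evaluation of its assignment at t=0 and the assignment removed;
    the model loses any dependence of initial state on the referenced
    parameters.  ``mode="symbolic"``: assignments are validated and kept on
    the model for resolution at compile time, so parameter changes keep
    propagating.
    """
    if mode not in ("hardcode", "symbolic"):
        raise ValueError(f"mode must be 'hardcode' or 'symbolic', got {mode!r}")
    out = model.copy()
    if not out.initial_assignments:
        return out
    if mode == "symbolic":
        _validate_assignment_symbols(out)
        _toposort_assignments(out)  # cycle check
        return out
    values = evaluate_initial_assignments(out)
    for target, value in values.items():
        sp = out.species.get(target)
        if sp is not None:
            sp.initial_amount = value
            sp.initial_concentration = None
            continue
        p = out.parameters.get(target)
        if p is not None:
            p.value = value
            continue
        c = out.compartments.get(target)
        if c is not None:
            c.size = value
            continue
        raise ResolutionError(f"initialAssignment targets unknown entity {target!r}")
    out.initial_assignments = {}
    return out


# ---------------------------------------------------------------------------
# presets

def preset_simplify_math(model: Model) -> Model:
    """Hard-code initial assignments, promote locals, expand functions."""
    return expand_functions(
        promote_local_parameters(
            apply_initial_assignments(model, mode="hardcode")))


def preset_promotelocals_expandfuns(model: Model) -> Model:
    """Promote locals and expand functions, keeping initial assignments
    symbolic (recommended when parameters will be estimated)."""
    return expand_functions(
        promote_local_parameters(
            apply_initial_assignments(model, mode="symbolic")))
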