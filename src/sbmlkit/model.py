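"""In-memory image of one SBML document (dynamic core only).

The types mirror the anatomy of an SBML file — compartments, species,
parameters, reactions with kinetic laws, function definitions, initial
assignments, rules and events — keyed by id with document order preserved
(Python dicts preserve insertion order).  Units, annotations and notes are
deliberately absent: this model targets dynamics, not document fidelity.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

from .errors import SerializationError
from .expressions import MathNode, free_symbols, TIME_ID


@dataclass
class Compartment:
    id: str
    size: float | None = None
    constant: bool = True
    spatial_dimensions: int = 3


@dataclass
class Species:
    id: str
    compartment: str
    initial_amount: float | None = None
    initial_concentration: float | None = None
    boundary_condition: bool = False
    constant: bool = False
    has_only_substance_units: bool = False


@dataclass
class Parameter:
    id: str
    value: float | None = None
    constant: bool = True


@dataclass
class Reaction:
    id: str
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    reversible: bool = False
    kinetic_law: MathNode | None = None
    local_parameters: dict[str, float] = field(default_factory=dict)


@dataclass
class FunctionDefinition:
    id: str
    arguments: list[str]
    body: MathNode


@dataclass
class InitialAssignment:
    target: str  # species, parameter or compartment id
    math: MathNode


@dataclass
class AssignmentRule:
    variable: str
    math: MathNode


@dataclass
class RateRule:
    variable: str
    math: MathNode


@dataclass
class AlgebraicRule:
    math: MathNode  # residual; must equal zero at all times


Rule = AssignmentRule | RateRule | AlgebraicRule


@dataclass
class Event:
    id: str
    trigger: MathNode
    assignments: list[tuple[str, MathNode]]
    has_delay: bool = False  # delay element present; fatal at support check


@dataclass
class Model:
    level: int = 3
    version: int = 2
    compartments: dict[str, Compartment] = field(default_factory=dict)
    species: dict[str, Species] = field(default_factory=dict)
    parameters: dict[str, Parameter] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    function_definitions: dict[str, FunctionDefinition] = field(default_factory=dict)
    initial_assignments: dict[str, InitialAssignment] = field(default_factory=dict)
    rules: list[Rule] = field(default_factory=list)
    events: dict[str, Event] = field(default_factory=dict)
    # features recorded at read time for support checking
    constraints: list[MathNode] = field(default_factory=list)
    stoichiometry_reference_ids: set[str] = field(default_factory=set)

    # -- convenience -------------------------------------------------------
    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def global_ids(self) -> set[str]:
        return (
            set(self.compartments)
            | set(self.species)
            | set(self.parameters)
            | set(self.reactions)
            | set(self.function_definitions)
        )

    def entity(self, eid: str):
        """The compartment, species or parameter with this id, else None."""
        return (
            self.species.get(eid)
            or self.parameters.get(eid)
            or self.compartments.get(eid)
        )

    def iter_math(self):
        """Yield (location, kind, MathNode) for every math expression."""
        for r in self.reactions.values():
            if r.kinetic_law is not None:
                yield r.id, "kinetic_law", r.kinetic_law
        for f in self.function_definitions.values():
            yield f.id, "function_body", f.body
        for ia in self.initial_assignments.values():
            yield ia.target, "initial_assignment", ia.math
        for i, rule in enumerate(self.rules):
            loc = getattr(rule, "variable", f"algebraic[{i}]")
            yield loc, type(rule).__name__, rule.math
        for ev in self.events.values():
            yield ev.id, "trigger", ev.trigger
            for var, m in ev.assignments:
                yield f"{ev.id}:{var}", "event_assignment", m
        for i, c in enumerate(self.constraints):
            yield f"constraint[{i}]", "constraint", c

    def map_math(self, fn) -> None:
        """Apply ``fn`` to every math expression, in place."""
        for r in self.reactions.values():
            if r.kinetic_law is not None:
                r.kinetic_law = fn(r.kinetic_law)
        for f in self.function_definitions.values():
            f.body = fn(f.body)
        for ia in self.initial_assignments.values():
            ia.math = fn(ia.math)
        for rule in self.rules:
            rule.math = fn(rule.math)
        for ev in self.events.values():
            ev.trigger = fn(ev.trigger)
            ev.assignments = [(v, fn(m)) for v, m in ev.assignments]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check cross-references, uniqueness and finiteness.

        Raises :class:`SerializationError` on the first violation (this is
        the writer's gate; the reader enforces the same rules while
        building the model).
        """
        seen: set[str] = set()
        for group in (self.compartments, self.species, self.parameters,
                      self.reactions, self.function_definitions):
            for eid in group:
                if eid in seen:
                    raise SerializationError(f"duplicate global id {eid!r}")
                seen.add(eid)
        for c in self.compartments.values():
            if c.size is not None and not math.isfinite(c.size):
                raise SerializationError(f"compartment {c.id!r} has non-finite size")
        for s in self.species.values():
            if s.compartment not in self.compartments:
                raise SerializationError(
                    f"species {s.id!r} references unknown compartment {s.compartment!r}")
            if s.initial_amount is not None and s.initial_concentration is not None:
                raise SerializationError(
                    f"species {s.id!r} sets both initialAmount and initialConcentration")
        for r in self.reactions.values():
            for sp, st in r.reactants + r.products:
                if sp not in self.species:
                    raise SerializationError(
                        f"reaction {r.id!r} references unknown species {sp!r}")
                if not (st > 0 and math.isfinite(st)):
                    raise SerializationError(
                        f"reaction {r.id!r}: stoichiometry of {sp!r} must be positive and finite")
        for f in self.function_definitions.values():
            extra = free_symbols(f.body) - set(f.arguments) - {TIME_ID}
            # calls to other functions appear as Apply ops, not symbols
            if extra:
                raise SerializationError(
                    f"function {f.id!r} body uses symbols outside its arguments: {sorted(extra)}")
        rule_targets: set[str] = set()
        for rule in self.rules:
            var = getattr(rule, "variable", None)
            if var is None:
                continue
            if var in rule_targets:
                raise SerializationError(f"{var!r} is the target of more than one rule")
            rule_targets.add(var)
            if self.entity(var) is None:
                raise SerializationError(f"rule targets unknown entity {var!r}")
        for ia in self.initial_assignments.values():
            if self.entity(ia.target) is None and \
                    ia.target not in self.stoichiometry_reference_ids:
                raise SerializationError(
                    f"initial assignment targets unknown entity {ia.target!r}")
        for ev in self.events.values():
            if not ev.assignments:
                raise SerializationError(f"event {ev.id!r} has no assignments")
            for var, _ in ev.assignments:
                if self.entity(var) is None:
                    raise SerializationError(
                        f"event {ev.id!r} assigns unknown entity {var!r}")
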