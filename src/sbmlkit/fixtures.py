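"""Programmatic SBML fixtures with known reference behavior.

Each builder returns a :class:`Fixture` holding the SBML text, the
parameters used, and a short description of the analytic reference the model
satisfies (closed forms chosen so the checks are simple: an exponential
decay read off at ``e^{-1}``, an event sawtooth with period ``ln 2``, linear
growth from a boundary species, the stationary mean ``lambda/mu`` of an
immigration-death process).  Everything is generated in memory; no file or
download is ever needed.

Builders default to Level 3 Version 2; ``level=(2, 4)`` emits Level 2
Version 4 documents with defaulted attributes omitted, to exercise level
harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expressions import Apply, Number, SymbolRef, apply, num, sym
from .io import write_sbml
from .model import (
    AssignmentRule, Compartment, Event, FunctionDefinition, InitialAssignment,
    Model, Parameter, RateRule, Reaction, Species,
)

L3V2 = (3, 2)
L2V4 = (2, 4)


@dataclass
class Fixture:
    name: str
    sbml_text: str
    reference: str
    parameters: dict = field(default_factory=dict)
    model: Model | None = None


def _base_model(level=L3V2) -> Model:
    m = Model(level=level[0], version=level[1])
    m.compartments["c"] = Compartment(id="c", size=1.0, constant=True)
    return m


def _species(sid, amount, hosu=True, boundary=False, constant=False,
             compartment="c") -> Species:
    return Species(id=sid, compartment=compartment, initial_amount=amount,
                   boundary_condition=boundary, constant=constant,
                   has_only_substance_units=hosu)


def _finish(name, model, reference, params, level) -> Fixture:
    return Fixture(name=name, sbml_text=write_sbml(model, level=level),
                   reference=reference, parameters=params, model=model)


def make_decay(k: float = 0.5, a0: float = 10.0, level=L3V2) -> Fixture:
    """A -> 0 with mass-action law k*A; A(t) = a0 * exp(-k t)."""
    if not k > 0:
        raise ValueError("k must be positive")
    if a0 < 0:
        raise ValueError("a0 must be non-negative")
    m = _base_model(level)
    m.species["A"] = _species("A", a0)
    m.parameters["k"] = Parameter("k", k, constant=True)
    m.reactions["decay"] = Reaction(
        id="decay", reactants=[("A", 1.0)], products=[], reversible=False,
        kinetic_law=apply("times", sym("k"), sym("A")))
    return _finish("decay", m, f"A(t) = {a0} * exp(-{k} t)",
                   {"k": k, "a0": a0}, level)


def make_reversible_binding(k1: float = 1.0, k2: float = 0.5, a0: float = 4.0,
                            b0: float = 3.0, c0: float = 0.0,
                            splittable: bool = True, level=L3V2) -> Fixture:
    """A + B <-> C with law k1*A*B - k2*C (a top-level difference).

    ``splittable=False`` wraps the law in a multiplication by 1, which is
    algebraically identical but not a top-level difference, so the compiler
    falls back to a single net-rate channel.  A+C and B+C are conserved;
    the equilibrium satisfies C/(A*B) = k1/k2.
    """
    if not (k1 > 0 and k2 > 0):
        raise ValueError("rates must be positive")
    m = _base_model(level)
    m.species["A"] = _species("A", a0)
    m.species["B"] = _species("B", b0)
    m.species["C"] = _species("C", c0)
    m.parameters["k1"] = Parameter("k1", k1, constant=True)
    m.parameters["k2"] = Parameter("k2", k2, constant=True)
    law = apply("minus",
                apply("times", sym("k1"), sym("A"), sym("B")),
                apply("times", sym("k2"), sym("C")))
    if not splittable:
        law = apply("times", num(1.0), law)
    m.reactions["binding"] = Reaction(
        id="binding", reactants=[("A", 1.0), ("B", 1.0)], products=[("C", 1.0)],
        reversible=True, kinetic_law=law)
    return _finish("reversible_binding" if splittable else "reversible_binding_netrate", m,
                   "A+C and B+C conserved; C/(A*B) -> k1/k2 at equilibrium",
                   {"k1": k1, "k2": k2, "a0": a0, "b0": b0, "c0": c0,
                    "splittable": splittable}, level)


def make_mm_with_functiondef(vmax: float = 1.0, km: float = 0.5,
                             s0: float = 2.0, level=L3V2) -> Fixture:
    """S -> P with a Michaelis-Menten law defined in listOfFunctions and
    Vmax/Km as reaction-local parameters; exercises function expansion and
    local-parameter promotion.  dS/dt(0) = -vmax*s0/(km+s0)."""
    if not (vmax > 0 and km > 0 and s0 > 0):
        raise ValueError("all parameters must be positive")
    m = _base_model(level)
    m.species["S"] = _species("S", s0)
    m.species["P"] = _species("P", 0.0)
    m.function_definitions["mm"] = FunctionDefinition(
        id="mm", arguments=["s", "v", "k"],
        body=apply("divide", apply("times", sym("v"), sym("s")),
                   apply("plus", sym("k"), sym("s"))))
    m.reactions["conv"] = Reaction(
        id="conv", reactants=[("S", 1.0)], products=[("P", 1.0)],
        reversible=False,
        kinetic_law=apply("mm", sym("S"), sym("Vmax"), sym("Km")),
        local_parameters={"Vmax": vmax, "Km": km})
    return _finish("mm_functiondef", m,
                   f"dS/dt(0) = -{vmax}*{s0}/({km}+{s0})",
                   {"vmax": vmax, "km": km, "s0": s0}, level)


def make_event_model(level=L3V2) -> Fixture:
    """Exponential volume growth dVol/dt = Vol from Vol(0)=Vol_init=1 with
    an event Vol >= 2*Vol_init resetting Vol := Vol_init.

    The event first fires at t = ln 2 and repeats with period ln 2
    (a sawtooth)."""
    m = _base_model(level)
    m.parameters["Vol"] = Parameter("Vol", 1.0, constant=False)
    m.parameters["Vol_init"] = Parameter("Vol_init", 1.0, constant=True)
    m.rules.append(RateRule("Vol", sym("Vol")))
    m.events["doubling"] = Event(
        id="doubling",
        trigger=apply("geq", sym("Vol"),
                      apply("times", num(2.0), sym("Vol_init"))),
        assignments=[("Vol", sym("Vol_init"))])
    return _finish("event_sawtooth", m,
                   "first firing at t = ln 2; period ln 2", {}, level)


def make_decreasing_event_model(level=L3V2) -> Fixture:
    """Mirrored variant: exponential decay dVol/dt = -Vol from Vol(0)=1 with
    trigger Vol <= Vol_init/2 and reset Vol := Vol_init; the residual
    crosses zero downward, so a direction-sensitive (false-to-true only)
    rule would behave identically here, but an upward re-crossing after the
    reset must also fire under the direction-agnostic convention."""
    m = _base_model(level)
    m.parameters["Vol"] = Parameter("Vol", 1.0, constant=False)
    m.parameters["Vol_init"] = Parameter("Vol_init", 1.0, constant=True)
    m.rules.append(RateRule("Vol", apply("minus", sym("Vol"))))
    m.events["halving"] = Event(
        id="halving",
        trigger=apply("leq", sym("Vol"),
                      apply("divide", sym("Vol_init"), num(2.0))),
        assignments=[("Vol", sym("Vol_init"))])
    return _finish("event_sawtooth_down", m,
                   "first firing at t = ln 2; period ln 2", {}, level)


def make_boundary_model(k: float = 0.3, s_const: float = 2.0, level=L3V2) -> Fixture:
    """Boundary species S consumed by S -> P at rate k*S while an assignment
    rule pins S := s_const; rules override reactions for boundary species,
    so S stays constant and P(t) = k*s_const*t exactly."""
    m = _base_model(level)
    m.species["S"] = _species("S", s_const, boundary=True)
    m.species["P"] = _species("P", 0.0)
    m.parameters["k"] = Parameter("k", k, constant=True)
    m.parameters["s_const"] = Parameter("s_const", s_const, constant=True)
    m.rules.append(AssignmentRule("S", sym("s_const")))
    m.reactions["feed"] = Reaction(
        id="feed", reactants=[("S", 1.0)], products=[("P", 1.0)],
        reversible=False, kinetic_law=apply("times", sym("k"), sym("S")))
    return _finish("boundary", m, f"S constant; P(t) = {k}*{s_const}*t",
                   {"k": k, "s_const": s_const}, level)


def make_initial_assignment_model(a_attr: float = 1.0, k: float = 3.0,
                                  kd: float = 0.5, level=L3V2) -> Fixture:
    """Decay model whose species carries initialAmount ``a_attr`` but is
    overridden by the initialAssignment A := 2*k; the compiled initial
    state must be 2*k, not the attribute value."""
    m = _base_model(level)
    m.species["A"] = _species("A", a_attr)
    m.parameters["k"] = Parameter("k", k, constant=True)
    m.parameters["kd"] = Parameter("kd", kd, constant=True)
    m.initial_assignments["A"] = InitialAssignment(
        "A", apply("times", num(2.0), sym("k")))
    m.reactions["decay"] = Reaction(
        id="decay", reactants=[("A", 1.0)], products=[], reversible=False,
        kinetic_law=apply("times", sym("kd"), sym("A")))
    return _finish("initial_assignment", m,
                   f"compiled A(0) = 2*k = {2 * k}, not {a_attr}",
                   {"a_attr": a_attr, "k": k, "kd": kd}, level)


def make_immigration_death(lam: float = 10.0, mu: float = 1.0,
                           a0: float = 0.0, level=L3V2) -> Fixture:
    """0 -> A at constant rate lambda, A -> 0 at rate mu*A (M/M/infinity).

    The stationary mean is lambda/mu; the transient mean is
    (lambda/mu)(1 - exp(-mu t)) from A(0)=0."""
    if not (lam > 0 and mu > 0):
        raise ValueError("rates must be positive")
    m = _base_model(level)
    m.species["A"] = _species("A", a0)
    m.parameters["lam"] = Parameter("lam", lam, constant=True)
    m.parameters["mu"] = Parameter("mu", mu, constant=True)
    m.reactions["immigration"] = Reaction(
        id="immigration", reactants=[], products=[("A", 1.0)],
        reversible=False, kinetic_law=sym("lam"))
    m.reactions["death"] = Reaction(
        id="death", reactants=[("A", 1.0)], products=[], reversible=False,
        kinetic_law=apply("times", sym("mu"), sym("A")))
    return _finish("immigration_death", m,
                   f"stationary mean A = lambda/mu = {lam / mu}",
                   {"lam": lam, "mu": mu, "a0": a0}, level)


def make_unsupported_models(level=L3V2) -> list[Fixture]:
    """One fixture per screened-out feature: a factorial in a kinetic law, a
    delay csymbol in a kinetic law, and a constraint element.  Each must
    produce exactly one fatal support finding with the matching tag."""
    out = []

    m = _base_model(level)
    m.species["A"] = _species("A", 5.0)
    m.parameters["k"] = Parameter("k", 0.1, constant=True)
    m.reactions["weird"] = Reaction(
        id="weird", reactants=[("A", 1.0)], products=[], reversible=False,
        kinetic_law=apply("times", sym("k"),
                          Apply("factorial", (sym("A"),))))
    out.append(_finish("unsupported_factorial", m,
                       "check_support -> fatal(factorial)", {}, level))

    m = _base_model(level)
    m.species["A"] = _species("A", 5.0)
    m.parameters["k"] = Parameter("k", 0.1, constant=True)
    m.parameters["tau"] = Parameter("tau", 1.0, constant=True)
    m.reactions["delayed"] = Reaction(
        id="delayed", reactants=[("A", 1.0)], products=[], reversible=False,
        kinetic_law=apply("times", sym("k"),
                          Apply("delay", (sym("A"), sym("tau")))))
    out.append(_finish("unsupported_delay", m,
                       "check_support -> fatal(delay)", {}, level))

    m = make_decay(level=level).model.copy()
    m.constraints.append(apply("geq", sym("A"), num(0.0)))
    out.append(Fixture("unsupported_constraint", write_sbml(m, level=level),
                       "check_support -> fatal(constraint)", {}, m))
    return out


def all_supported_fixtures(level=L3V2) -> list[Fixture]:
    return [
        make_decay(level=level),
        make_reversible_binding(level=level),
        make_reversible_binding(splittable=False, level=level),
        make_mm_with_functiondef(level=level),
        make_event_model(level=level),
        make_decreasing_event_model(level=level),
        make_boundary_model(level=level),
        make_initial_assignment_model(level=level),
        make_immigration_death(level=level),
    ]


def all_fixtures(level=L3V2) -> list[Fixture]:
    return all_supported_fixtures(level) + make_unsupported_models(level)


def write_fixture_files(out_dir) -> list[str]:
    """Materialize every fixture as an .xml file; returns the paths."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for fx in all_fixtures():
        path = os.path.join(out_dir, f"{fx.name}.xml")
        with open(path, "w") as fh:
            fh.write(fx.sbml_text)
        paths.append(path)
    return paths
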