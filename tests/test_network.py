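"""Network compilation: classification, splitting, amounts convention,
event residuals, boundary semantics."""

import numpy as np
import pytest
import sympy

import sbmlkit as sk
from sbmlkit import fixtures
from sbmlkit.expressions import Apply, Number, Piecewise, SymbolRef, TimeSymbol, apply, num, sym
from sbmlkit.model import (
    AlgebraicRule, AssignmentRule, Event, Parameter, RateRule, Reaction, Species,
)
from conftest import parse, network_for


# ---------------------------------------------------------------------------
# classification

def test_decay_classification():
    states, constants, observed = sk.classify_entities(parse(fixtures.make_decay()))
    assert states == ["A"]
    assert constants == {"k": 0.5, "c": 1.0}
    assert observed == []


def test_rate_rule_parameter_becomes_state():
    model = parse(fixtures.make_event_model())
    states, constants, _ = sk.classify_entities(model)
    assert "Vol" in states
    assert "Vol_init" in constants


def test_boundary_species_with_rule_is_observed_and_flux_discarded():
    model = parse(fixtures.make_boundary_model())
    states, _, observed = sk.classify_entities(model)
    assert observed == ["S"]
    assert states == ["P"]
    net = sk.compile_network(model)
    for r in net.reactions:
        assert "S" not in r.net_stoichiometry


def test_constant_entity_targeted_by_rule_conflicts():
    model = parse(fixtures.make_boundary_model())
    model.species["S"].constant = True
    with pytest.raises(sk.ConflictError, match="constant"):
        sk.classify_entities(model)


def test_non_boundary_species_in_reaction_and_rule_conflicts():
    model = parse(fixtures.make_boundary_model())
    model.species["S"].boundary_condition = False
    with pytest.raises(sk.ConflictError, match="both reactions and rules"):
        sk.classify_entities(model)


def test_classification_is_a_partition_covering_compiled_math():
    for fx in fixtures.all_supported_fixtures():
        model = sk.preset_promotelocals_expandfuns(parse(fx))
        states, constants, observed = sk.classify_entities(model)
        assert not set(states) & set(constants)
        assert not set(states) & set(observed)
        assert not set(constants) & set(observed)
        net = sk.compile_network(model)
        known = set(states) | set(constants) | set(observed) | \
            {v for _, v in net.algebraic_rules} | {sk.TIME_ID}
        for r in net.reactions:
            assert sk.free_symbols(r.rate) <= known


# ---------------------------------------------------------------------------
# reversible splitting

def test_top_level_difference_splits():
    model = parse(fixtures.make_reversible_binding())
    channels, warns = sk.split_reversible(model.reactions["binding"])
    assert not warns
    assert [c.source[1] for c in channels] == ["forward", "reverse"]
    fwd, rev = channels
    assert fwd.net_stoichiometry == {"C": 1.0, "A": -1.0, "B": -1.0}
    assert rev.net_stoichiometry == {"C": -1.0, "A": 1.0, "B": 1.0}
    assert fwd.rate == apply("times", sym("k1"), sym("A"), sym("B"))
    assert rev.rate == apply("times", sym("k2"), sym("C"))


def test_irreversible_reaction_single_channel():
    model = parse(fixtures.make_decay())
    channels, warns = sk.split_reversible(model.reactions["decay"])
    assert len(channels) == 1 and not warns
    assert channels[0].net_stoichiometry == {"A": -1.0}
    assert channels[0].source == ("decay", "irreversible")


def test_unsplittable_reversible_falls_back_to_net_rate():
    model = parse(fixtures.make_reversible_binding(splittable=False))
    channels, warns = sk.split_reversible(model.reactions["binding"])
    assert len(channels) == 1
    assert channels[0].stochastic_ok is False
    assert warns and "net-rate" in warns[0]


def test_split_vs_netrate_trajectories_coincide(binding_nets):
    split, unsplit = binding_nets
    assert len(split.reactions) == 2
    assert len(unsplit.reactions) == 1
    t1 = sk.simulate_ode(split, (0, 10))
    t2 = sk.simulate_ode(unsplit, (0, 10))
    scale = np.abs(t1.states) + 1e-12
    assert np.max(np.abs(t1.states - t2.states) / scale) < 1e-8


def _to_sympy(node):
    if isinstance(node, Number):
        return sympy.Float(node.value)
    if isinstance(node, SymbolRef):
        return sympy.Symbol(node.id)
    if isinstance(node, TimeSymbol):
        return sympy.Symbol("__t")
    if isinstance(node, Apply):
        args = [_to_sympy(a) for a in node.args]
        op = node.op
        if op == "plus":
            return sympy.Add(*args)
        if op == "times":
            return sympy.Mul(*args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
    raise NotImplementedError(node)


def test_split_ode_equals_unsplit_ode_symbolically(binding_nets):
    """Independent symbolic oracle: the stoichiometry-weighted rate sums of
    the split and net-rate compilations are the same expressions."""
    split, unsplit = binding_nets
    for sid in split.states:
        def rhs(net):
            return sympy.simplify(sympy.Add(*[
                r.net_stoichiometry.get(sid, 0) * _to_sympy(r.rate)
                for r in net.reactions]))
        assert sympy.simplify(rhs(split) - rhs(unsplit)) == 0


# ---------------------------------------------------------------------------
# amounts convention

def test_substance_units_species_stays_bare():
    model = parse(fixtures.make_decay())
    law = model.reactions["decay"].kinetic_law
    assert sk.resolve_species_symbols(law, model) == law


def test_concentration_species_divided_by_compartment():
    model = parse(fixtures.make_decay())
    model.compartments["c"].size = 2.0
    model.species["A"].has_only_substance_units = False
    law = sk.resolve_species_symbols(model.reactions["decay"].kinetic_law, model)
    assert law == apply("times", sym("k"),
                        apply("divide", sym("A"), sym("c")))
    # trajectory oracle: dA/dt = -k*A/2  =>  A(t) = a0*exp(-k t/2)
    net = sk.compile_network(model)
    traj = sk.simulate_ode(net, (0, 4))
    expected = 10.0 * np.exp(-0.5 * traj.times / 2.0)
    assert np.allclose(traj.state("A"), expected, rtol=1e-7)


def test_math_without_species_unchanged():
    model = parse(fixtures.make_decay())
    expr = apply("plus", sym("k"), num(1))
    assert sk.resolve_species_symbols(expr, model) is not expr  # rebuilt tree
    assert sk.resolve_species_symbols(expr, model) == expr


# ---------------------------------------------------------------------------
# events

def test_trigger_residual_sign_conventions():
    model = parse(fixtures.make_event_model())
    events, warnings = sk.compile_events(model)
    assert events[0].residual == apply(
        "minus", sym("Vol"), apply("times", num(2), sym("Vol_init")))
    assert len(warnings) == 1 and "EITHER direction" in warnings[0]

    model.events["doubling"].trigger = apply("leq", sym("Vol"), sym("Vol_init"))
    events, _ = sk.compile_events(model)
    assert events[0].residual == apply("minus", sym("Vol_init"), sym("Vol"))


def test_compound_and_non_relational_triggers_rejected():
    model = parse(fixtures.make_event_model())
    model.events["doubling"].trigger = apply(
        "and", apply("gt", sym("Vol"), num(1)), apply("gt", sym("Vol_init"), num(1)))
    with pytest.raises(sk.UnsupportedFeatureError, match="Boolean"):
        sk.compile_events(model)
    model.events["doubling"].trigger = apply("eq", sym("Vol"), num(2))
    with pytest.raises(sk.UnsupportedFeatureError, match="relational"):
        sk.compile_events(model)


# ---------------------------------------------------------------------------
# full compilation

def test_decay_network_shape(decay_net):
    assert decay_net.states == ["A"]
    assert set(decay_net.constants) == {"k", "c"}
    assert len(decay_net.reactions) == 1
    assert not decay_net.rate_rules and not decay_net.events


def test_assignment_rule_overrides_initial_value():
    model = parse(fixtures.make_decay())
    model.species["B"] = Species("B", "c", initial_amount=99.0,
                                 has_only_substance_units=True)
    model.rules.append(AssignmentRule("B", apply("times", num(2), sym("A"))))
    model.species["A"].initial_amount = 3.0
    net = sk.compile_network(model)
    assert net.observed_initial["B"] == 6.0


def test_compile_refuses_unnormalized_model():
    mm = parse(fixtures.make_mm_with_functiondef())
    with pytest.raises(sk.ResolutionError, match="expand_functions"):
        sk.compile_network(mm)
    with pytest.raises(sk.ResolutionError, match="promote_local_parameters"):
        sk.compile_network(sk.expand_functions(mm))


def test_compile_refuses_fatal_support_findings():
    model = parse(fixtures.make_unsupported_models()[0])
    with pytest.raises(sk.UnsupportedFeatureError):
        sk.compile_network(model)


def test_boundary_species_has_zero_stoichiometry_everywhere():
    # boundary species consumed AND produced by several reactions
    model = parse(fixtures.make_boundary_model())
    model.reactions["r2"] = Reaction(
        "r2", [("P", 1.0)], [("S", 2.0)], False,
        apply("times", sym("k"), sym("P")))
    net = sk.compile_network(model)
    for r in net.reactions:
        assert r.net_stoichiometry.get("S", 0.0) == 0.0


def test_algebraic_rule_single_unknown_solved():
    model = parse(fixtures.make_decay())
    model.parameters["x"] = Parameter("x", None, constant=False)
    model.rules.append(AlgebraicRule(
        apply("minus", sym("x"), apply("times", num(2), sym("A")))))
    net = sk.compile_network(model)
    assert net.algebraic_rules[0][1] == "x"
    assert net.algebraic_initial["x"] == pytest.approx(20.0)  # 2 * A(0)
    traj = sk.simulate_ode(net, (0, 2))
    assert np.allclose(traj.state("x"), 2 * traj.state("A"), rtol=1e-6)


def test_algebraic_rule_with_two_unknowns_rejected():
    model = parse(fixtures.make_decay())
    model.parameters["x"] = Parameter("x", None, constant=False)
    model.parameters["y"] = Parameter("y", None, constant=False)
    model.rules.append(AlgebraicRule(
        apply("minus", sym("x"), sym("y"))))
    rep = sk.check_support(model)
    assert "algebraic-rule" in [f.feature for f in rep.fatal]
    with pytest.raises(sk.UnsupportedFeatureError):
        sk.compile_network(model)


def test_network_dump_is_json_ready(binding_nets):
    import json
    split, _ = binding_nets
    dump = sk.network_to_dict(split)
    text = json.dumps(dump)
    assert "binding_fwd" in text and "binding_rev" in text
    assert len(dump["reactions"]) == 2
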