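"""Normalization passes: support checking, level harmonization, function
expansion, local-parameter promotion, initial assignments, presets."""

import random

import pytest

import sbmlkit as sk
from sbmlkit import fixtures
from sbmlkit.expressions import apply, num, sym, evaluate_math
from sbmlkit.model import FunctionDefinition, InitialAssignment, Parameter
from conftest import parse


def test_clean_model_has_empty_report():
    rep = sk.check_support(parse(fixtures.make_decay()))
    assert rep.ok and not rep.findings


def test_factorial_is_fatal():
    model = parse(fixtures.make_decay())
    model.reactions["decay"].kinetic_law = apply(
        "times", sym("k"), sk.Apply("factorial", (sym("A"),)))
    rep = sk.check_support(model)
    assert [f.feature for f in rep.fatal] == ["factorial"]


def test_event_model_gets_exactly_one_warning():
    rep = sk.check_support(parse(fixtures.make_event_model()))
    assert rep.ok
    assert [f.feature for f in rep.warnings] == ["event-directionality"]


def test_non_integer_stoichiometry_warns():
    model = parse(fixtures.make_decay())
    model.reactions["decay"].reactants = [("A", 1.5)]
    rep = sk.check_support(model)
    assert rep.ok
    assert "non-integer-stoichiometry" in [f.feature for f in rep.findings]


def test_stoichiometry_assignment_is_fatal():
    model = parse(fixtures.make_decay())
    model.stoichiometry_reference_ids.add("sr1")
    model.initial_assignments["sr1"] = InitialAssignment("sr1", num(2))
    rep = sk.check_support(model)
    assert "stoichiometry-assignment" in [f.feature for f in rep.fatal]


def test_check_support_is_pure():
    model = parse(fixtures.make_event_model())
    snapshot = model.copy()
    sk.check_support(model)
    assert model == snapshot


# ---------------------------------------------------------------------------
# level/version

def test_set_level_and_version():
    l2 = parse(fixtures.make_decay(level=fixtures.L2V4))
    out = sk.set_level_and_version(l2, 3, 2)
    assert (out.level, out.version) == (3, 2)
    # semantics already materialized at read: explicit flags survive
    assert out.species["A"].has_only_substance_units is True

    l3 = parse(fixtures.make_decay())
    assert sk.set_level_and_version(l3, 3, 2) == l3  # fixed point

    l3v1 = l3.copy()
    l3v1.version = 1
    out = sk.set_level_and_version(l3v1, 3, 2)
    assert out.version == 2 and out.level == 3

    with pytest.raises(sk.UnsupportedFeatureError):
        sk.set_level_and_version(l3, 2, 4)


def test_l2_defaults_materialized_against_specification_table():
    # oracle: the L2 attribute-default table (species flags false,
    # parameter constant true, reaction reversible true)
    text = fixtures.make_decay(level=fixtures.L2V4).sbml_text
    assert "hasOnlySubstanceUnits" in text  # true is non-default, so written
    model, _ = sk.read_sbml(text)
    out = sk.set_level_and_version(model, 3, 2)
    assert out.parameters["k"].constant is True
    assert out.species["A"].boundary_condition is False


# ---------------------------------------------------------------------------
# function expansion

def test_expand_single_function():
    model = parse(fixtures.make_mm_with_functiondef())
    out = sk.expand_functions(model)
    assert not out.function_definitions
    law = out.reactions["conv"].kinetic_law
    assert law == apply("divide", apply("times", sym("Vmax"), sym("S")),
                        apply("plus", sym("Km"), sym("S")))


def test_expand_nested_functions_against_random_point_oracle():
    # f(x) = g(x) + 1, g(x) = 2x; expanding f(S) must equal 2S + 1
    model = parse(fixtures.make_decay())
    model.function_definitions["g"] = FunctionDefinition(
        "g", ["x"], apply("times", num(2), sym("x")))
    model.function_definitions["f"] = FunctionDefinition(
        "f", ["x"], apply("plus", apply("g", sym("x")), num(1)))
    model.reactions["decay"].kinetic_law = apply("f", sym("A"))
    out = sk.expand_functions(model)
    law = out.reactions["decay"].kinetic_law
    rng = random.Random(0)
    for _ in range(10):
        a = rng.uniform(-50, 50)
        assert evaluate_math(law, {"A": a}) == pytest.approx(2 * a + 1)


def test_expand_is_identity_without_functions_and_idempotent():
    model = parse(fixtures.make_decay())
    assert sk.expand_functions(model) == model
    mm = parse(fixtures.make_mm_with_functiondef())
    once = sk.expand_functions(mm)
    assert sk.expand_functions(once) == once


def test_recursive_functions_rejected():
    model = parse(fixtures.make_decay())
    model.function_definitions["f"] = FunctionDefinition(
        "f", ["x"], apply("f", sym("x")))
    with pytest.raises(sk.UnsupportedFeatureError, match="recursive"):
        sk.expand_functions(model)


def test_arity_mismatch_rejected():
    model = parse(fixtures.make_mm_with_functiondef())
    model.reactions["conv"].kinetic_law = apply("mm", sym("S"))
    with pytest.raises(sk.ResolutionError, match="argument"):
        sk.expand_functions(model)


# ---------------------------------------------------------------------------
# local-parameter promotion

def test_promotion_renames_and_preserves_trajectory():
    import numpy as np
    mm = parse(fixtures.make_mm_with_functiondef())
    promoted = sk.promote_local_parameters(mm)
    assert promoted.parameters["conv_Vmax"].value == 1.0
    assert not promoted.reactions["conv"].local_parameters
    # oracle: hand-built equivalent with global parameters simulates the same
    vmax, km, s0 = 1.0, 0.5, 2.0
    hand = parse(fixtures.make_decay())
    hand.species.clear()
    hand.parameters.clear()
    hand.reactions.clear()
    from sbmlkit.model import Reaction, Species
    hand.species["S"] = Species("S", "c", initial_amount=s0,
                                has_only_substance_units=True)
    hand.species["P"] = Species("P", "c", initial_amount=0.0,
                                has_only_substance_units=True)
    hand.parameters["v"] = Parameter("v", vmax)
    hand.parameters["km"] = Parameter("km", km)
    hand.reactions["conv"] = Reaction(
        "conv", [("S", 1.0)], [("P", 1.0)], False,
        apply("divide", apply("times", sym("v"), sym("S")),
              apply("plus", sym("km"), sym("S"))))
    t1 = sk.simulate_ode(sk.compile_network(sk.expand_functions(promoted)), (0, 4))
    t2 = sk.simulate_ode(sk.compile_network(hand), (0, 4))
    assert np.allclose(t1.states, t2.states, rtol=1e-8)


def test_promotion_namespaces_identical_local_names():
    model = parse(fixtures.make_decay())
    model.reactions["decay"].local_parameters = {"k2": 1.0}
    model.reactions["decay"].kinetic_law = apply("times", sym("k2"), sym("A"))
    from sbmlkit.model import Reaction
    model.reactions["r2"] = Reaction(
        "r2", [("A", 1.0)], [], False,
        apply("times", sym("k2"), sym("A")), local_parameters={"k2": 2.0})
    out = sk.promote_local_parameters(model)
    assert out.parameters["decay_k2"].value == 1.0
    assert out.parameters["r2_k2"].value == 2.0
    assert out.reactions["r2"].kinetic_law == apply("times", sym("r2_k2"), sym("A"))


def test_promotion_collision_appends_underscore():
    model = parse(fixtures.make_decay())
    model.parameters["decay_k2"] = Parameter("decay_k2", 9.0)
    model.reactions["decay"].local_parameters = {"k2": 1.0}
    model.reactions["decay"].kinetic_law = apply("times", sym("k2"), sym("A"))
    out = sk.promote_local_parameters(model)
    assert out.parameters["decay_k2_"].value == 1.0
    assert out.parameters["decay_k2"].value == 9.0
    assert out.reactions["decay"].kinetic_law == apply(
        "times", sym("decay_k2_"), sym("A"))


def test_promotion_idempotent():
    mm = parse(fixtures.make_mm_with_functiondef())
    once = sk.promote_local_parameters(mm)
    assert sk.promote_local_parameters(once) == once


# ---------------------------------------------------------------------------
# initial assignments

def test_hardcode_overrides_initial_value():
    model = parse(fixtures.make_initial_assignment_model())
    out = sk.apply_initial_assignments(model, mode="hardcode")
    assert out.species["A"].initial_amount == 6.0  # 2*k with k=3
    assert not out.initial_assignments


def test_symbolic_mode_keeps_assignment_but_compiles_same_state():
    model = parse(fixtures.make_initial_assignment_model())
    out = sk.apply_initial_assignments(model, mode="symbolic")
    assert out.initial_assignments  # retained
    hard_net = sk.compile_network(sk.apply_initial_assignments(model, "hardcode"))
    symb_net = sk.compile_network(out)
    assert hard_net.initial["A"] == symb_net.initial["A"] == 6.0


def test_assignment_chain_topological_evaluation():
    # a := 2*b, b := 2*c, c = 1  =>  a = 4 (brute-force fixed point oracle)
    model = parse(fixtures.make_decay())
    for pid in ("a", "b", "cp"):
        model.parameters[pid] = Parameter(pid, 0.0, constant=True)
    model.parameters["cp"].value = 1.0
    model.initial_assignments["a"] = InitialAssignment(
        "a", apply("times", num(2), sym("b")))
    model.initial_assignments["b"] = InitialAssignment(
        "b", apply("times", num(2), sym("cp")))
    # oracle: iterate assignments to a fixed point regardless of order
    values = {"a": 0.0, "b": 0.0, "cp": 1.0}
    for _ in range(5):
        values["b"] = 2 * values["cp"]
        values["a"] = 2 * values["b"]
    out = sk.apply_initial_assignments(model, mode="hardcode")
    assert out.parameters["a"].value == values["a"] == 4.0


def test_cyclic_assignments_rejected():
    model = parse(fixtures.make_decay())
    model.parameters["a"] = Parameter("a", 0.0)
    model.parameters["b"] = Parameter("b", 0.0)
    model.initial_assignments["a"] = InitialAssignment("a", sym("b"))
    model.initial_assignments["b"] = InitialAssignment("b", sym("a"))
    with pytest.raises(sk.ResolutionError, match="cycl"):
        sk.apply_initial_assignments(model, mode="hardcode")


# ---------------------------------------------------------------------------
# presets

def _combined_fixture():
    """Function definitions + local parameters + an initial assignment."""
    model = parse(fixtures.make_mm_with_functiondef())
    model.parameters["s_init"] = Parameter("s_init", 1.5, constant=True)
    model.initial_assignments["S"] = InitialAssignment(
        "S", apply("times", num(2), sym("s_init")))
    return model


def test_presets_agree_at_t0():
    model = _combined_fixture()
    n1 = sk.compile_network(sk.preset_simplify_math(model))
    n2 = sk.compile_network(sk.preset_promotelocals_expandfuns(model))
    assert n1.initial == n2.initial
    assert n1.initial["S"] == 3.0


def test_hardcoding_breaks_parameter_dependency_and_symbolic_keeps_it():
    model = _combined_fixture()
    hard = sk.preset_simplify_math(model)
    symb = sk.preset_promotelocals_expandfuns(model)
    for m in (hard, symb):
        m.parameters["s_init"].value = 10.0
    assert sk.compile_network(hard).initial["S"] == 3.0      # frozen
    assert sk.compile_network(symb).initial["S"] == 20.0     # propagates
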