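"""Read and write SBML XML (dynamic core, Levels 2-3) with content MathML.

Elements are matched by local name within the SBML and MathML namespaces;
annotations, notes and unit machinery are skipped with a warning since the
importer targets dynamics, not document fidelity.  Documents that declare an
SBML Level 3 package namespace (comp, fbc, layout, ...) are rejected with an
error naming the package.

Species declared with an ``initialConcentration`` are converted to amounts
(concentration x compartment size) at read time when the compartment size is
known, matching the amounts convention used throughout the compiler; when
the size is only set later by an initial assignment the concentration is
kept and converted during network compilation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from lxml import etree

from .errors import ParseError, SerializationError, UnsupportedFeatureError
from .expressions import (
    Apply, BoolConst, MathNode, Number, Piecewise, SymbolRef, TimeSymbol,
    OPERATORS, TIME,
)
from .model import (
    AlgebraicRule, AssignmentRule, Compartment, Event, FunctionDefinition,
    InitialAssignment, Model, Parameter, RateRule, Reaction, Species,
)

SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"
SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
SBML_L2V4_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_PACKAGE_NS_RE = re.compile(
    r"http://www\.sbml\.org/sbml/level3/version\d+/(\w+)/version\d+"
)

# MathML operator element local names that map 1:1 onto MathNode tags
_OP_ELEMENTS = OPERATORS - {"delay"}

_TIME_URLS = {
    "http://www.sbml.org/sbml/symbols/time",
}
_DELAY_URLS = {
    "http://www.sbml.org/sbml/symbols/delay",
}


@dataclass
class ParseIssue:
    severity: str  # "error" | "warning"
    xml_path: str
    message: str


def _local(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _children(el):
    return [c for c in el if isinstance(c.tag, str)]


def _find(el, name):
    for c in _children(el):
        if _local(c) == name:
            return c
    return None


def _attr(el, name, path, required=False, default=None):
    v = el.get(name)
    if v is None:
        if required:
            raise ParseError(f"missing required attribute {name!r} on <{_local(el)}>", path)
        return default
    return v


def _bool_attr(el, name, path, required=False, default=None):
    v = _attr(el, name, path, required)
    if v is None:
        return default
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise ParseError(f"attribute {name}={v!r} is not a Boolean", path)


def _float_attr(el, name, path, required=False, default=None):
    v = _attr(el, name, path, required)
    if v is None:
        return default
    try:
        return float(v)
    except ValueError:
        raise ParseError(f"attribute {name}={v!r} is not a number", path) from None


# ---------------------------------------------------------------------------
# MathML

def parse_mathml(math_el, path: str = "/math") -> MathNode:
    """Parse a content-MathML ``<math>`` element (or a bare expression
    element) into a MathNode tree.  ``<lambda>`` is rejected here; function
    definitions go through :func:`parse_lambda`."""
    if _local(math_el) == "math":
        kids = [c for c in _children(math_el) if _local(c) != "annotation"]
        if len(kids) != 1:
            raise ParseError(f"<math> must contain exactly one expression, got {len(kids)}", path)
        math_el = kids[0]
    return _parse_expr(math_el, path)


def parse_lambda(math_el, path: str = "/math"):
    """Parse a ``<math><lambda>`` function definition body; returns
    (argument ids, body MathNode)."""
    if _local(math_el) == "math":
        kids = _children(math_el)
        if len(kids) != 1 or _local(kids[0]) != "lambda":
            raise ParseError("function definition math must be a single <lambda>", path)
        math_el = kids[0]
    args: list[str] = []
    body = None
    for c in _children(math_el):
        if _local(c) == "bvar":
            ci = _find(c, "ci")
            if ci is None or not (ci.text or "").strip():
                raise ParseError("<bvar> must contain a <ci>", path)
            args.append(ci.text.strip())
        else:
            if body is not None:
                raise ParseError("<lambda> has more than one body expression", path)
            body = _parse_expr(c, path)
    if body is None:
        raise ParseError("<lambda> has no body", path)
    return args, body


def _parse_expr(el, path: str) -> MathNode:
    name = _local(el)
    p = f"{path}/{name}"
    if name == "ci":
        ident = (el.text or "").strip()
        if not ident:
            raise ParseError("<ci> with empty identifier", p)
        return SymbolRef(ident)
    if name == "cn":
        return _parse_cn(el, p)
    if name == "csymbol":
        url = (el.get("definitionURL") or "").strip()
        if url in _TIME_URLS:
            return TIME
        raise ParseError(f"unknown csymbol definitionURL {url!r}", p)
    if name == "true":
        return BoolConst(True)
    if name == "false":
        return BoolConst(False)
    if name == "pi":
        return Number(math.pi)
    if name == "exponentiale":
        return Number(math.e)
    if name == "apply":
        return _parse_apply(el, p)
    if name == "piecewise":
        return _parse_piecewise(el, p)
    if name == "lambda":
        raise ParseError("<lambda> is only allowed inside a function definition", p)
    raise ParseError(f"unknown MathML element <{name}>", p)


def _parse_cn(el, path: str) -> Number:
    ctype = el.get("type", "real")
    head = (el.text or "").strip()
    sep = _find(el, "sep")
    tail = (sep.tail or "").strip() if sep is not None else None
    try:
        if ctype in ("real", "integer", "double"):
            return Number(float(head))
        if ctype == "e-notation":
            if tail is None:
                raise ParseError("e-notation <cn> needs a <sep/>", path)
            return Number(float(head) * 10.0 ** float(tail))
        if ctype == "rational":
            if tail is None:
                raise ParseError("rational <cn> needs a <sep/>", path)
            return Number(float(head) / float(tail))
    except ValueError:
        raise ParseError(f"cannot parse <cn> content {head!r}", path) from None
    raise ParseError(f"unknown <cn> type {ctype!r}", path)


def _parse_apply(el, path: str):
    kids = _children(el)
    if not kids:
        raise ParseError("<apply> with no operator", path)
    head, rest = kids[0], kids[1:]
    hname = _local(head)
    # qualifiers (degree for root, logbase for log) are pulled out of args
    def plain_args():
        return tuple(_parse_expr(a, path) for a in rest)

    if hname in _OP_ELEMENTS:
        if hname == "root":
            degree = next((a for a in rest if _local(a) == "degree"), None)
            radicand = [a for a in rest if _local(a) != "degree"]
            if len(radicand) != 1:
                raise ParseError("<root> needs exactly one radicand", path)
            rad = _parse_expr(radicand[0], path)
            if degree is None:
                return Apply("root", (rad,))
            dkids = _children(degree)
            if len(dkids) != 1:
                raise ParseError("<degree> must contain one expression", path)
            return Apply("root", (_parse_expr(dkids[0], path), rad))
        if hname == "log":
            base = next((a for a in rest if _local(a) == "logbase"), None)
            operand = [a for a in rest if _local(a) != "logbase"]
            if len(operand) != 1:
                raise ParseError("<log> needs exactly one operand", path)
            x = _parse_expr(operand[0], path)
            if base is None:
                return Apply("log", (x,))
            bkids = _children(base)
            if len(bkids) != 1:
                raise ParseError("<logbase> must contain one expression", path)
            return Apply("log", (_parse_expr(bkids[0], path), x))
        try:
            return Apply(hname, plain_args())
        except ValueError as exc:  # arity violation
            raise ParseError(str(exc), path) from None
    if hname == "ci":
        fname = (head.text or "").strip()
        if not fname:
            raise ParseError("function call with empty <ci>", path)
        return Apply(fname, plain_args())
    if hname == "csymbol":
        url = (head.get("definitionURL") or "").strip()
        if url in _DELAY_URLS:
            return Apply("delay", plain_args())
        if url in _TIME_URLS:
            raise ParseError("time csymbol cannot head an <apply>", path)
        raise ParseError(f"unknown csymbol definitionURL {url!r}", path)
    raise ParseError(f"unknown operator element <{hname}>", path)


def _parse_piecewise(el, path: str) -> Piecewise:
    branches = []
    otherwise = None
    for c in _children(el):
        name = _local(c)
        if name == "piece":
            kids = _children(c)
            if len(kids) != 2:
                raise ParseError("<piece> must contain value and condition", path)
            branches.append((_parse_expr(kids[0], path), _parse_expr(kids[1], path)))
        elif name == "otherwise":
            kids = _children(c)
            if len(kids) != 1:
                raise ParseError("<otherwise> must contain one expression", path)
            otherwise = _parse_expr(kids[0], path)
        else:
            raise ParseError(f"unknown element <{name}> in <piecewise>", path)
    return Piecewise(tuple(branches), otherwise)


# ---------------------------------------------------------------------------
# reading

def read_sbml(text: str | bytes) -> tuple[Model, list[ParseIssue]]:
    """Parse an SBML document into a :class:`Model` plus warnings.

    Raises :class:`ParseError` / :class:`UnsupportedFeatureError` on fatal
    problems (malformed XML, missing required attributes, Level 1,
    package namespaces); warnings are returned as :class:`ParseIssue`
    objects.
    """
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}", "/") from None
    if _local(root) != "sbml":
        raise ParseError(f"root element is <{_local(root)}>, expected <sbml>", "/")

    for uri in (root.nsmap or {}).values():
        m = _PACKAGE_NS_RE.match(uri or "")
        if m:
            raise UnsupportedFeatureError(
                f"SBML package {m.group(1)!r} is not supported", feature=m.group(1))

    path = "/sbml"
    level = _attr(root, "level", path, required=True)
    version = _attr(root, "version", path, required=True)
    try:
        level, version = int(level), int(version)
    except ValueError:
        raise ParseError("level/version must be integers", path) from None
    if level < 2:
        raise UnsupportedFeatureError(
            f"SBML Level {level} is not supported (Level 2 or 3 required)",
            feature="level")
    if level > 3:
        raise ParseError(f"unknown SBML level {level}", path)

    model_el = _find(root, "model")
    if model_el is None:
        raise ParseError("document has no <model>", path)

    issues: list[ParseIssue] = []
    model = Model(level=level, version=version)
    _read_model(model_el, model, f"{path}/model", issues)

    # concentration -> amount where the compartment size is already known
    for s in model.species.values():
        if s.initial_concentration is None:
            continue
        comp = model.compartments[s.compartment]
        if comp.size is not None:
            s.initial_amount = s.initial_concentration * comp.size
            s.initial_concentration = None
        elif s.compartment not in model.initial_assignments and not any(
            getattr(r, "variable", None) == s.compartment for r in model.rules
        ):
            raise ParseError(
                f"species {s.id!r} has initialConcentration but compartment "
                f"{s.compartment!r} has no size and no assignment defining one",
                f"{path}/model/listOfSpecies")
    return model, issues


_SKIP_SILENT = {"listOfUnitDefinitions"}


def _read_model(model_el, model: Model, path: str, issues):
    handlers = {
        "listOfCompartments": _read_compartments,
        "listOfSpecies": _read_species,
        "listOfParameters": _read_parameters,
        "listOfReactions": _read_reactions,
        "listOfFunctionDefinitions": _read_function_definitions,
        "listOfInitialAssignments": _read_initial_assignments,
        "listOfRules": _read_rules,
        "listOfEvents": _read_events,
        "listOfConstraints": _read_constraints,
    }
    for c in _children(model_el):
        name = _local(c)
        p = f"{path}/{name}"
        if name in handlers:
            handlers[name](c, model, p, issues)
        elif name in ("annotation", "notes"):
            issues.append(ParseIssue("warning", p, f"<{name}> skipped (not preserved)"))
        elif name in _SKIP_SILENT:
            issues.append(ParseIssue("warning", p, f"<{name}> skipped (units are ignored)"))
        else:
            issues.append(ParseIssue("warning", p, f"unknown element <{name}> skipped"))


def _check_unique(model: Model, eid: str, path: str):
    if eid in model.global_ids():
        raise ParseError(f"duplicate global id {eid!r}", path)


def _skip_sub(el, issues, path):
    for c in _children(el):
        if _local(c) in ("annotation", "notes"):
            issues.append(ParseIssue("warning", f"{path}/{_local(c)}",
                                     f"<{_local(c)}> skipped (not preserved)"))


def _read_compartments(lst, model, path, issues):
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/compartment[{i}]"
        if _local(el) != "compartment":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        cid = _attr(el, "id", p, required=True)
        _check_unique(model, cid, p)
        size = _float_attr(el, "size", p)
        if size is None:
            size = _float_attr(el, "volume", p)  # L2V1 synonym
        constant = _bool_attr(el, "constant", p, default=True)
        dims = _attr(el, "spatialDimensions", p, default="3")
        _skip_sub(el, issues, p)
        model.compartments[cid] = Compartment(
            id=cid, size=size, constant=constant,
            spatial_dimensions=int(float(dims)))


def _read_species(lst, model, path, issues):
    l3 = model.level == 3
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/species[{i}]"
        if _local(el) != "species":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        sid = _attr(el, "id", p, required=True)
        _check_unique(model, sid, p)
        comp = _attr(el, "compartment", p, required=True)
        if comp not in model.compartments:
            raise ParseError(f"species {sid!r} references unknown compartment {comp!r}", p)
        amount = _float_attr(el, "initialAmount", p)
        conc = _float_attr(el, "initialConcentration", p)
        if amount is not None and conc is not None:
            raise ParseError(
                f"species {sid!r} sets both initialAmount and initialConcentration", p)
        bc = _bool_attr(el, "boundaryCondition", p, required=l3, default=False)
        hosu = _bool_attr(el, "hasOnlySubstanceUnits", p, required=l3, default=False)
        constant = _bool_attr(el, "constant", p, required=l3, default=False)
        _skip_sub(el, issues, p)
        model.species[sid] = Species(
            id=sid, compartment=comp, initial_amount=amount,
            initial_concentration=conc, boundary_condition=bc,
            constant=constant, has_only_substance_units=hosu)


def _read_parameters(lst, model, path, issues):
    l3 = model.level == 3
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/parameter[{i}]"
        if _local(el) != "parameter":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        pid = _attr(el, "id", p, required=True)
        _check_unique(model, pid, p)
        value = _float_attr(el, "value", p)
        constant = _bool_attr(el, "constant", p, required=l3, default=True)
        _skip_sub(el, issues, p)
        model.parameters[pid] = Parameter(id=pid, value=value, constant=constant)


def _read_species_refs(lst_el, model, path, out, model_obj):
    for i, el in enumerate(_children(lst_el), 1):
        p = f"{path}/speciesReference[{i}]"
        if _local(el) != "speciesReference":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        sp = _attr(el, "species", p, required=True)
        if sp not in model.species:
            raise ParseError(f"reference to unknown species {sp!r}", p)
        st = _float_attr(el, "stoichiometry", p, default=1.0)
        if not (st > 0 and math.isfinite(st)):
            raise ParseError(f"stoichiometry {st!r} must be positive and finite", p)
        ref_id = el.get("id")
        if ref_id:
            model_obj.stoichiometry_reference_ids.add(ref_id)
        out.append((sp, st))


def _read_reactions(lst, model, path, issues):
    l3 = model.level == 3
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/reaction[{i}]"
        if _local(el) != "reaction":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        rid = _attr(el, "id", p, required=True)
        _check_unique(model, rid, p)
        reversible = _bool_attr(el, "reversible", p, required=l3, default=True)
        rxn = Reaction(id=rid, reversible=reversible)
        for c in _children(el):
            name = _local(c)
            if name == "listOfReactants":
                _read_species_refs(c, model, f"{p}/{name}", rxn.reactants, model)
            elif name == "listOfProducts":
                _read_species_refs(c, model, f"{p}/{name}", rxn.products, model)
            elif name == "listOfModifiers":
                pass  # modifiers carry no dynamics beyond the kinetic law
            elif name == "kineticLaw":
                _read_kinetic_law(c, rxn, f"{p}/kineticLaw", issues)
            elif name in ("annotation", "notes"):
                issues.append(ParseIssue("warning", f"{p}/{name}", f"<{name}> skipped"))
            else:
                issues.append(ParseIssue("warning", f"{p}/{name}",
                                         f"unknown element <{name}> skipped"))
        if rxn.kinetic_law is None:
            raise ParseError(f"reaction {rid!r} has no kineticLaw", p)
        model.reactions[rid] = rxn


def _read_kinetic_law(el, rxn: Reaction, path, issues):
    for c in _children(el):
        name = _local(c)
        if name == "math":
            rxn.kinetic_law = parse_mathml(c, f"{path}/math")
        elif name in ("listOfLocalParameters", "listOfParameters"):
            for j, pe in enumerate(_children(c), 1):
                pp = f"{path}/{name}[{j}]"
                if _local(pe) not in ("localParameter", "parameter"):
                    raise ParseError(f"unexpected element <{_local(pe)}>", pp)
                pid = _attr(pe, "id", pp, required=True)
                value = _float_attr(pe, "value", pp)
                if value is None:
                    raise ParseError(f"local parameter {pid!r} has no value", pp)
                rxn.local_parameters[pid] = value
        elif name in ("annotation", "notes"):
            issues.append(ParseIssue("warning", f"{path}/{name}", f"<{name}> skipped"))


def _read_function_definitions(lst, model, path, issues):
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/functionDefinition[{i}]"
        if _local(el) != "functionDefinition":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        fid = _attr(el, "id", p, required=True)
        _check_unique(model, fid, p)
        math_el = _find(el, "math")
        if math_el is None:
            raise ParseError(f"function {fid!r} has no <math>", p)
        args, body = parse_lambda(math_el, f"{p}/math")
        model.function_definitions[fid] = FunctionDefinition(fid, args, body)


def _read_initial_assignments(lst, model, path, issues):
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/initialAssignment[{i}]"
        if _local(el) != "initialAssignment":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        target = _attr(el, "symbol", p, required=True)
        if target in model.initial_assignments:
            raise ParseError(f"{target!r} has more than one initialAssignment", p)
        math_el = _find(el, "math")
        if math_el is None:
            raise ParseError("initialAssignment has no <math>", p)
        model.initial_assignments[target] = InitialAssignment(
            target, parse_mathml(math_el, f"{p}/math"))


def _read_rules(lst, model, path, issues):
    for i, el in enumerate(_children(lst), 1):
        name = _local(el)
        p = f"{path}/{name}[{i}]"
        math_el = _find(el, "math")
        if math_el is None:
            raise ParseError(f"<{name}> has no <math>", p)
        node = parse_mathml(math_el, f"{p}/math")
        if name == "algebraicRule":
            model.rules.append(AlgebraicRule(node))
            continue
        var = _attr(el, "variable", p, required=True)
        if name == "assignmentRule":
            model.rules.append(AssignmentRule(var, node))
        elif name == "rateRule":
            model.rules.append(RateRule(var, node))
        else:
            raise ParseError(f"unknown rule element <{name}>", p)


def _read_events(lst, model, path, issues):
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/event[{i}]"
        if _local(el) != "event":
            raise ParseError(f"unexpected element <{_local(el)}>", p)
        eid = _attr(el, "id", p) or f"_event{i}"
        trigger_el = _find(el, "trigger")
        if trigger_el is None:
            raise ParseError(f"event {eid!r} has no trigger", p)
        math_el = _find(trigger_el, "math")
        if math_el is None:
            raise ParseError(f"event {eid!r} trigger has no <math>", p)
        trigger = parse_mathml(math_el, f"{p}/trigger/math")
        has_delay = _find(el, "delay") is not None
        assignments: list[tuple[str, MathNode]] = []
        la = _find(el, "listOfEventAssignments")
        if la is not None:
            for j, ae in enumerate(_children(la), 1):
                ap = f"{p}/listOfEventAssignments/eventAssignment[{j}]"
                if _local(ae) != "eventAssignment":
                    raise ParseError(f"unexpected element <{_local(ae)}>", ap)
                var = _attr(ae, "variable", ap, required=True)
                am = _find(ae, "math")
                if am is None:
                    raise ParseError("eventAssignment has no <math>", ap)
                assignments.append((var, parse_mathml(am, f"{ap}/math")))
        if not assignments:
            raise ParseError(f"event {eid!r} has no eventAssignments", p)
        if _find(el, "priority") is not None:
            issues.append(ParseIssue("warning", f"{p}/priority",
                                     "<priority> skipped (event priorities ignored)"))
        model.events[eid] = Event(eid, trigger, assignments, has_delay=has_delay)


def _read_constraints(lst, model, path, issues):
    for i, el in enumerate(_children(lst), 1):
        p = f"{path}/constraint[{i}]"
        math_el = _find(el, "math")
        node = parse_mathml(math_el, f"{p}/math") if math_el is not None else BoolConst(True)
        model.constraints.append(node)


# ---------------------------------------------------------------------------
# writing

def serialize_mathml(node: MathNode):
    """MathNode -> ``<math>`` element (content MathML)."""
    math_el = etree.Element(f"{{{MATHML_NS}}}math")
    math_el.append(_ser_expr(node))
    return math_el


def _mel(name: str, text: str | None = None):
    el = etree.Element(f"{{{MATHML_NS}}}{name}")
    if text is not None:
        el.text = text
    return el


def _ser_expr(node: MathNode):
    if isinstance(node, Number):
        return _mel("cn", repr(node.value))
    if isinstance(node, SymbolRef):
        return _mel("ci", node.id)
    if isinstance(node, TimeSymbol):
        el = _mel("csymbol", "time")
        el.set("encoding", "text")
        el.set("definitionURL", "http://www.sbml.org/sbml/symbols/time")
        return el
    if isinstance(node, BoolConst):
        return _mel("true" if node.value else "false")
    if isinstance(node, Piecewise):
        el = _mel("piecewise")
        for v, c in node.branches:
            piece = _mel("piece")
            piece.append(_ser_expr(v))
            piece.append(_ser_expr(c))
            el.append(piece)
        if node.otherwise is not None:
            oth = _mel("otherwise")
            oth.append(_ser_expr(node.otherwise))
            el.append(oth)
        return el
    if isinstance(node, Apply):
        el = _mel("apply")
        op = node.op
        if op == "delay":
            head = _mel("csymbol", "delay")
            head.set("encoding", "text")
            head.set("definitionURL", "http://www.sbml.org/sbml/symbols/delay")
            el.append(head)
            for a in node.args:
                el.append(_ser_expr(a))
        elif op == "root" and len(node.args) == 2:
            el.append(_mel("root"))
            deg = _mel("degree")
            deg.append(_ser_expr(node.args[0]))
            el.append(deg)
            el.append(_ser_expr(node.args[1]))
        elif op == "log" and len(node.args) == 2:
            el.append(_mel("log"))
            base = _mel("logbase")
            base.append(_ser_expr(node.args[0]))
            el.append(base)
            el.append(_ser_expr(node.args[1]))
        elif op in OPERATORS:
            el.append(_mel(op))
            for a in node.args:
                el.append(_ser_expr(a))
        else:  # user function call
            el.append(_mel("ci", op))
            for a in node.args:
                el.append(_ser_expr(a))
        return el
    raise SerializationError(f"cannot serialize {node!r}")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_sbml(model: Model, level: tuple[int, int] = (3, 2)) -> str:
    """Serialize a Model as SBML XML text.

    The default (and recommended) target is Level 3 Version 2 with all
    attributes materialized.  ``level=(2, 4)`` emits a Level 2 Version 4
    document in which attributes equal to the L2 defaults are omitted —
    used to generate fixtures that exercise level harmonization.
    """
    model.validate()
    if level == (3, 2):
        ns, l, v = SBML_L3V2_NS, 3, 2
    elif level == (2, 4):
        ns, l, v = SBML_L2V4_NS, 2, 4
    else:
        raise SerializationError(f"unsupported output level/version {level}")
    l3 = l == 3
    root = etree.Element(f"{{{ns}}}sbml", nsmap={None: ns})
    root.set("level", str(l))
    root.set("version", str(v))
    model_el = etree.SubElement(root, f"{{{ns}}}model")
    model_el.set("id", "model")

    def sub(parent, name):
        return etree.SubElement(parent, f"{{{ns}}}{name}")

    if model.function_definitions:
        lst = sub(model_el, "listOfFunctionDefinitions")
        for f in model.function_definitions.values():
            el = sub(lst, "functionDefinition")
            el.set("id", f.id)
            math_el = etree.SubElement(el, f"{{{MATHML_NS}}}math")
            lam = _mel("lambda")
            for a in f.arguments:
                bv = _mel("bvar")
                bv.append(_mel("ci", a))
                lam.append(bv)
            lam.append(_ser_expr(f.body))
            math_el.append(lam)

    if model.compartments:
        lst = sub(model_el, "listOfCompartments")
        for c in model.compartments.values():
            el = sub(lst, "compartment")
            el.set("id", c.id)
            el.set("spatialDimensions", str(c.spatial_dimensions))
            if c.size is not None:
                el.set("size", _fmt(c.size))
            if l3 or not c.constant:
                el.set("constant", "true" if c.constant else "false")

    if model.species:
        lst = sub(model_el, "listOfSpecies")
        for s in model.species.values():
            el = sub(lst, "species")
            el.set("id", s.id)
            el.set("compartment", s.compartment)
            if s.initial_amount is not None:
                el.set("initialAmount", _fmt(s.initial_amount))
            if s.initial_concentration is not None:
                el.set("initialConcentration", _fmt(s.initial_concentration))
            if l3 or s.has_only_substance_units:
                el.set("hasOnlySubstanceUnits",
                       "true" if s.has_only_substance_units else "false")
            if l3 or s.boundary_condition:
                el.set("boundaryCondition",
                       "true" if s.boundary_condition else "false")
            if l3 or s.constant:
                el.set("constant", "true" if s.constant else "false")

    if model.parameters:
        lst = sub(model_el, "listOfParameters")
        for p in model.parameters.values():
            el = sub(lst, "parameter")
            el.set("id", p.id)
            if p.value is not None:
                el.set("value", _fmt(p.value))
            if l3 or not p.constant:
                el.set("constant", "true" if p.constant else "false")

    if model.initial_assignments:
        lst = sub(model_el, "listOfInitialAssignments")
        for ia in model.initial_assignments.values():
            el = sub(lst, "initialAssignment")
            el.set("symbol", ia.target)
            el.append(serialize_mathml(ia.math))

    if model.rules:
        lst = sub(model_el, "listOfRules")
        for rule in model.rules:
            if isinstance(rule, AssignmentRule):
                el = sub(lst, "assignmentRule")
                el.set("variable", rule.variable)
            elif isinstance(rule, RateRule):
                el = sub(lst, "rateRule")
                el.set("variable", rule.variable)
            else:
                el = sub(lst, "algebraicRule")
            el.append(serialize_mathml(rule.math))

    if model.constraints:
        lst = sub(model_el, "listOfConstraints")
        for cm in model.constraints:
            el = sub(lst, "constraint")
            el.append(serialize_mathml(cm))

    if model.reactions:
        lst = sub(model_el, "listOfReactions")
        for r in model.reactions.values():
            el = sub(lst, "reaction")
            el.set("id", r.id)
            if l3 or not r.reversible:
                el.set("reversible", "true" if r.reversible else "false")
            for tag, refs in (("listOfReactants", r.reactants),
                              ("listOfProducts", r.products)):
                if refs:
                    le = sub(el, tag)
                    for sp, st in refs:
                        ref = sub(le, "speciesReference")
                        ref.set("species", sp)
                        ref.set("stoichiometry", _fmt(st))
                        if l3:
                            ref.set("constant", "true")
            kl = sub(el, "kineticLaw")
            kl.append(serialize_mathml(r.kinetic_law))
            if r.local_parameters:
                lp = sub(kl, "listOfLocalParameters" if l3 else "listOfParameters")
                for pid, value in r.local_parameters.items():
                    pe = sub(lp, "localParameter" if l3 else "parameter")
                    pe.set("id", pid)
                    pe.set("value", _fmt(value))

    if model.events:
        lst = sub(model_el, "listOfEvents")
        for ev in model.events.values():
            el = sub(lst, "event")
            el.set("id", ev.id)
            if l3:
                el.set("useValuesFromTriggerTime", "true")
            trig = sub(el, "trigger")
            if l3:
                trig.set("persistent", "true")
                trig.set("initialValue", "true")
            trig.append(serialize_mathml(ev.trigger))
            la = sub(el, "listOfEventAssignments")
            for var, m in ev.assignments:
                ae = sub(la, "eventAssignment")
                ae.set("variable", var)
                ae.append(serialize_mathml(m))

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")
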