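"""SBML Level 3 import/export for the reaction networks.

The writer emits SBML Level 3 Version 2 core documents: one compartment,
species with initial concentrations and boundary flags, reactions with
stoichiometry, modifiers, kinetic laws (content MathML generated from the
symbolic rate expression) and local parameters, and time-triggered events.

Because the package's rate-law catalogue is closed, each kinetic law also
carries a structured annotation (a small XML element in the package's own
namespace) recording the rate-law kind and its species-role bindings. The
reader reconstructs models from that annotation plus the standard SBML
species/stoichiometry/parameter elements; this guarantees algebraic
round-trip fidelity without a general MathML interpreter. Documents that
lack the annotation, or that use constructs outside the supported subset
(function definitions, rules, constraints, event delays, non-integer
stoichiometry), are rejected with an error naming the offending element.
"""

from __future__ import annotations

import json

import sympy as sp
from lxml import etree

from .reaction_network import (
    Event,
    NetworkModel,
    RateLaw,
    ReactionDef,
    SpeciesDef,
    _rate_expr,
    validate_model,
)

__all__ = ["export_sbml", "import_sbml", "UnsupportedSBMLError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:wntrho:ratelaw"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


class UnsupportedSBMLError(ValueError):
    """An SBML construct outside the supported subset was encountered."""


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _emit_content_mathml(expr, parent) -> None:
    """Append content MathML for a sympy rational expression to ``parent``.

    Handles symbols, numbers and the +, *, / and integer-power operations the
    rate-law catalogue produces; identifiers are emitted verbatim as <ci>.
    """
    if expr.is_Symbol:
        ci = etree.SubElement(parent, _q(MATHML_NS, "ci"))
        ci.text = expr.name
        return
    if expr.is_Number:
        cn = etree.SubElement(parent, _q(MATHML_NS, "cn"))
        cn.text = repr(float(expr))
        return
    apply_ = etree.SubElement(parent, _q(MATHML_NS, "apply"))
    if expr.is_Add:
        etree.SubElement(apply_, _q(MATHML_NS, "plus"))
        args = expr.args
    elif expr.is_Mul:
        numer, denom = expr.as_numer_denom()
        if denom != 1:
            etree.SubElement(apply_, _q(MATHML_NS, "divide"))
            _emit_content_mathml(numer, apply_)
            _emit_content_mathml(denom, apply_)
            return
        etree.SubElement(apply_, _q(MATHML_NS, "times"))
        args = expr.args
    elif expr.is_Pow:
        base, exponent = expr.args
        if exponent.is_negative:
            etree.SubElement(apply_, _q(MATHML_NS, "divide"))
            _emit_content_mathml(sp.Integer(1), apply_)
            _emit_content_mathml(base ** (-exponent), apply_)
            return
        etree.SubElement(apply_, _q(MATHML_NS, "power"))
        args = expr.args
    else:
        raise ValueError(f"cannot serialise expression node {expr!r} to MathML")
    for arg in args:
        _emit_content_mathml(arg, apply_)


def _mathml_for_rate(law: RateLaw, species: list[str]) -> etree._Element:
    """Content-MathML element for the rate expression of ``law``."""
    conc = {name: sp.Symbol(name) for name in species}
    params = {name: sp.Symbol(name) for name in law.parameters}
    expr = _rate_expr(law, conc, params)
    math = etree.Element(_q(MATHML_NS, "math"), nsmap={None: MATHML_NS})
    _emit_content_mathml(sp.sympify(expr), math)
    return math


def export_sbml(model: NetworkModel) -> str:
    """Serialise ``model`` to an SBML Level 3 document (UTF-8 string)."""
    problems = validate_model(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    names = model.species_names()

    sbml = etree.Element(_q(SBML_NS, "sbml"), nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    mdl = etree.SubElement(sbml, _q(SBML_NS, "model"))
    mdl.set("id", model.name.replace("[", "_").replace("]", "").replace(
        ",", "_").replace("+", "_").replace("-", "_") or "model")
    mdl.set("name", model.name)

    comps = etree.SubElement(mdl, _q(SBML_NS, "listOfCompartments"))
    comp = etree.SubElement(comps, _q(SBML_NS, "compartment"))
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")

    sl = etree.SubElement(mdl, _q(SBML_NS, "listOfSpecies"))
    for s in model.species:
        el = etree.SubElement(sl, _q(SBML_NS, "species"))
        el.set("id", s.name)
        el.set("compartment", "cell")
        el.set("initialConcentration", repr(s.initial_concentration))
        el.set("boundaryCondition", "true" if s.is_boundary else "false")
        el.set("constant", "false")
        el.set("hasOnlySubstanceUnits", "false")

    rl = etree.SubElement(mdl, _q(SBML_NS, "listOfReactions"))
    for r in model.reactions:
        rel = etree.SubElement(rl, _q(SBML_NS, "reaction"))
        rel.set("id", r.label)
        rel.set("reversible", "false")
        if r.reactants:
            lst = etree.SubElement(rel, _q(SBML_NS, "listOfReactants"))
            for name, stoich in r.reactants:
                ref = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                ref.set("species", name)
                ref.set("stoichiometry", str(stoich))
                ref.set("constant", "true")
        if r.products:
            lst = etree.SubElement(rel, _q(SBML_NS, "listOfProducts"))
            for name, stoich in r.products:
                ref = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                ref.set("species", name)
                ref.set("stoichiometry", str(stoich))
                ref.set("constant", "true")
        if r.modifiers:
            lst = etree.SubElement(rel, _q(SBML_NS, "listOfModifiers"))
            for name in r.modifiers:
                ref = etree.SubElement(lst, _q(SBML_NS, "modifierSpeciesReference"))
                ref.set("species", name)
        kl = etree.SubElement(rel, _q(SBML_NS, "kineticLaw"))
        annot = etree.SubElement(kl, _q(SBML_NS, "annotation"))
        rate_el = etree.SubElement(annot, _q(ANNOT_NS, "rateLaw"), nsmap={"wr": ANNOT_NS})
        rate_el.set("kind", r.rate_law.kind)
        rate_el.set("speciesRefs", json.dumps(r.rate_law.species_refs))
        kl.append(_mathml_for_rate(r.rate_law, names))
        pl = etree.SubElement(kl, _q(SBML_NS, "listOfLocalParameters"))
        for pname, value in r.rate_law.parameters.items():
            pel = etree.SubElement(pl, _q(SBML_NS, "localParameter"))
            pel.set("id", pname)
            pel.set("value", repr(value))

    if model.events:
        el_list = etree.SubElement(mdl, _q(SBML_NS, "listOfEvents"))
        for i, e in enumerate(model.events):
            ev = etree.SubElement(el_list, _q(SBML_NS, "event"))
            ev.set("id", f"event{i}")
            ev.set("useValuesFromTriggerTime", "true")
            trig = etree.SubElement(ev, _q(SBML_NS, "trigger"))
            trig.set("initialValue", "true")
            trig.set("persistent", "true")
            math = etree.SubElement(trig, _q(MATHML_NS, "math"), nsmap={None: MATHML_NS})
            apply_ = etree.SubElement(math, _q(MATHML_NS, "apply"))
            etree.SubElement(apply_, _q(MATHML_NS, "geq"))
            csym = etree.SubElement(apply_, _q(MATHML_NS, "csymbol"))
            csym.set("encoding", "text")
            csym.set("definitionURL", TIME_CSYMBOL)
            csym.text = "time"
            cn = etree.SubElement(apply_, _q(MATHML_NS, "cn"))
            cn.text = repr(e.time)
            eas = etree.SubElement(ev, _q(SBML_NS, "listOfEventAssignments"))
            ea = etree.SubElement(eas, _q(SBML_NS, "eventAssignment"))
            ea.set("variable", e.species)
            math = etree.SubElement(ea, _q(MATHML_NS, "math"), nsmap={None: MATHML_NS})
            cn = etree.SubElement(math, _q(MATHML_NS, "cn"))
            cn.text = repr(e.new_value)

    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


_UNSUPPORTED = (
    "listOfFunctionDefinitions",
    "listOfRules",
    "listOfConstraints",
    "listOfInitialAssignments",
)


def _float_attr(el, name, default=0.0):
    value = el.get(name)
    return float(value) if value is not None else default


def import_sbml(document: str | bytes) -> NetworkModel:
    """Reconstruct a :class:`NetworkModel` from an SBML document.

    Only documents produced by (or structured like) :func:`export_sbml` are
    accepted: kinetic laws must carry the rate-law annotation, stoichiometry
    must be a positive integer, and rules/function definitions/constraints
    and event delays are rejected explicitly.
    """
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    mdl = root.find(_q(SBML_NS, "model"))
    if mdl is None:
        raise UnsupportedSBMLError("document has no <model> element")
    for tag in _UNSUPPORTED:
        el = mdl.find(_q(SBML_NS, tag))
        if el is not None and len(el):
            raise UnsupportedSBMLError(f"unsupported SBML construct: {tag}")

    species = []
    for el in mdl.iterfind(f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"):
        species.append(
            SpeciesDef(
                el.get("id"),
                _float_attr(el, "initialConcentration"),
                el.get("boundaryCondition") == "true",
            )
        )

    def _stoich_list(rel, tag):
        out = []
        for ref in rel.iterfind(f"{_q(SBML_NS, tag)}/{_q(SBML_NS, 'speciesReference')}"):
            raw = float(ref.get("stoichiometry", "1"))
            if raw <= 0 or raw != int(raw):
                raise UnsupportedSBMLError(
                    f"non-integer stoichiometry in reaction {rel.get('id')!r}"
                )
            out.append((ref.get("species"), int(raw)))
        return out

    reactions = []
    for rel in mdl.iterfind(f"{_q(SBML_NS, 'listOfReactions')}/{_q(SBML_NS, 'reaction')}"):
        kl = rel.find(_q(SBML_NS, "kineticLaw"))
        if kl is None:
            raise UnsupportedSBMLError(f"reaction {rel.get('id')!r} has no kinetic law")
        annot = kl.find(f"{_q(SBML_NS, 'annotation')}/{_q(ANNOT_NS, 'rateLaw')}")
        if annot is None:
            raise UnsupportedSBMLError(
                f"reaction {rel.get('id')!r}: kinetic law lacks the rate-law "
                "annotation required by this reader"
            )
        params = {}
        for pel in kl.iterfind(
            f"{_q(SBML_NS, 'listOfLocalParameters')}/{_q(SBML_NS, 'localParameter')}"
        ):
            params[pel.get("id")] = float(pel.get("value"))
        law = RateLaw(annot.get("kind"), params, json.loads(annot.get("speciesRefs")))
        modifiers = [
            ref.get("species")
            for ref in rel.iterfind(
                f"{_q(SBML_NS, 'listOfModifiers')}/{_q(SBML_NS, 'modifierSpeciesReference')}"
            )
        ]
        reactions.append(
            ReactionDef(
                rel.get("id"),
                _stoich_list(rel, "listOfReactants"),
                _stoich_list(rel, "listOfProducts"),
                law,
                modifiers,
            )
        )

    events = []
    for ev in mdl.iterfind(f"{_q(SBML_NS, 'listOfEvents')}/{_q(SBML_NS, 'event')}"):
        if ev.find(_q(SBML_NS, "delay")) is not None:
            raise UnsupportedSBMLError(
                f"event {ev.get('id')!r}: delayed events are not supported"
            )
        trig = ev.find(_q(SBML_NS, "trigger"))
        cn = trig.find(f"{_q(MATHML_NS, 'math')}/{_q(MATHML_NS, 'apply')}/{_q(MATHML_NS, 'cn')}")
        if cn is None:
            raise UnsupportedSBMLError(
                f"event {ev.get('id')!r}: trigger is not of the form time >= t0"
            )
        time = float(cn.text)
        ea = ev.find(
            f"{_q(SBML_NS, 'listOfEventAssignments')}/{_q(SBML_NS, 'eventAssignment')}"
        )
        value_cn = ea.find(f"{_q(MATHML_NS, 'math')}/{_q(MATHML_NS, 'cn')}")
        if value_cn is None:
            raise UnsupportedSBMLError(
                f"event {ev.get('id')!r}: assignment is not a constant"
            )
        events.append(Event(time, ea.get("variable"), float(value_cn.text)))

    name = mdl.get("name") or mdl.get("id") or "model"
    model = NetworkModel(name=name, species=species, reactions=reactions, events=events)
    problems = validate_model(model)
    if problems:
        raise UnsupportedSBMLError("imported model invalid: " + "; ".join(problems))
    return model
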