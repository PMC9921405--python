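"""SBML Level 3 Version 1 (core) export/import of pathway models.

The writer emits standard SBML structure — compartments, species with the
``boundaryCondition`` flag for clamped species, global parameters, and
reactions with kinetic laws rendered as MathML — so that the models load
in third-party SBML tools.  Because generic MathML cannot be mapped back
onto this package's structured rate laws without symbolic analysis, each
kinetic law (and each parameter's unit string, which SBML would otherwise
require unit definitions for) also carries a structured annotation in the
``urn:hepatosim:sbml`` namespace; the reader reconstructs models from
those annotations, which makes the export -> import round trip exact.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .reaction_network import (
    COMPARTMENTS,
    HillFactor,
    Parameter,
    PathwayModel,
    RateLaw,
    Reaction,
    Species,
)

__all__ = ["write_sbml", "read_sbml", "sbml_string", "model_from_sbml_string"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
HS_NS = "urn:hepatosim:sbml"

NSMAP = {None: SBML_NS}


def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _h(tag: str) -> str:
    return f"{{{HS_NS}}}{tag}"


# ---------------------------------------------------------------------------
# MathML rendering of rate laws
# ---------------------------------------------------------------------------

def _ci(name: str) -> etree._Element:
    el = etree.Element(_m("ci"))
    el.text = f" {name} "
    return el


def _apply(op: str, *children: etree._Element) -> etree._Element:
    el = etree.Element(_m("apply"))
    el.append(etree.Element(_m(op)))
    for c in children:
        el.append(c)
    return el


def _pow(base: etree._Element, exp: etree._Element) -> etree._Element:
    return _apply("power", base, exp)


def _factor_math(fac: HillFactor) -> etree._Element:
    half_n = _pow(_ci(fac.half_conc), _ci(fac.hill_n))
    x_n = _pow(_ci(fac.species_id), _ci(fac.hill_n))
    denom = _apply("plus", _pow(_ci(fac.half_conc), _ci(fac.hill_n)),
                   _pow(_ci(fac.species_id), _ci(fac.hill_n)))
    numer = half_n if fac.kind == "inhibition" else x_n
    return _apply("divide", numer, denom)


def _rate_law_math(rxn: Reaction) -> etree._Element:
    law = rxn.rate_law
    terms: list[etree._Element] = []
    if law.kind == "mass_action":
        terms.extend(_ci(p) for p in law.rate_constants)
        for sid, n in rxn.reactants:
            terms.append(_ci(sid) if n == 1 else _pow(_ci(sid), _int(n)))
    else:
        if law.kcat is not None:
            terms.extend([_ci(law.kcat), _ci(law.enzyme)])
        else:
            terms.append(_ci(law.vmax))
        sub = law.substrate or next(s for s, _ in rxn.reactants
                                    if s != law.enzyme)
        terms.append(_apply("divide", _ci(sub),
                            _apply("plus", _ci(law.km), _ci(sub))))
    terms.extend(_factor_math(f) for f in law.factors)
    math = etree.Element(_m("math"), nsmap={None: MATHML_NS})
    math.append(terms[0] if len(terms) == 1 else _apply("times", *terms))
    return math


def _int(n: int) -> etree._Element:
    el = etree.Element(_m("cn"), type="integer")
    el.text = f" {n} "
    return el


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def sbml_string(model: PathwayModel) -> str:
    root = etree.Element(_s("sbml"), nsmap=NSMAP, level="3", version="1")
    mdl = etree.SubElement(root, _s("model"), id=model.name, name=model.name)

    ann = etree.SubElement(mdl, _s("annotation"))
    etree.SubElement(ann, _h("pathway"), nsmap={"hs": HS_NS},
                     biomarker=model.biomarker_id)

    comps = etree.SubElement(mdl, _s("listOfCompartments"))
    for cid in COMPARTMENTS:
        etree.SubElement(comps, _s("compartment"), id=cid, size="1",
                         spatialDimensions="3", constant="true")

    sps = etree.SubElement(mdl, _s("listOfSpecies"))
    for sp in model.species:
        etree.SubElement(
            sps, _s("species"), id=sp.id, name=sp.name,
            compartment=sp.compartment,
            initialConcentration=repr(sp.initial_concentration),
            boundaryCondition="true" if sp.is_boundary else "false",
            hasOnlySubstanceUnits="false", constant="false")

    pars = etree.SubElement(mdl, _s("listOfParameters"))
    for par in model.parameters.values():
        pel = etree.SubElement(pars, _s("parameter"), id=par.name,
                               value=repr(par.value), constant="true")
        pann = etree.SubElement(pel, _s("annotation"))
        etree.SubElement(pann, _h("units"), nsmap={"hs": HS_NS},
                         value=par.units)

    rxns = etree.SubElement(mdl, _s("listOfReactions"))
    for rxn in model.reactions:
        rel = etree.SubElement(rxns, _s("reaction"), id=rxn.id,
                               reversible="false")
        if rxn.name:
            rel.set("name", rxn.name)
        if rxn.reactants:
            lst = etree.SubElement(rel, _s("listOfReactants"))
            for sid, n in rxn.reactants:
                etree.SubElement(lst, _s("speciesReference"), species=sid,
                                 stoichiometry=str(n), constant="true")
        if rxn.products:
            lst = etree.SubElement(rel, _s("listOfProducts"))
            for sid, n in rxn.products:
                etree.SubElement(lst, _s("speciesReference"), species=sid,
                                 stoichiometry=str(n), constant="true")
        if rxn.modifiers:
            lst = etree.SubElement(rel, _s("listOfModifiers"))
            for sid, role in rxn.modifiers:
                mel = etree.SubElement(lst, _s("modifierSpeciesReference"),
                                       species=sid)
                mann = etree.SubElement(mel, _s("annotation"))
                etree.SubElement(mann, _h("modifierRole"),
                                 nsmap={"hs": HS_NS}, value=role)
        kin = etree.SubElement(rel, _s("kineticLaw"))
        kann = etree.SubElement(kin, _s("annotation"))
        law = rxn.rate_law
        lel = etree.SubElement(kann, _h("rateLaw"), nsmap={"hs": HS_NS},
                               kind=law.kind)
        if law.rate_constants:
            lel.set("rateConstants", " ".join(law.rate_constants))
        for attr in ("kcat", "vmax", "km", "enzyme", "substrate"):
            val = getattr(law, attr)
            if val is not None:
                lel.set(attr, val)
        for fac in law.factors:
            etree.SubElement(lel, _h("hillFactor"), species=fac.species_id,
                             kind=fac.kind, halfConc=fac.half_conc,
                             hillN=fac.hill_n)
        kin.append(_rate_law_math(rxn))

    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def write_sbml(model: PathwayModel, path) -> None:
    """Export a model as an SBML L3V1 document."""
    Path(path).write_text(sbml_string(model))


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

def model_from_sbml_string(text: str) -> PathwayModel:
    root = etree.fromstring(text.encode())
    mdl = root.find(_s("model"))
    if mdl is None:
        raise ValueError("no <model> element in SBML document")
    pathway = mdl.find(f"{_s('annotation')}/{_h('pathway')}")
    if pathway is None:
        raise ValueError("model lacks the hepatosim annotation; only "
                         "documents written by this package can be re-read")
    biomarker = pathway.get("biomarker")

    species = []
    for sel in mdl.findall(f"{_s('listOfSpecies')}/{_s('species')}"):
        species.append(Species(
            id=sel.get("id"), name=sel.get("name") or sel.get("id"),
            compartment=sel.get("compartment"),
            initial_concentration=float(sel.get("initialConcentration", "0")),
            is_boundary=sel.get("boundaryCondition") == "true"))

    parameters = {}
    for pel in mdl.findall(f"{_s('listOfParameters')}/{_s('parameter')}"):
        uel = pel.find(f"{_s('annotation')}/{_h('units')}")
        parameters[pel.get("id")] = Parameter(
            pel.get("id"), float(pel.get("value")),
            uel.get("value") if uel is not None else "dimensionless")

    reactions = []
    for rel in mdl.findall(f"{_s('listOfReactions')}/{_s('reaction')}"):
        def refs(tag):
            return tuple(
                (el.get("species"), int(float(el.get("stoichiometry", "1"))))
                for el in rel.findall(f"{_s(tag)}/{_s('speciesReference')}"))
        modifiers = []
        for mel in rel.findall(f"{_s('listOfModifiers')}"
                               f"/{_s('modifierSpeciesReference')}"):
            role_el = mel.find(f"{_s('annotation')}/{_h('modifierRole')}")
            modifiers.append((mel.get("species"),
                              role_el.get("value") if role_el is not None
                              else "inhibitor"))
        lel = rel.find(f"{_s('kineticLaw')}/{_s('annotation')}/{_h('rateLaw')}")
        if lel is None:
            raise ValueError(f"reaction {rel.get('id')!r} lacks the rate-law "
                             f"annotation")
        factors = tuple(
            HillFactor(f.get("species"), f.get("kind"), f.get("halfConc"),
                       f.get("hillN"))
            for f in lel.findall(_h("hillFactor")))
        law = RateLaw(
            kind=lel.get("kind"),
            rate_constants=tuple((lel.get("rateConstants") or "").split()),
            kcat=lel.get("kcat"), vmax=lel.get("vmax"), km=lel.get("km"),
            enzyme=lel.get("enzyme"), substrate=lel.get("substrate"),
            factors=factors)
        reactions.append(Reaction(
            id=rel.get("id"), reactants=refs("listOfReactants"),
            products=refs("listOfProducts"), modifiers=tuple(modifiers),
            rate_law=law, name=rel.get("name") or ""))

    return PathwayModel(mdl.get("id"), tuple(species), tuple(reactions),
                        parameters, biomarker)


def read_sbml(path) -> PathwayModel:
    """Import a model from an SBML document written by :func:`write_sbml`."""
    return model_from_sbml_string(Path(path).read_text())
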