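"""SBML Level 3 serialisation of the simplified reaction network.

Writes the 10-species, 17-reaction system as an SBML Level 3 Version 1
document with mass-action kinetic laws expressed in MathML, and reads
such documents back.  Species are in substance units (molecule counts)
in a single unit-volume compartment, so the kinetic-law constants are
the stochastic propensity constants used by the simulator.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from lxml import etree

from .model import SPECIES, ParameterSet, ReactionNetwork, build_network

__all__ = ["export_sbml", "read_sbml", "SBML_NS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: Which model parameter each reaction's rate constant is.
_RATE_PARAM = {
    "expression_C": "alpha",
    "expression_F": "alpha",
    "degradation_C": "beta_p",
    "degradation_F": "beta_p",
    "excision_Z00_Z10": "k1c",
    "excision_Z00_Z01": "k1f",
    "excision_Z10_Z11": "k2f",
    "excision_Z01_Z11": "k2c",
    "insertion_Z10_Z00": "k_1c",
    "insertion_Z01_Z00": "k_1f",
    "insertion_Z11_Z10": "k_2f",
    "insertion_Z11_Z01": "k_2c",
    "dilution_Z10X": "delta_X",
    "dilution_Z01X": "delta_X",
    "dilution_Z11Xc": "delta_X",
    "dilution_Z11Xf": "delta_X",
    "dilution_Z00": "delta_D",
}


def _e(parent, tag, **attrs):
    el = etree.SubElement(parent, f"{{{SBML_NS}}}{tag}")
    for k, v in attrs.items():
        el.set(k, v)
    return el


def _kinetic_math(parent, factor_ids: list[str]):
    math = etree.SubElement(parent, f"{{{MATHML_NS}}}math")
    if len(factor_ids) == 1:
        ci = etree.SubElement(math, f"{{{MATHML_NS}}}ci")
        ci.text = f" {factor_ids[0]} "
        return
    apply = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
    etree.SubElement(apply, f"{{{MATHML_NS}}}times")
    for fid in factor_ids:
        ci = etree.SubElement(apply, f"{{{MATHML_NS}}}ci")
        ci.text = f" {fid} "


def export_sbml(
    params: ParameterSet,
    input_condition: tuple[bool, bool] = (True, True),
    initial_dna: int = 1000,
    path: str | Path | None = None,
) -> str:
    """Serialise the network to SBML; returns the XML text.

    The input condition is encoded by zeroing the unused expression
    reaction's rate through dedicated parameters ``alpha_C``/``alpha_F``.
    """
    net = build_network(params, input_condition)
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    model = _e(root, "model", id="blade_simplified_2input", name="Simplified 2-input BLADE model")

    comps = _e(model, "listOfCompartments")
    _e(comps, "compartment", id="cell", size="1", spatialDimensions="3", constant="true")

    species_el = _e(model, "listOfSpecies")
    for i, sp in enumerate(SPECIES):
        amount = float(initial_dna) if sp == "Z00" else 0.0
        _e(
            species_el,
            "species",
            id=sp,
            compartment="cell",
            initialAmount=repr(amount),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )

    pars = _e(model, "listOfParameters")
    for name, value in params.as_dict().items():
        _e(pars, "parameter", id=name, value=repr(float(value)), constant="true")
    cre_on, flp_on = input_condition
    _e(pars, "parameter", id="alpha_C", value=repr(params.alpha if cre_on else 0.0), constant="true")
    _e(pars, "parameter", id="alpha_F", value=repr(params.alpha if flp_on else 0.0), constant="true")

    rxns = _e(model, "listOfReactions")
    for j, name in enumerate(net.names):
        rx = _e(rxns, "reaction", id=name, reversible="false")
        s = net.stoich[j]
        reactants = [(SPECIES[i], -int(s[i])) for i in np.where(s < 0)[0]]
        products = [(SPECIES[i], int(s[i])) for i in np.where(s > 0)[0]]
        if reactants:
            lr = _e(rx, "listOfReactants")
            for sp, st in reactants:
                _e(lr, "speciesReference", species=sp, stoichiometry=str(st), constant="true")
        if products:
            lp = _e(rx, "listOfProducts")
            for sp, st in products:
                _e(lp, "speciesReference", species=sp, stoichiometry=str(st), constant="true")
        kl = _e(rx, "kineticLaw")
        if name == "expression_C":
            factors = ["alpha_C"]
        elif name == "expression_F":
            factors = ["alpha_F"]
        else:
            factors = [_RATE_PARAM[name]]
            for idx in (net.r1[j], net.r2[j]):
                if idx >= 0:
                    factors.append(SPECIES[idx])
        _kinetic_math(kl, factors)

    xml = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
    if path is not None:
        Path(path).write_text(xml)
    return xml


def read_sbml(source: str | Path) -> dict:
    """Parse an SBML document written by :func:`export_sbml`.

    Returns a dict with ``species`` (id -> initial amount),
    ``parameters`` (id -> value) and ``reactions`` (list of dicts with
    id, reactants, products, rate_constant name and value).  Performs
    structural validation: sbml/model elements, level-3 namespace, and
    kinetic-law factors referring to declared parameters/species.
    """
    text = Path(source).read_text() if not str(source).lstrip().startswith("<") else str(source)
    root = etree.fromstring(text.encode())
    if etree.QName(root).localname != "sbml" or etree.QName(root).namespace != SBML_NS:
        raise ValueError("not an SBML level-3 core document")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError("SBML document has no model element")

    species = {
        s.get("id"): float(s.get("initialAmount", "0"))
        for s in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    }
    parameters = {
        p.get("id"): float(p.get("value"))
        for p in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
    }
    reactions = []
    for rx in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        cis = [
            ci.text.strip()
            for ci in rx.findall(f".//{{{MATHML_NS}}}ci")
        ]
        rate_name = next((c for c in cis if c in parameters), None)
        if rate_name is None:
            raise ValueError(f"reaction {rx.get('id')} has no parameter in its kinetic law")
        for c in cis:
            if c not in parameters and c not in species:
                raise ValueError(f"kinetic law refers to undeclared symbol {c!r}")
        reactions.append(
            {
                "id": rx.get("id"),
                "reactants": {
                    sr.get("species"): float(sr.get("stoichiometry", "1"))
                    for sr in rx.findall(f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference")
                },
                "products": {
                    sr.get("species"): float(sr.get("stoichiometry", "1"))
                    for sr in rx.findall(f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference")
                },
                "rate_constant": rate_name,
                "rate_value": parameters[rate_name],
            }
        )
    return {"species": species, "parameters": parameters, "reactions": reactions}
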