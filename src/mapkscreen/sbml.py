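"""Minimal SBML Level 3 export/import for the cascade and the reaction store.

Writes a self-contained SBML L3V1 document: species (with the p-/pp-
display-name convention), global parameters for the rate constants, and
reactions with elementary mass-action kinetic laws in MathML.  The reader
recovers species, reactions (participants with stoichiometry, modifiers)
and a textual rate-law descriptor — enough for model interchange and for
the reaction-based database, not a general SBML toolkit (no units, no
events, no rules).
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import (FIXED_ACTIVATION, ConcentrationVector, KineticRates,
                      ReactionNetwork)

__all__ = ["write_sbml", "read_sbml", "SbmlReaction", "SbmlModel"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def sanitize_id(name: str) -> str:
    """SBML SId-safe identifier for a display name."""
    sid = name.replace("*", "_act").replace(":", "__")
    sid = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    sid = re.sub(r"___+", "__", sid).strip("_") or "x"
    if re.match(r"^\d", sid):
        sid = "_" + sid
    return sid


def write_sbml(network: ReactionNetwork, rates: KineticRates | None = None,
               cv: ConcentrationVector | None = None, S: float = 0.0,
               model_id: str = "mapk_cascade") -> str:
    """Serialize the assembled network to an SBML L3 document string."""
    ET.register_namespace("", SBML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model",
                          {"id": model_id, "name": model_id})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true"})

    init = cv.quiescent_state() if cv is not None else np.zeros(network.n_species)
    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for i, name in enumerate(network.species):
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": sanitize_id(name), "name": name, "compartment": "cell",
            "initialConcentration": repr(float(init[i])),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false"})

    params = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    pvals = {n: (rates[n] if rates is not None else 1.0)
             for n in network.rate_names}
    pvals[FIXED_ACTIVATION] = 1.0
    pvals["S"] = float(S)
    for name, value in pvals.items():
        ET.SubElement(params, f"{{{SBML_NS}}}parameter", {
            "id": sanitize_id(name), "name": name, "value": repr(float(value)),
            "constant": "true"})

    rxns = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for j, r in enumerate(network.reactions):
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", {
            "id": f"r{j:02d}_{sanitize_id(r.name.replace(' ', '_'))}",
            "name": r.name, "reversible": "false", "fast": "false"})
        reactants = {sp: -c for sp, c in r.stoich.items() if c < 0}
        products = {sp: c for sp, c in r.stoich.items() if c > 0}
        modifiers = [sp for sp in r.rate_species if sp not in reactants]
        if reactants:
            lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp, c in sorted(reactants.items()):
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference", {
                    "species": sanitize_id(network.species[sp]),
                    "stoichiometry": str(c), "constant": "true"})
        if products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, c in sorted(products.items()):
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference", {
                    "species": sanitize_id(network.species[sp]),
                    "stoichiometry": str(c), "constant": "true"})
        if modifiers:
            lom = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for sp in modifiers:
                ET.SubElement(lom, f"{{{SBML_NS}}}modifierSpeciesReference", {
                    "species": sanitize_id(network.species[sp])})
        law = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(law, f"{{{MATHML_NS}}}math")
        factors = [sanitize_id(r.rate_constant)]
        if r.stimulus_scaled:
            factors.append("S")
        factors += [sanitize_id(network.species[sp]) for sp in r.rate_species]
        apply_el = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{MATHML_NS}}}times")
        for fct in factors:
            ci = ET.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
            ci.text = fct

    ET.indent(root)
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode"))


@dataclass
class SbmlReaction:
    """Parsed reaction: participants by species id with stoichiometry."""

    id: str
    name: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    modifiers: list[str] = field(default_factory=list)
    rate_law: str = ""


@dataclass
class SbmlModel:
    id: str
    species: dict[str, str]           # id -> display name
    parameters: dict[str, float]
    reactions: list[SbmlReaction]


def _math_to_text(el) -> str:
    """Flatten a MathML product into 'a * b * c'; fall back to raw XML."""
    apply_el = el.find(f"{{{MATHML_NS}}}apply")
    if apply_el is not None and apply_el.find(f"{{{MATHML_NS}}}times") is not None:
        cis = [c.text.strip() for c in apply_el.findall(f"{{{MATHML_NS}}}ci")]
        if cis:
            return " * ".join(cis)
    return re.sub(r"\s+", " ", ET.tostring(el, encoding="unicode")).strip()


def read_sbml(source: str | Path) -> SbmlModel:
    """Parse an SBML document (path or XML string) into a plain model record."""
    text = str(source)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    root = ET.fromstring(text)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError("document has no SBML model element")
    species = {}
    for sp in model.iter(f"{{{SBML_NS}}}species"):
        species[sp.get("id")] = sp.get("name", sp.get("id"))
    parameters = {}
    for p in model.iter(f"{{{SBML_NS}}}parameter"):
        try:
            parameters[p.get("id")] = float(p.get("value", "nan"))
        except ValueError:
            parameters[p.get("id")] = float("nan")
    reactions = []
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        rec = SbmlReaction(id=rx.get("id"), name=rx.get("name", rx.get("id")))
        for tag, store in (("listOfReactants", rec.reactants),
                           ("listOfProducts", rec.products)):
            lo = rx.find(f"{{{SBML_NS}}}{tag}")
            if lo is not None:
                for sr in lo.findall(f"{{{SBML_NS}}}speciesReference"):
                    store[sr.get("species")] = float(sr.get("stoichiometry", "1"))
        lom = rx.find(f"{{{SBML_NS}}}listOfModifiers")
        if lom is not None:
            rec.modifiers = [m.get("species") for m in
                             lom.findall(f"{{{SBML_NS}}}modifierSpeciesReference")]
        law = rx.find(f"{{{SBML_NS}}}kineticLaw")
        if law is not None:
            math = law.find(f"{{{MATHML_NS}}}math")
            if math is not None:
                rec.rate_law = _math_to_text(math)
        reactions.append(rec)
    return SbmlModel(id=model.get("id", "model"), species=species,
                     parameters=parameters, reactions=reactions)
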