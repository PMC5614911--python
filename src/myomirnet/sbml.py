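"""SBML Level 3 Version 1 exchange for mass-action networks.

The writer emits the subset of SBML these models need: species with
integer initial amounts in substance units "item" (molecule counts),
global parameters, and one reaction per mass-action step whose kinetic
law is the explicit MathML product ``k * reactant1 [* reactant2]``.
Element ordering is deterministic (stable diffs).  The reader accepts
Level 3 Version 1 and, read-only, the older Level 2 Version 4 dialect;
any kinetic law that is not a plain mass-action product of one
parameter and the reactant species is rejected with a named diagnostic
rather than silently approximated.

Gene-state conservation is deliberately exported as plain species —
conservation is emergent from the stoichiometry, which keeps the files
readable by any SBML tool.  Conservation groups and readout aliases are
package-level metadata and are carried in an annotation element so the
round trip is the identity on the network data model.
"""

from __future__ import annotations

import json
from pathlib import Path

from lxml import etree

from .core import ParameterSet, ReactionNetwork, validate_network

__all__ = ["export_sbml", "import_sbml", "SbmlError", "UnsupportedKineticLaw"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
SBML_L2_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://myomirnet.invalid/sbml-annotations"


class SbmlError(ValueError):
    """Malformed or unreadable SBML input."""


class UnsupportedKineticLaw(SbmlError):
    """Kinetic law is not zeroth/first/second-order mass action."""


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_sbml(net: ReactionNetwork, path: str | Path) -> Path:
    """Write ``net`` as SBML L3V1 with mass-action kinetic laws."""
    issues = validate_network(net)
    if issues:
        raise SbmlError(f"refusing to export invalid network: {issues}")
    nsmap = {None: SBML_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, _q("model"))
    model.set("id", net.name)
    model.set("substanceUnits", "item")
    model.set("timeUnits", "second")
    model.set("extentUnits", "item")

    # package metadata (conservation groups, readouts) as an annotation
    annot = etree.SubElement(model, _q("annotation"))
    meta = etree.SubElement(annot, _q("networkMetadata", ANNOT_NS))
    meta.text = json.dumps(
        {
            "conserved_groups": [sorted(g) for g in net.conserved_groups],
            "readouts": {k: list(v) for k, v in net.readouts.items()},
            "descriptions": {s.id: s.description for s in net.species},
            "gene_states": [s.id for s in net.species if s.is_gene_state],
        },
        sort_keys=True,
    )

    comps = etree.SubElement(model, _q("listOfCompartments"))
    comp = etree.SubElement(comps, _q("compartment"))
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")

    species_el = etree.SubElement(model, _q("listOfSpecies"))
    for s in net.species:
        el = etree.SubElement(species_el, _q("species"))
        el.set("id", s.id)
        el.set("compartment", "cell")
        el.set("initialAmount", str(float(s.initial_amount)))
        el.set("substanceUnits", "item")
        el.set("hasOnlySubstanceUnits", "true")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")

    params_el = etree.SubElement(model, _q("listOfParameters"))
    for name, value in net.parameters.items():
        el = etree.SubElement(params_el, _q("parameter"))
        el.set("id", name)
        el.set("value", repr(float(value)))
        el.set("constant", "true")

    rxns_el = etree.SubElement(model, _q("listOfReactions"))
    for r in net.reactions:
        el = etree.SubElement(rxns_el, _q("reaction"))
        el.set("id", r.id)
        el.set("reversible", "false")
        if r.note:
            notes = etree.SubElement(el, _q("notes"))
            body = etree.SubElement(
                notes, "{http://www.w3.org/1999/xhtml}p"
            )
            body.text = r.note
        for side, tag in (
            (r.reactants, "listOfReactants"),
            (r.products, "listOfProducts"),
        ):
            if not side:
                continue
            lst = etree.SubElement(el, _q(tag))
            counts: dict[str, int] = {}
            for sid in side:
                counts[sid] = counts.get(sid, 0) + 1
            for sid in sorted(counts):
                ref = etree.SubElement(lst, _q("speciesReference"))
                ref.set("species", sid)
                ref.set("stoichiometry", str(float(counts[sid])))
                ref.set("constant", "true")
        law = etree.SubElement(el, _q("kineticLaw"))
        math = etree.SubElement(law, _q("math", MATHML_NS))
        factors = [r.rate_constant_name, *r.reactants]
        if len(factors) == 1:
            ci = etree.SubElement(math, _q("ci", MATHML_NS))
            ci.text = f" {factors[0]} "
        else:
            apply = etree.SubElement(math, _q("apply", MATHML_NS))
            etree.SubElement(apply, _q("times", MATHML_NS))
            for f in factors:
                ci = etree.SubElement(apply, _q("ci", MATHML_NS))
                ci.text = f" {f} "

    path = Path(path)
    path.write_bytes(
        etree.tostring(
            root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    )
    return path


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------


def _parse_kinetic_law(law_el, ns: str) -> list[str]:
    """Return the flat factor list of a mass-action kinetic law."""
    math = law_el.find(_q("math", MATHML_NS))
    if math is None:
        raise UnsupportedKineticLaw("kineticLaw has no <math> element")
    children = [c for c in math if isinstance(c.tag, str)]
    if len(children) != 1:
        raise UnsupportedKineticLaw("kineticLaw math must hold one expression")
    expr = children[0]
    if expr.tag == _q("ci", MATHML_NS):
        return [expr.text.strip()]
    if expr.tag != _q("apply", MATHML_NS):
        raise UnsupportedKineticLaw(
            f"unsupported math element {etree.QName(expr).localname!r}"
        )
    ops = [c for c in expr if isinstance(c.tag, str)]
    if not ops or ops[0].tag != _q("times", MATHML_NS):
        name = etree.QName(ops[0]).localname if ops else "nothing"
        raise UnsupportedKineticLaw(
            f"kinetic law is not a product (found <{name}>); "
            "only mass action is supported"
        )
    factors = []
    for c in ops[1:]:
        if c.tag != _q("ci", MATHML_NS):
            raise UnsupportedKineticLaw(
                "kinetic law factors must be plain identifiers "
                f"(found <{etree.QName(c).localname}>)"
            )
        factors.append(c.text.strip())
    return factors


def import_sbml(path: str | Path) -> ReactionNetwork:
    """Read an SBML file (L3V1, or L2V4 read-only) into a ReactionNetwork."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"malformed XML in {path.name}: {exc}") from exc
    root = tree.getroot()
    ns = etree.QName(root).namespace
    if ns not in (SBML_NS, SBML_L2_NS):
        raise SbmlError(f"unsupported SBML namespace {ns!r}")
    model = root.find(_q("model", ns))
    if model is None:
        raise SbmlError("no <model> element")
    net = ReactionNetwork(name=model.get("id") or path.stem)

    meta = None
    annot = model.find(_q("annotation", ns))
    if annot is not None:
        meta_el = annot.find(_q("networkMetadata", ANNOT_NS))
        if meta_el is not None and meta_el.text:
            meta = json.loads(meta_el.text)
    descriptions = (meta or {}).get("descriptions", {})
    gene_states = set((meta or {}).get("gene_states", []))

    for el in model.findall(
        f"{_q('listOfSpecies', ns)}/{_q('species', ns)}"
    ):
        sid = el.get("id")
        amount = float(el.get("initialAmount") or 0.0)
        if abs(amount - round(amount)) > 1e-9:
            raise SbmlError(
                f"species {sid!r}: non-integer initial amount {amount} "
                "(molecule counts required)"
            )
        net.add_species(
            sid,
            int(round(amount)),
            descriptions.get(sid, ""),
            gene_state=sid in gene_states,
        )

    net.parameters = ParameterSet()
    for el in model.findall(
        f"{_q('listOfParameters', ns)}/{_q('parameter', ns)}"
    ):
        net.parameters[el.get("id")] = float(el.get("value"))

    known_params = set(net.parameters)
    known_species = set(net.species_ids)
    for el in model.findall(
        f"{_q('listOfReactions', ns)}/{_q('reaction', ns)}"
    ):
        rid = el.get("id")
        if el.get("reversible") == "true":
            raise UnsupportedKineticLaw(
                f"reaction {rid!r}: reversible reactions are not supported; "
                "split into forward/backward steps"
            )

        def side(tag: str) -> tuple[str, ...]:
            out: list[str] = []
            for ref in el.findall(f"{_q(tag, ns)}/{_q('speciesReference', ns)}"):
                n = float(ref.get("stoichiometry") or 1.0)
                if abs(n - round(n)) > 1e-9:
                    raise SbmlError(
                        f"reaction {rid!r}: fractional stoichiometry {n}"
                    )
                out.extend([ref.get("species")] * int(round(n)))
            return tuple(out)

        reactants = side("listOfReactants")
        products = side("listOfProducts")
        if len(reactants) > 2:
            raise UnsupportedKineticLaw(
                f"reaction {rid!r}: order {len(reactants)} exceeds "
                "mass-action limit of 2"
            )
        law = el.find(_q("kineticLaw", ns))
        if law is None:
            raise UnsupportedKineticLaw(f"reaction {rid!r}: no kinetic law")
        # L2 allows local parameters; fold them into the global set
        for lp in law.findall(
            f"{_q('listOfParameters', ns)}/{_q('parameter', ns)}"
        ) + law.findall(
            f"{_q('listOfLocalParameters', ns)}/{_q('localParameter', ns)}"
        ):
            net.parameters.setdefault(lp.get("id"), float(lp.get("value")))
            known_params.add(lp.get("id"))
        factors = _parse_kinetic_law(law, ns)
        params_in_law = [f for f in factors if f in known_params]
        species_in_law = sorted(f for f in factors if f in known_species)
        unknown = [
            f for f in factors
            if f not in known_params and f not in known_species
        ]
        if unknown or len(params_in_law) != 1:
            raise UnsupportedKineticLaw(
                f"reaction {rid!r}: kinetic law {factors} is not "
                "k * reactants mass action"
            )
        if species_in_law != sorted(reactants):
            raise UnsupportedKineticLaw(
                f"reaction {rid!r}: kinetic-law species {species_in_law} "
                f"do not match reactants {sorted(reactants)}"
            )
        note = ""
        notes_el = el.find(_q("notes", ns))
        if notes_el is not None:
            note = " ".join(notes_el.itertext()).strip()
        net.add_reaction(rid, reactants, products, params_in_law[0], note)

    if meta:
        for group in meta.get("conserved_groups", []):
            net.add_conserved(*group)
        net.readouts = {
            k: tuple(v) for k, v in meta.get("readouts", {}).items()
        }
    issues = validate_network(net)
    if issues:
        raise SbmlError(f"imported network is inconsistent: {issues}")
    return net
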