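"""SBML Level 3 Version 2 export of the two-cell model, plus a generic reader.

The exporter unrolls the coupled two-cell network into one SBML reaction
per derivative term: transcription (with Hill kinetic laws and the
regulators as modifiers), mRNA export, translation, compartment
transport, linear and saturated decay, the trans-activation reaction
(consuming sender membrane DLL1 and receiver membrane NOTCH1, producing
receiver cytoplasmic NICD) and the same-cell cis-inhibition reactions in
cytoplasm and membrane.  Cells are encoded as compartment-name prefixes
(``c0_cyt``, ``c1_mem``, ...).

The reader is deliberately generic: it reconstructs an ODE right-hand
side purely from the document's species, parameters, stoichiometry and
MathML kinetic laws, without reference to the native model code -- which
makes an SBML round-trip an independent cross-check of the simulator.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .grn_model import GrnModel, species_names
from .interfaces import RunConfig

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

__all__ = ["export_sbml", "load_sbml", "SbmlModel"]


# ---------------------------------------------------------------------------
# MathML construction helpers

def _m(tag: str, *children: ET.Element, text: str | None = None) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}{tag}")
    if text is not None:
        el.text = text
    el.extend(children)
    return el


def _ci(name: str) -> ET.Element:
    return _m("ci", text=f" {name} ")


def _cn(value: float) -> ET.Element:
    return _m("cn", text=f" {value!r} ")


def _apply(op: str, *args: ET.Element) -> ET.Element:
    return _m("apply", _m(op), *args)


def _times(*args: ET.Element) -> ET.Element:
    return _apply("times", *args)


def _hill_rep(conc: ET.Element, H: ET.Element, h: ET.Element) -> ET.Element:
    return _apply("divide", _cn(1.0),
                  _apply("plus", _cn(1.0),
                         _apply("power", _apply("divide", conc, H), h)))


def _hill_act(conc: ET.Element, H: ET.Element, h: ET.Element) -> ET.Element:
    x = _apply("power", _apply("divide", conc, H), h)
    return _apply("divide", x, _apply("plus", _cn(1.0), x))


# ---------------------------------------------------------------------------
# export

_COMPARTMENT_OF = {
    "mN": "nuc", "pN": "nuc", "mC": "cyt", "pC": "cyt",
    "pM": "mem", "m": "cyt",
}


def _species_id(cell: int, name: str) -> str:
    return f"c{cell}_" + name.replace(".", "_")


def export_sbml(cfg: RunConfig, path: str | Path) -> None:
    """Write the two-cell, non-growing configuration as SBML L3V2.

    The initial concentrations are the configuration's pre-noise initial
    state.  Growing-PSM configurations are rejected: conveyor growth and
    mitotic gating are not representable as a fixed reaction network.
    """
    cfg.validate()
    if cfg.psm.enabled:
        raise ValueError("growing-PSM configurations cannot be exported to SBML")
    if tuple(cfg.shape) != (2,):
        raise ValueError("SBML export covers exactly the two-cell system")
    model = cfg.build_model()
    from .simulation import initial_states
    init = initial_states(cfg, model, 2)

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model",
                        {"id": "delta_notch_two_cell", "name": "Delta/Notch coupled Hes7 oscillators, two cells"})

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for cell in (0, 1):
        for cname in ("nuc", "cyt", "mem"):
            ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                          {"id": f"c{cell}_{cname}", "size": "1",
                           "spatialDimensions": "3", "constant": "true"})

    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for cell in (0, 1):
        for k, name in enumerate(model.species):
            suffix = name.split(".")[1]
            ET.SubElement(sps, f"{{{SBML_NS}}}species", {
                "id": _species_id(cell, name),
                "compartment": f"c{cell}_{_COMPARTMENT_OF[suffix]}",
                "initialConcentration": repr(float(init[cell, k])),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false", "constant": "false",
            })

    pars = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    par_ids = {}
    for gene, key, in ((g, k) for g, blk in model.params.to_dict().items() for k in blk):
        pid = f"{gene}_{key}"
        par_ids[(gene, key)] = pid
        ET.SubElement(pars, f"{{{SBML_NS}}}parameter",
                      {"id": pid, "value": repr(model.params[gene][key]),
                       "constant": "true"})

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")

    def P(gene: str, key: str) -> ET.Element:
        return _ci(par_ids[(gene, key)])

    def add_reaction(rid: str, reactants: list[str], products: list[str],
                     modifiers: list[str], math: ET.Element) -> None:
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction",
                           {"id": rid, "reversible": "false"})
        if reactants:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s in reactants:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": "1", "constant": "true"})
        if products:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s in products:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": "1", "constant": "true"})
        if modifiers:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for s in modifiers:
                ET.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference", {"species": s})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        math_el.append(math)

    imp, exp = model._nicd_transport_rates()
    # transport rates resolve to one of the two printed constants
    imp_key = "epC" if imp == model.params["nicd"]["epC"] else "epN"
    exp_key = "epN" if imp_key == "epC" else "epC"

    for i in (0, 1):
        j = 1 - i
        S = lambda name, cell=None: _species_id(i if cell is None else cell, name)

        # --- Hes7 ------------------------------------------------------
        promoter = _times(
            _hill_rep(_ci(S("hes7.pN")), P("hes7", "H_R"), P("hes7", "h_R")),
            _hill_act(_ci(S("nicd.pN")), P("hes7", "H_A"), P("hes7", "h_A")))
        add_reaction(f"hes7_transcription_c{i}", [], [S("hes7.mN")],
                     [S("hes7.pN"), S("nicd.pN")],
                     _times(P("hes7", "k"), promoter))
        add_reaction(f"hes7_mN_decay_c{i}", [S("hes7.mN")], [], [],
                     _times(P("hes7", "dmN"), _ci(S("hes7.mN"))))
        add_reaction(f"hes7_mRNA_export_c{i}", [S("hes7.mN")], [S("hes7.mC")], [],
                     _times(P("hes7", "emN"), _ci(S("hes7.mN"))))
        add_reaction(f"hes7_mC_decay_c{i}", [S("hes7.mC")], [], [],
                     _times(P("hes7", "dmC"), _ci(S("hes7.mC"))))
        add_reaction(f"hes7_translation_c{i}", [], [S("hes7.pC")], [S("hes7.mC")],
                     _times(P("hes7", "K"), _ci(S("hes7.mC"))))
        add_reaction(f"hes7_pC_decay_c{i}", [S("hes7.pC")], [], [],
                     _times(P("hes7", "dpC"), _ci(S("hes7.pC"))))
        add_reaction(f"hes7_nuclear_import_c{i}", [S("hes7.pC")], [S("hes7.pN")], [],
                     _times(P("hes7", "epC"), _ci(S("hes7.pC"))))
        add_reaction(f"hes7_nuclear_export_c{i}", [S("hes7.pN")], [S("hes7.pC")], [],
                     _times(P("hes7", "epN"), _ci(S("hes7.pN"))))
        add_reaction(f"hes7_pN_saturated_decay_c{i}", [S("hes7.pN")], [], [],
                     _apply("divide",
                            _times(P("hes7", "G"), _ci(S("hes7.pN"))),
                            _apply("plus", P("hes7", "F"), _ci(S("hes7.pN")))))

        # --- NICD ------------------------------------------------------
        if model.lfng_enabled:
            mod = _apply("plus", P("nicd", "r0"),
                         _times(P("nicd", "raLfng"),
                                _hill_act(_ci(S("lfng.pC")),
                                          P("coupling", "lfng_mod_H"),
                                          P("coupling", "lfng_mod_h"))))
        else:
            mod = P("nicd", "r0")
        add_reaction(f"trans_activation_c{i}",
                     [S("notch1.pM"), S("dll1.pM", cell=j)], [S("nicd.pC")],
                     ([S("lfng.pC")] if model.lfng_enabled else []),
                     _times(P("nicd", "rDN"), _ci(S("notch1.pM")),
                            _ci(S("dll1.pM", cell=j)), mod))
        add_reaction(f"nicd_nuclear_import_c{i}", [S("nicd.pC")], [S("nicd.pN")], [],
                     _times(P("nicd", imp_key), _ci(S("nicd.pC"))))
        add_reaction(f"nicd_nuclear_export_c{i}", [S("nicd.pN")], [S("nicd.pC")], [],
                     _times(P("nicd", exp_key), _ci(S("nicd.pN"))))
        add_reaction(f"nicd_pC_decay_c{i}", [S("nicd.pC")], [], [],
                     _times(P("nicd", "dpC"), _ci(S("nicd.pC"))))

        # --- Dll1 ------------------------------------------------------
        add_reaction(f"dll1_transcription_c{i}", [], [S("dll1.mN")], [S("hes7.pN")],
                     _times(P("dll1", "k"),
                            _hill_rep(_ci(S("hes7.pN")), P("dll1", "H_R"),
                                      P("dll1", "h_R"))))
        add_reaction(f"dll1_mN_decay_c{i}", [S("dll1.mN")], [], [],
                     _times(P("dll1", "dmN"), _ci(S("dll1.mN"))))
        add_reaction(f"dll1_mRNA_export_c{i}", [S("dll1.mN")], [S("dll1.mC")], [],
                     _times(P("dll1", "emN"), _ci(S("dll1.mN"))))
        add_reaction(f"dll1_mC_decay_c{i}", [S("dll1.mC")], [], [],
                     _times(P("dll1", "dmC"), _ci(S("dll1.mC"))))
        add_reaction(f"dll1_translation_c{i}", [], [S("dll1.pC")], [S("dll1.mC")],
                     _times(P("dll1", "K"), _ci(S("dll1.mC"))))
        add_reaction(f"dll1_pC_decay_c{i}", [S("dll1.pC")], [], [],
                     _times(P("dll1", "dpC"), _ci(S("dll1.pC"))))
        add_reaction(f"dll1_membrane_delivery_c{i}", [S("dll1.pC")], [S("dll1.pM")], [],
                     _times(P("dll1", "epM"), _ci(S("dll1.pC"))))
        add_reaction(f"dll1_pM_decay_c{i}", [S("dll1.pM")], [], [],
                     _times(P("dll1", "dpM"), _ci(S("dll1.pM"))))
        if model.dll1_recycling:
            add_reaction(f"dll1_membrane_recycling_c{i}",
                         [S("dll1.pM")], [S("dll1.pC")], [],
                         _times(P("dll1", "epC"), _ci(S("dll1.pM"))))

        # --- Notch1 ----------------------------------------------------
        add_reaction(f"notch1_transcription_c{i}", [], [S("notch1.m")], [],
                     P("notch1", "k"))
        add_reaction(f"notch1_m_decay_c{i}", [S("notch1.m")], [], [],
                     _times(P("notch1", "dm"), _ci(S("notch1.m"))))
        add_reaction(f"notch1_translation_c{i}", [], [S("notch1.pC")], [S("notch1.m")],
                     _times(P("notch1", "K"), _ci(S("notch1.m"))))
        add_reaction(f"notch1_pC_decay_c{i}", [S("notch1.pC")], [], [],
                     _times(P("notch1", "dpC"), _ci(S("notch1.pC"))))
        add_reaction(f"notch1_membrane_delivery_c{i}",
                     [S("notch1.pC")], [S("notch1.pM")], [],
                     _times(P("notch1", "epC"), _ci(S("notch1.pC"))))
        add_reaction(f"notch1_pM_decay_c{i}", [S("notch1.pM")], [], [],
                     _times(P("notch1", "dpM"), _ci(S("notch1.pM"))))

        # --- cis-inhibition (same cell, per compartment) ---------------
        add_reaction(f"cis_inhibition_cyt_c{i}",
                     [S("dll1.pC"), S("notch1.pC")], [], [],
                     _times(P("coupling", "rDNcis"), _ci(S("dll1.pC")),
                            _ci(S("notch1.pC"))))
        add_reaction(f"cis_inhibition_mem_c{i}",
                     [S("dll1.pM"), S("notch1.pM")], [], [],
                     _times(P("coupling", "rDNcis"), _ci(S("dll1.pM")),
                            _ci(S("notch1.pM"))))

        # --- Lfng ------------------------------------------------------
        if model.lfng_enabled:
            promoter_l = _times(
                _hill_rep(_ci(S("hes7.pN")), P("lfng", "H_R"), P("lfng", "h_R")),
                _hill_act(_ci(S("nicd.pN")), P("lfng", "H_A"), P("lfng", "h_A")))
            add_reaction(f"lfng_transcription_c{i}", [], [S("lfng.mN")],
                         [S("hes7.pN"), S("nicd.pN")],
                         _times(P("lfng", "k"), promoter_l))
            add_reaction(f"lfng_mN_decay_c{i}", [S("lfng.mN")], [], [],
                         _times(P("lfng", "dmN"), _ci(S("lfng.mN"))))
            add_reaction(f"lfng_mRNA_export_c{i}", [S("lfng.mN")], [S("lfng.mC")], [],
                         _times(P("lfng", "emN"), _ci(S("lfng.mN"))))
            add_reaction(f"lfng_mC_decay_c{i}", [S("lfng.mC")], [], [],
                         _times(P("lfng", "dmC"), _ci(S("lfng.mC"))))
            add_reaction(f"lfng_translation_c{i}", [], [S("lfng.pC")], [S("lfng.mC")],
                         _times(P("lfng", "K"), _ci(S("lfng.mC"))))
            add_reaction(f"lfng_pC_decay_c{i}", [S("lfng.pC")], [], [],
                         _times(P("lfng", "dpC"), _ci(S("lfng.pC"))))
            add_reaction(f"lfng_nuclear_import_c{i}", [S("lfng.pC")], [S("lfng.pN")], [],
                         _times(P("lfng", "epC"), _ci(S("lfng.pC"))))
            add_reaction(f"lfng_nuclear_export_c{i}", [S("lfng.pN")], [S("lfng.pC")], [],
                         _times(P("lfng", "epN"), _ci(S("lfng.pN"))))
            add_reaction(f"lfng_pN_saturated_decay_c{i}", [S("lfng.pN")], [], [],
                         _apply("divide",
                                _times(P("lfng", "G"), _ci(S("lfng.pN"))),
                                _apply("plus", P("lfng", "F"), _ci(S("lfng.pN")))))

    _structural_check(root)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def _structural_check(root: ET.Element) -> None:
    ns = {"s": SBML_NS, "m": MATHML_NS}
    comp_ids = {c.get("id") for c in root.iterfind(".//s:compartment", ns)}
    sp_ids = [s.get("id") for s in root.iterfind(".//s:species", ns)]
    par_ids = {p.get("id") for p in root.iterfind(".//s:parameter", ns)}
    rx_ids = [r.get("id") for r in root.iterfind(".//s:reaction", ns)]
    if len(set(sp_ids)) != len(sp_ids) or len(set(rx_ids)) != len(rx_ids):
        raise AssertionError("duplicate SBML ids")
    for s in root.iterfind(".//s:species", ns):
        if s.get("compartment") not in comp_ids:
            raise AssertionError(f"species {s.get('id')} in unknown compartment")
    known = set(sp_ids) | par_ids
    for ci in root.iterfind(".//m:ci", ns):
        if ci.text.strip() not in known:
            raise AssertionError(f"unresolved symbol {ci.text.strip()!r}")
    for ref in root.iterfind(".//s:speciesReference", ns):
        if ref.get("species") not in set(sp_ids):
            raise AssertionError("dangling species reference")


# ---------------------------------------------------------------------------
# generic import

def _compile_mathml(node: ET.Element) -> Callable[[dict], float]:
    tag = node.tag.split("}")[-1]
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise ValueError("math element must have one child")
        return _compile_mathml(children[0])
    if tag == "ci":
        name = node.text.strip()
        return lambda env, _n=name: env[_n]
    if tag == "cn":
        val = float(node.text.strip())
        return lambda env, _v=val: _v
    if tag == "apply":
        children = list(node)
        op = children[0].tag.split("}")[-1]
        args = [_compile_mathml(c) for c in children[1:]]
        if op == "times":
            return lambda env: float(np.prod([a(env) for a in args]))
        if op == "plus":
            return lambda env: float(sum(a(env) for a in args))
        if op == "minus":
            if len(args) == 1:
                return lambda env: -args[0](env)
            return lambda env: args[0](env) - args[1](env)
        if op == "divide":
            return lambda env: args[0](env) / args[1](env)
        if op == "power":
            return lambda env: args[0](env) ** args[1](env)
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


@dataclass
class SbmlModel:
    """ODE system reconstructed from an SBML document."""

    species: list[str]
    initial: np.ndarray
    parameters: dict[str, float]
    reactions: list[tuple[dict[str, float], Callable[[dict], float]]]

    def rhs(self, y: np.ndarray) -> np.ndarray:
        env = dict(self.parameters)
        env.update(zip(self.species, y))
        dy = np.zeros_like(y)
        index = {s: i for i, s in enumerate(self.species)}
        for stoich, rate in self.reactions:
            v = rate(env)
            for sp, coef in stoich.items():
                dy[index[sp]] += coef * v
        return dy


def load_sbml(path: str | Path) -> SbmlModel:
    """Parse an SBML L3V2 document into an integrable ODE system."""
    ns = {"s": SBML_NS, "m": MATHML_NS}
    root = ET.parse(path).getroot()
    species, initial = [], []
    for s in root.iterfind(".//s:species", ns):
        species.append(s.get("id"))
        initial.append(float(s.get("initialConcentration", "0")))
    parameters = {p.get("id"): float(p.get("value"))
                  for p in root.iterfind(".//s:parameter", ns)}
    reactions = []
    for rx in root.iterfind(".//s:reaction", ns):
        stoich: dict[str, float] = {}
        for ref in rx.iterfind("./s:listOfReactants/s:speciesReference", ns):
            sp = ref.get("species")
            stoich[sp] = stoich.get(sp, 0.0) - float(ref.get("stoichiometry", "1"))
        for ref in rx.iterfind("./s:listOfProducts/s:speciesReference", ns):
            sp = ref.get("species")
            stoich[sp] = stoich.get(sp, 0.0) + float(ref.get("stoichiometry", "1"))
        math = rx.find("./s:kineticLaw/m:math", ns)
        if math is None:
            raise ValueError(f"reaction {rx.get('id')} lacks a kinetic law")
        reactions.append((stoich, _compile_mathml(math)))
    return SbmlModel(species=species, initial=np.array(initial),
                     parameters=parameters, reactions=reactions)
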