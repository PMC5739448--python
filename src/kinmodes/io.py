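"""Model serialization: native JSON, minimal mass-action SBML, TSV matrices.

The native JSON format mirrors :class:`~kinmodes.network.ReactionNetwork`
verbatim and round-trips exactly.  The SBML layer targets Level 3 core and
only the elementary mass-action subset this package analyzes: each kinetic
law must be a single difference (or single product) of rate-constant times
concentration monomials whose species powers match the reaction
stoichiometry.  Anything else is rejected with a clear error rather than
silently approximated.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from lxml import etree

from .network import (
    KineticState,
    ModelDefinitionError,
    Reaction,
    ReactionNetwork,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def network_to_dict(
    network: ReactionNetwork, state: KineticState | None = None
) -> dict:
    doc = {
        "name": network.name,
        "units": dict(network.units),
        "species": list(network.species),
        "reactions": [
            {
                "id": r.id,
                "substrates": dict(r.substrates),
                "products": dict(r.products),
                "k_forward": r.k_fwd,
                "k_reverse": r.k_rev,
            }
            for r in network.reactions
        ],
    }
    if state is not None:
        doc["state"] = {
            "concentrations": {
                sp: float(state.x[i]) for i, sp in enumerate(network.species)
            },
            "residual": state.residual,
            "is_steady": bool(state.is_steady),
            "tolerance": state.tolerance,
        }
    return doc


def network_from_dict(doc: Mapping) -> tuple[ReactionNetwork, KineticState | None]:
    try:
        reactions = [
            Reaction(
                id=r["id"],
                substrates={k: int(v) for k, v in r["substrates"].items()},
                products={k: int(v) for k, v in r["products"].items()},
                k_fwd=float(r["k_forward"]),
                k_rev=float(r.get("k_reverse", 0.0)),
            )
            for r in doc["reactions"]
        ]
        network = ReactionNetwork(
            species=list(doc["species"]),
            reactions=reactions,
            name=doc.get("name", "network"),
            units=dict(doc.get("units", {"concentration": "mmol/L", "time": "h"})),
        )
    except (KeyError, TypeError) as exc:
        raise ModelDefinitionError(f"malformed model document: {exc}") from exc
    state = None
    if "state" in doc:
        state = KineticState.at(network, doc["state"]["concentrations"])
    return network, state


def write_json(
    path: str | Path, network: ReactionNetwork, state: KineticState | None = None
) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(network, state), indent=2, sort_keys=False) + "\n"
    )


def read_json(path: str | Path) -> tuple[ReactionNetwork, KineticState | None]:
    return network_from_dict(json.loads(Path(path).read_text()))


def load_model(path: str | Path) -> tuple[ReactionNetwork, KineticState | None]:
    """Dispatch on extension: ``.json`` native format, ``.xml``/``.sbml`` SBML."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_json(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(path)
    raise ModelDefinitionError(f"unrecognized model format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# SBML (Level 3, elementary mass action only)
# ---------------------------------------------------------------------------

def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _math_monomial(k_name: str, side: Mapping[str, int]) -> etree._Element:
    """MathML for k * prod(species^stoich)."""
    factors = [(_ci(k_name))]
    for sp, st in side.items():
        if st == 1:
            factors.append(_ci(sp))
        else:
            power = etree.Element(_m("apply"))
            etree.SubElement(power, _m("power"))
            power.append(_ci(sp))
            cn = etree.SubElement(power, _m("cn"))
            cn.set("type", "integer")
            cn.text = str(st)
            factors.append(power)
    if len(factors) == 1:
        return factors[0]
    times = etree.Element(_m("apply"))
    etree.SubElement(times, _m("times"))
    for f in factors:
        times.append(f)
    return times


def _ci(name: str) -> etree._Element:
    ci = etree.Element(_m("ci"))
    ci.text = f" {name} "
    return ci


_SANITIZE = str.maketrans({"&": "_and_", " ": "_", "-": "_", "+": "_plus_"})


def _sbml_id(name: str) -> str:
    """SBML SIds must match [A-Za-z_][A-Za-z0-9_]*; map '&' complexes etc."""
    sid = name.translate(_SANITIZE)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def write_sbml(
    path: str | Path, network: ReactionNetwork, state: KineticState | None = None
) -> None:
    """Serialize as SBML L3 with explicit mass-action kinetic laws.

    Species identifiers are sanitized to valid SBML SIds; the original names
    are preserved in the ``name`` attribute and restored on read.
    """
    nsmap = {None: SBML_NS}
    sbml = etree.Element(_s("sbml"), nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "2")
    sbml.set("timeUnits", "hour" if network.units.get("time") == "h" else "second")
    model = etree.SubElement(sbml, _s("model"))
    model.set("id", _sbml_id(network.name))
    model.set("name", network.name)

    comps = etree.SubElement(model, _s("listOfCompartments"))
    comp = etree.SubElement(comps, _s("compartment"))
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")

    sid_of = {sp: _sbml_id(sp) for sp in network.species}
    if len(set(sid_of.values())) != len(sid_of):
        raise ModelDefinitionError("species identifiers collide after SBML sanitizing")

    species_el = etree.SubElement(model, _s("listOfSpecies"))
    for i, sp in enumerate(network.species):
        el = etree.SubElement(species_el, _s("species"))
        el.set("id", sid_of[sp])
        el.set("name", sp)
        el.set("compartment", "cell")
        if state is not None:
            el.set("initialConcentration", repr(float(state.x[i])))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")

    rxns_el = etree.SubElement(model, _s("listOfReactions"))
    for rxn in network.reactions:
        el = etree.SubElement(rxns_el, _s("reaction"))
        el.set("id", _sbml_id(rxn.id))
        el.set("name", rxn.id)
        el.set("reversible", "true" if rxn.k_rev > 0 else "false")
        for side, tag in (
            (rxn.substrates, "listOfReactants"),
            (rxn.products, "listOfProducts"),
        ):
            if not side:
                continue
            lst = etree.SubElement(el, _s(tag))
            for sp, st in side.items():
                ref = etree.SubElement(lst, _s("speciesReference"))
                ref.set("species", sid_of[sp])
                ref.set("stoichiometry", str(st))
                ref.set("constant", "true")
        kl = etree.SubElement(el, _s("kineticLaw"))
        math = etree.SubElement(kl, _m("math"), nsmap={None: MATHML_NS})
        fwd = _math_monomial("kf", {sid_of[sp]: st for sp, st in rxn.substrates.items()})
        if rxn.k_rev > 0:
            apply = etree.SubElement(math, _m("apply"))
            etree.SubElement(apply, _m("minus"))
            apply.append(fwd)
            apply.append(
                _math_monomial(
                    "kr", {sid_of[sp]: st for sp, st in rxn.products.items()}
                )
            )
        else:
            math.append(fwd)
        params = etree.SubElement(kl, _s("listOfLocalParameters"))
        for pid, val in (("kf", rxn.k_fwd), ("kr", rxn.k_rev)):
            p = etree.SubElement(params, _s("localParameter"))
            p.set("id", pid)
            p.set("value", repr(float(val)))
    tree = etree.ElementTree(sbml)
    tree.write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _parse_mathml_monomials(node: etree._Element) -> list[tuple[int, list[str]]]:
    """Flatten a MathML expression into signed products of <ci> symbols.

    Returns ``[(sign, [symbol, symbol, ...]), ...]`` where repeated symbols
    encode powers.  Raises if the expression is not a plain +/-/times/power
    combination (i.e. not elementary mass action).
    """
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ModelDefinitionError("kinetic law math must have one root")
        return _parse_mathml_monomials(children[0])
    if tag == "ci":
        return [(1, [node.text.strip()])]
    if tag == "cn":
        raise ModelDefinitionError(
            "numeric literals in kinetic laws are not elementary mass action"
        )
    if tag != "apply":
        raise ModelDefinitionError(f"unsupported MathML element <{tag}>")
    children = [c for c in node if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op == "minus":
        if len(args) == 1:
            return [(-s, f) for s, f in _parse_mathml_monomials(args[0])]
        if len(args) == 2:
            return _parse_mathml_monomials(args[0]) + [
                (-s, f) for s, f in _parse_mathml_monomials(args[1])
            ]
        raise ModelDefinitionError("minus with more than two arguments")
    if op == "plus":
        out: list[tuple[int, list[str]]] = []
        for a in args:
            out += _parse_mathml_monomials(a)
        return out
    if op == "times":
        prod: list[tuple[int, list[str]]] = [(1, [])]
        for a in args:
            factors = _parse_mathml_monomials(a)
            prod = [
                (s1 * s2, f1 + f2) for s1, f1 in prod for s2, f2 in factors
            ]
            if len(prod) != 1:
                raise ModelDefinitionError(
                    "kinetic law is not a product of simple factors"
                )
        return prod
    if op == "power":
        base, exp = args
        if etree.QName(base).localname != "ci" or etree.QName(exp).localname != "cn":
            raise ModelDefinitionError("only integer powers of species supported")
        n = int(float(exp.text.strip()))
        return [(1, [base.text.strip()] * n)]
    raise ModelDefinitionError(
        f"kinetic law operator <{op}> is not elementary mass action"
    )


def read_sbml(path: str | Path) -> tuple[ReactionNetwork, KineticState | None]:
    """Read an SBML L3 model whose kinetic laws are elementary mass action.

    The declared ``timeUnits`` are recorded in ``network.units['time']``
    (defaulting to hours when the file declares none).  A kinetic law that is
    not a single difference/product of rate-constant-times-concentration
    monomials matching the stoichiometry raises ``ModelDefinitionError``.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    model = root.find(_s("model"))
    if model is None:
        raise ModelDefinitionError("no <model> element in SBML file")
    time_units = root.get("timeUnits") or model.get("timeUnits") or "hour"
    units = {"concentration": "mmol/L", "time": "h" if "hour" in time_units else time_units}

    global_params: dict[str, float] = {}
    lop = model.find(_s("listOfParameters"))
    if lop is not None:
        for p in lop.findall(_s("parameter")):
            if p.get("value") is not None:
                global_params[p.get("id")] = float(p.get("value"))

    species: list[str] = []
    name_of_sid: dict[str, str] = {}
    conc: dict[str, float] = {}
    have_conc = True
    los = model.find(_s("listOfSpecies"))
    if los is None:
        raise ModelDefinitionError("SBML model has no species")
    for el in los.findall(_s("species")):
        sid = el.get("id")
        name = el.get("name") or sid
        name_of_sid[sid] = name
        species.append(name)
        if el.get("initialConcentration") is not None:
            conc[name] = float(el.get("initialConcentration"))
        else:
            have_conc = False

    reactions: list[Reaction] = []
    lor = model.find(_s("listOfReactions"))
    for el in (lor.findall(_s("reaction")) if lor is not None else []):
        rid = el.get("name") or el.get("id")
        subs: dict[str, int] = {}
        prods: dict[str, int] = {}
        for tag, store in (("listOfReactants", subs), ("listOfProducts", prods)):
            lst = el.find(_s(tag))
            if lst is None:
                continue
            for ref in lst.findall(_s("speciesReference")):
                st = int(float(ref.get("stoichiometry", "1")))
                store[name_of_sid[ref.get("species")]] = st
        kl = el.find(_s("kineticLaw"))
        if kl is None:
            raise ModelDefinitionError(f"reaction {rid!r} has no kinetic law")
        params = dict(global_params)
        lolp = kl.find(_s("listOfLocalParameters"))
        if lolp is None:
            lolp = kl.find(_s("listOfParameters"))  # tolerate L2-style
        if lolp is not None:
            for p in lolp:
                params[p.get("id")] = float(p.get("value"))
        math = kl.find(_m("math"))
        if math is None:
            raise ModelDefinitionError(f"reaction {rid!r}: kinetic law has no math")
        monomials = _parse_mathml_monomials(math)
        k_fwd, k_rev = _match_mass_action(
            rid, monomials, params, name_of_sid, subs, prods
        )
        reactions.append(
            Reaction(id=rid, substrates=subs, products=prods, k_fwd=k_fwd, k_rev=k_rev)
        )

    network = ReactionNetwork(
        species=species,
        reactions=reactions,
        name=model.get("name") or model.get("id") or "sbml_model",
        units=units,
    )
    state = KineticState.at(network, conc) if have_conc and conc else None
    return network, state


def _match_mass_action(
    rid: str,
    monomials: list[tuple[int, list[str]]],
    params: Mapping[str, float],
    name_of_sid: Mapping[str, str],
    subs: Mapping[str, int],
    prods: Mapping[str, int],
) -> tuple[float, float]:
    """Check the parsed monomials are exactly (+)k_f.subs [- k_r.prods]."""
    if len(monomials) not in (1, 2):
        raise ModelDefinitionError(
            f"reaction {rid!r}: kinetic law has {len(monomials)} terms; "
            "not elementary mass action"
        )
    k_fwd = k_rev = 0.0
    for sign, symbols in monomials:
        ks = [s for s in symbols if s in params]
        sps = [name_of_sid.get(s, s) for s in symbols if s not in params]
        if len(ks) != 1:
            raise ModelDefinitionError(
                f"reaction {rid!r}: each kinetic-law term needs exactly one "
                "rate-constant parameter"
            )
        counts: dict[str, int] = {}
        for sp in sps:
            counts[sp] = counts.get(sp, 0) + 1
        expected = dict(subs) if sign > 0 else dict(prods)
        if counts != expected:
            raise ModelDefinitionError(
                f"reaction {rid!r}: kinetic-law species powers {counts} do not "
                f"match stoichiometry {expected}; not elementary mass action"
            )
        if sign > 0:
            k_fwd = params[ks[0]]
        else:
            k_rev = params[ks[0]]
    if k_fwd == 0.0 and len(monomials) == 1:
        raise ModelDefinitionError(
            f"reaction {rid!r}: single-term kinetic law must be the forward term"
        )
    return k_fwd, k_rev


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def matrix_frame(
    M: np.ndarray, row_labels: list[str], col_labels: list[str]
) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(M), index=row_labels, columns=col_labels)


def write_matrix_tsv(
    path: str | Path, M: np.ndarray, row_labels: list[str], col_labels: list[str]
) -> None:
    """TSV export with species/reaction identifier header rows."""
    matrix_frame(M, row_labels, col_labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
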