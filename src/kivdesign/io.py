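"""Model input/output: SBML Level 3 + FBC, and a native plain-text dialect.

The native dialect is a line-oriented format meant for fixtures and diffable
model exchange::

    # comment
    @model toy
    @compartments c e
    @objective BIOMASS
    @metabolites
    glc_e | D-glucose | e
    ...
    @reactions
    EX_glc_e: glc_e --> [-10, 0] ex
    EMP: glc_c + 2 nad_c --> 2 pyr_c + 2 nadh_c [0, 1000]
    PDH: pyr_c + nad_c --> accoa_c + nadh_c [0, 1000] gpr{aceF}

A reaction line is ``id: LHS arrow RHS [lb, ub] gpr{rule} ex`` where the
bounds, rule and exchange flag are optional. ``<=>`` without bounds defaults
to [-1000, 1000]; ``-->`` defaults to [0, 1000]. Either side may be empty
(boundary reactions). Write -> read round-trips a model exactly.

SBML support covers the FBC subset used by genome-scale reconstructions:
species, reactions, fbc flux bounds, the active fbc objective and
fbc:geneProductAssociation trees. Anything else is ignored.
"""

from __future__ import annotations

import re
from pathlib import Path

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, validate_model


class ModelSyntaxError(ValueError):
    """Parse failure in a model file; the message names file line/element."""


# --------------------------------------------------------------------------
# native dialect
# --------------------------------------------------------------------------

_BOUNDS_RE = re.compile(r"\[\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*\]")
_GPR_RE = re.compile(r"gpr\{([^}]*)\}")


def _parse_side(text: str, lineno: int) -> dict[str, float]:
    stoich: dict[str, float] = {}
    text = text.strip()
    if not text:
        return stoich
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            coeff, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError:
                raise ModelSyntaxError(
                    f"line {lineno}: bad stoichiometric coefficient {parts[0]!r}"
                ) from None
            met = parts[1]
        else:
            raise ModelSyntaxError(f"line {lineno}: malformed term {term.strip()!r}")
        stoich[met] = stoich.get(met, 0.0) + coeff
    return stoich


def _parse_reaction_line(line: str, lineno: int) -> Reaction:
    if ":" not in line:
        raise ModelSyntaxError(f"line {lineno}: missing ':' after reaction id")
    rxn_id, rest = line.split(":", 1)
    rxn_id = rxn_id.strip()
    if not rxn_id:
        raise ModelSyntaxError(f"line {lineno}: empty reaction id")

    gene_rule = ""
    m = _GPR_RE.search(rest)
    if m:
        gene_rule = m.group(1).strip()
        rest = rest[: m.start()] + rest[m.end():]

    is_exchange = False
    stripped = rest.rstrip()
    if stripped.endswith(" ex") or stripped == "ex":
        is_exchange = True
        rest = stripped[: -2].rstrip()

    bounds: tuple[float, float] | None = None
    m = _BOUNDS_RE.search(rest)
    if m:
        bounds = (float(m.group(1)), float(m.group(2)))
        rest = rest[: m.start()] + rest[m.end():]

    if "<=>" in rest:
        lhs, rhs = rest.split("<=>", 1)
        default = (-DEFAULT_BOUND, DEFAULT_BOUND)
    elif "-->" in rest:
        lhs, rhs = rest.split("-->", 1)
        default = (0.0, DEFAULT_BOUND)
    else:
        raise ModelSyntaxError(f"line {lineno}: reaction {rxn_id!r} has no arrow")
    lb, ub = bounds if bounds is not None else default
    if lb > ub:
        raise ModelSyntaxError(
            f"line {lineno}: reaction {rxn_id!r} lower bound {lb} exceeds upper bound {ub}"
        )

    stoich = _parse_side(lhs, lineno)
    for met, coeff in stoich.items():
        stoich[met] = -coeff
    for met, coeff in _parse_side(rhs, lineno).items():
        stoich[met] = stoich.get(met, 0.0) + coeff

    return Reaction(
        id=rxn_id,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gene_rule=gene_rule,
        is_exchange=is_exchange,
    )


def read_native_model(path: str | Path) -> MetabolicModel:
    """Read a model in the native dialect; errors carry line numbers."""
    model = MetabolicModel()
    section = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            head, _, arg = line.partition(" ")
            head = head.lower()
            if head == "@model":
                model.name = arg.strip() or "model"
            elif head == "@compartments":
                model.compartment_chain = arg.split()
            elif head == "@objective":
                model.objective_id = arg.strip()
            elif head == "@metabolites":
                section = "metabolites"
            elif head == "@reactions":
                section = "reactions"
            else:
                raise ModelSyntaxError(f"line {lineno}: unknown directive {head!r}")
            continue
        if section == "metabolites":
            parts = [p.strip() for p in line.split("|")]
            if len(parts) != 3:
                raise ModelSyntaxError(
                    f"line {lineno}: metabolite line needs 'id | name | compartment'"
                )
            model.metabolites.append(Metabolite(id=parts[0], name=parts[1], compartment=parts[2]))
        elif section == "reactions":
            model.reactions.append(_parse_reaction_line(line, lineno))
        else:
            raise ModelSyntaxError(f"line {lineno}: content outside any @section")

    findings = validate_model(model)
    if findings:
        raise ModelSyntaxError(f"{path}: invalid model: " + "; ".join(findings))
    return model


def _format_side(stoich: dict[str, float], sign: int) -> str:
    terms = []
    for met, coeff in stoich.items():
        c = sign * coeff
        if c <= 0:
            continue
        terms.append(met if c == 1 else f"{c:g} {met}")
    return " + ".join(terms)


def write_native_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the native dialect; read_native_model(path) reproduces the model."""
    lines = [f"@model {model.name}"]
    if model.compartment_chain:
        lines.append("@compartments " + " ".join(model.compartment_chain))
    if model.objective_id:
        lines.append(f"@objective {model.objective_id}")
    lines.append("@metabolites")
    for m in model.metabolites:
        lines.append(f"{m.id} | {m.name} | {m.compartment}")
    lines.append("@reactions")
    for r in model.reactions:
        lhs = _format_side(r.stoichiometry, -1)
        rhs = _format_side(r.stoichiometry, +1)
        parts = [f"{r.id}: {lhs} --> {rhs}".rstrip(), f"[{r.lower_bound:g}, {r.upper_bound:g}]"]
        if r.gene_rule:
            parts.append(f"gpr{{{r.gene_rule}}}")
        if r.is_exchange:
            parts.append("ex")
        lines.append(" ".join(p for p in parts if p))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# SBML Level 3 + FBC
# --------------------------------------------------------------------------

_COMPARTMENT_PRIORITY = {"c": 0, "cytosol": 0, "p": 1, "periplasm": 1, "e": 2, "extracellular": 2}


def _strip(sbml_id: str, prefix: str) -> str:
    """Undo the COBRA SBML id convention (R_/M_/G_ prefixes)."""
    return sbml_id[len(prefix):] if sbml_id.startswith(prefix) else sbml_id


def _gpa_to_string(assoc) -> str:
    """Render a libsbml FbcAssociation tree as the package's GPR string."""
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return _strip(assoc.getGeneProduct(), "G_")
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_gpa_to_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_gpa_to_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelSyntaxError(f"unsupported gene association node {type(assoc).__name__}")


def read_sbml_fbc(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 model using the FBC package.

    Bounds come from fbc flux-bound parameters, the objective from the
    active fbc objective, GPR rules from fbc:geneProductAssociation.
    Explicit infinities in bounds are replaced by +/-1000, the community
    convention that keeps the linear program bounded.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelSyntaxError(f"{path}: SBML read error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelSyntaxError(f"{path}: file contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelSyntaxError(f"{path}: SBML model lacks the FBC package")

    model = MetabolicModel(name=sbml_model.getId() or sbml_model.getName() or "model")

    comps = [sbml_model.getCompartment(i).getId() for i in range(sbml_model.getNumCompartments())]
    model.compartment_chain = sorted(
        comps, key=lambda c: _COMPARTMENT_PRIORITY.get(c.lower(), len(_COMPARTMENT_PRIORITY))
    )

    seen_mets: set[str] = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are not balanced rows
        sid = _strip(sp.getId(), "M_")
        if sid in seen_mets:
            raise ModelSyntaxError(f"{path}: duplicate species id {sid!r}")
        seen_mets.add(sid)
        model.metabolites.append(
            Metabolite(id=sid, name=sp.getName(), compartment=sp.getCompartment())
        )

    def bound_value(rxn, param_id: str, which: str) -> float:
        if not param_id:
            raise ModelSyntaxError(
                f"{path}: reaction {rxn.getId()!r} has no fbc {which} flux bound"
            )
        param = sbml_model.getParameter(param_id)
        if param is None:
            raise ModelSyntaxError(
                f"{path}: reaction {rxn.getId()!r} references missing parameter {param_id!r}"
            )
        v = param.getValue()
        if v == float("inf"):
            return DEFAULT_BOUND
        if v == float("-inf"):
            return -DEFAULT_BOUND
        return v

    seen_rxns: set[str] = set()
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = _strip(rxn.getId(), "R_")
        if rid in seen_rxns:
            raise ModelSyntaxError(f"{path}: duplicate reaction id {rid!r}")
        seen_rxns.add(rid)
        rfbc = rxn.getPlugin("fbc")
        if rfbc is None:
            raise ModelSyntaxError(f"{path}: reaction {rxn.getId()!r} lacks FBC bounds")
        lb = bound_value(rxn, rfbc.getLowerFluxBound(), "lower")
        ub = bound_value(rxn, rfbc.getUpperFluxBound(), "upper")

        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            mid = _strip(ref.getSpecies(), "M_")
            if mid in seen_mets:
                stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            mid = _strip(ref.getSpecies(), "M_")
            if mid in seen_mets:
                stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()

        gene_rule = ""
        gpa = rfbc.getGeneProductAssociation()
        if gpa is not None:
            gene_rule = _gpa_to_string(gpa.getAssociation())

        model.reactions.append(
            Reaction(
                id=rid,
                name=rxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene_rule,
                is_exchange=len(stoich) <= 1,
            )
        )

    # fbc gene products may use label != id; rules reference the id.
    obj = fbc.getActiveObjective()
    if obj is not None and obj.getNumFluxObjectives() > 0:
        model.objective_id = _strip(obj.getFluxObjective(0).getReaction(), "R_")

    findings = validate_model(model)
    if findings:
        raise ModelSyntaxError(f"{path}: invalid model: " + "; ".join(findings))
    return model


def count_sbml_gene_products(path: str | Path) -> int:
    """Number of fbc geneProduct entries declared in an SBML file."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    fbc = doc.getModel().getPlugin("fbc")
    return fbc.getNumGeneProducts()
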