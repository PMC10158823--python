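"""Core constraint-based model containers.

A :class:`MetabolicModel` is a stoichiometric network: an ordered list of
metabolites (rows of the stoichiometric matrix S), an ordered list of
reactions (columns of S, each with flux bounds and an optional
gene-protein-reaction boolean rule), and a designated objective reaction.
Row/column order is definitional: every matrix index in the package derives
from the metabolite/reaction order stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import gpr

#: Conventional finite stand-in for an unbounded flux (mmol gDCW^-1 h^-1).
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """One network metabolite (a row of S)."""

    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """One network reaction (a column of S).

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed). ``gene_rule`` is a boolean expression over gene
    ids with ``and`` / ``or`` / parentheses; the empty string means the
    reaction is unconditionally available. Exchange reactions are boundary
    pseudo-reactions and are the only ones allowed an empty or singleton
    stoichiometry.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    is_exchange: bool = False
    name: str = ""

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, GPR rules and an objective."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str = ""
    compartment_chain: list[str] = field(default_factory=list)
    name: str = "model"

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        """Union of gene ids appearing in any reaction's GPR rule."""
        out: set[str] = set()
        for r in self.reactions:
            if r.gene_rule:
                out |= gpr.genes_in_rule(r.gene_rule)
        return out

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"unknown reaction id {rxn_id!r}")

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"unknown metabolite id {met_id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            compartment_chain=list(self.compartment_chain),
            name=self.name,
        )

    # -- matrix view -----------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape (n_metabolites, n_reactions), file order."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coeff in r.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub


def validate_model(model: MetabolicModel) -> list[str]:
    """Check every structural invariant; return one finding per violation.

    An empty list means the model is valid. Findings are human-readable
    strings naming the offending elements; no exception is raised.
    """
    findings: list[str] = []
    if not model.reactions:
        findings.append("empty network: model has no reactions")

    met_ids = model.metabolite_ids
    seen: set[str] = set()
    for mid in met_ids:
        if not mid:
            findings.append("metabolite with empty id")
        elif mid in seen:
            findings.append(f"duplicate metabolite id {mid!r}")
        seen.add(mid)
    compartments = set(model.compartment_chain)
    if compartments:
        for m in model.metabolites:
            if m.compartment not in compartments:
                findings.append(
                    f"metabolite {m.id!r} in compartment {m.compartment!r} "
                    "absent from the model's compartment chain"
                )

    met_set = set(met_ids)
    seen_r: set[str] = set()
    for r in model.reactions:
        if not r.id:
            findings.append("reaction with empty id")
        elif r.id in seen_r:
            findings.append(f"duplicate reaction id {r.id!r}")
        seen_r.add(r.id)
        if r.lower_bound > r.upper_bound:
            findings.append(
                f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                f"upper bound {r.upper_bound}"
            )
        if not r.stoichiometry and not r.is_exchange:
            findings.append(
                f"reaction {r.id!r}: empty stoichiometry on a non-exchange reaction"
            )
        for met_id in r.stoichiometry:
            if met_id not in met_set:
                findings.append(
                    f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                )
        if r.gene_rule:
            try:
                gpr.parse_rule(r.gene_rule)
            except gpr.GPRSyntaxError as exc:
                findings.append(f"reaction {r.id!r}: unparsable gene rule ({exc})")

    if model.objective_id and model.objective_id not in seen_r:
        findings.append(f"objective reaction {model.objective_id!r} not in model")
    elif not model.objective_id:
        findings.append("model has no objective reaction")

    return findings
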