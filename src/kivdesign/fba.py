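"""Flux balance analysis and model manipulation.

The steady-state flux problem is the linear program

    maximize  c' v
    s.t.      S v = 0,   lb <= v <= ub

where S is the stoichiometric matrix, v the flux vector
(mmol gDCW^-1 h^-1; h^-1 for the biomass reaction) and c selects the
objective reaction. Solved with the HiGHS solver through
scipy.optimize.linprog. Gene knockouts act through GPR logic: a deletion
closes (bounds [0, 0]) exactly the reactions whose gene rule evaluates
false, preserving the matrix shape across scenarios.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .gpr import evaluate_gene_rule
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

#: Fluxes with magnitude below this are reported as exactly 0.
FLUX_ZERO_TOL = 1e-9


@dataclass
class FluxSolution:
    """One optimal flux distribution (or a solver failure status)."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["reaction_id", "flux"])
            for rid, v in self.fluxes.items():
                writer.writerow([rid, repr(v)])


@dataclass
class KnockoutSet:
    """A gene deletion set and the reactions it disables."""

    genes: set[str]
    disabled_reactions: set[str]


@dataclass
class FvaResult:
    """Per-reaction flux ranges at a stated objective-fraction constraint."""

    ranges: dict[str, tuple[float, float]]
    objective_fraction: float

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["reaction_id", "min_flux", "max_flux"])
            for rid, (lo, hi) in self.ranges.items():
                writer.writerow([rid, repr(lo), repr(hi)])


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _linprog_solve(S, lb, ub, c, sense):
    """Run HiGHS on max/min c'v s.t. Sv=0, box bounds. Returns (status, x, obj)."""
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, None, None
    return status, res.x, sign * res.fun


def solve_fba(
    model: MetabolicModel,
    objective_sense: str = "max",
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    objective: str | None = None,
) -> FluxSolution:
    """Solve the flux balance LP for the model's (or a given) objective.

    ``extra_bounds`` overrides per-reaction bounds for this solve only,
    e.g. to impose a medium. Fluxes below 1e-9 in magnitude are reported
    as 0.
    """
    if objective_sense not in ("max", "min"):
        raise ValueError("objective_sense must be 'max' or 'min'")
    objective_id = objective if objective is not None else model.objective_id
    rxn_ids = model.reaction_ids
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    if objective_id not in idx:
        raise KeyError(f"objective reaction {objective_id!r} not in model")

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            if rid not in idx:
                raise KeyError(f"extra_bounds names unknown reaction {rid!r}")
            lb[idx[rid]], ub[idx[rid]] = lo, hi

    c = np.zeros(len(rxn_ids))
    c[idx[objective_id]] = 1.0
    status, x, obj = _linprog_solve(S, lb, ub, c, objective_sense)
    if status != "optimal":
        return FluxSolution(status=status)
    x = np.where(np.abs(x) < FLUX_ZERO_TOL, 0.0, x)
    if abs(obj) < FLUX_ZERO_TOL:
        obj = 0.0
    return FluxSolution(
        status="optimal",
        objective_value=float(obj),
        fluxes={rid: float(v) for rid, v in zip(rxn_ids, x)},
    )


def apply_gene_knockouts(
    model: MetabolicModel, genes: set[str]
) -> tuple[MetabolicModel, KnockoutSet]:
    """Close the reactions disabled by deleting ``genes``.

    Returns a new model with bounds [0, 0] on exactly the reactions whose
    GPR rule evaluates false under the deletion; the input model is left
    untouched. Unknown gene ids raise, listing them — a misspelled gene
    must never become a silent no-op.
    """
    unknown = set(genes) - model.genes
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    out = model.copy()
    disabled: set[str] = set()
    for r in out.reactions:
        if r.gene_rule and not evaluate_gene_rule(r.gene_rule, genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
            disabled.add(r.id)
    return out, KnockoutSet(genes=set(genes), disabled_reactions=disabled)


def add_secretion_pathway(
    model: MetabolicModel,
    metabolite_id: str,
    compartment_chain: list[str] | None = None,
) -> MetabolicModel:
    """Give the model the ability to secrete an intracellular metabolite.

    Appends one transport reaction per compartment hop along the chain
    (innermost to extracellular) plus a terminal irreversible exchange with
    bounds [0, 1000]; compartment-specific metabolite copies are created as
    needed. For a chain of length k this adds exactly k reactions (k-1
    transports + 1 exchange). Pre-existing reactions are untouched.
    """
    chain = compartment_chain if compartment_chain is not None else model.compartment_chain
    if len(chain) < 2:
        raise ValueError("compartment chain needs at least two compartments")
    if not model.has_metabolite(metabolite_id):
        raise KeyError(f"metabolite {metabolite_id!r} not in model")
    inner = model.metabolite(metabolite_id)
    if inner.compartment != chain[0]:
        raise ValueError(
            f"metabolite {metabolite_id!r} is in compartment {inner.compartment!r}, "
            f"not the chain's innermost {chain[0]!r}"
        )
    base = metabolite_id
    suffix = f"_{chain[0]}"
    if base.endswith(suffix):
        base = base[: -len(suffix)]
    exchange_id = f"EX_{base}_{chain[-1]}"
    if model.has_reaction(exchange_id):
        raise ValueError(f"secretion route exists: reaction {exchange_id!r} already present")

    out = model.copy()
    prev_id = metabolite_id
    for frm, to in zip(chain[:-1], chain[1:]):
        new_id = f"{base}_{to}"
        if not out.has_metabolite(new_id):
            out.metabolites.append(Metabolite(id=new_id, name=inner.name, compartment=to))
        out.reactions.append(
            Reaction(
                id=f"{base.upper()}t{frm}{to}",
                stoichiometry={prev_id: -1.0, new_id: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
        prev_id = new_id
    out.reactions.append(
        Reaction(
            id=exchange_id,
            stoichiometry={prev_id: -1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            is_exchange=True,
        )
    )
    return out


def run_fva(
    model: MetabolicModel,
    objective_fraction: float = 0.0,
    reactions: list[str] | None = None,
    return_vectors: bool = False,
):
    """Flux variability analysis: per-reaction min/max flux.

    The model objective's optimum is computed first; the constraint
    ``c'v >= objective_fraction * optimum`` (for maximisation) is then
    imposed and every listed reaction is minimised and maximised in turn
    (2n LP solves). With ``return_vectors`` the optimal flux vectors are
    also returned (the warmup points for the sampler).
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must be in [0, 1]")
    base = solve_fba(model)
    if base.status != "optimal":
        raise RuntimeError(f"FVA requires a solvable model; FBA status: {base.status}")

    rxn_ids = model.reaction_ids
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    targets = reactions if reactions is not None else rxn_ids
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()

    n = len(rxn_ids)
    if objective_fraction > 0.0:
        # encode c'v >= f*opt as an extra row fixed through bounds on a slack-free
        # formulation: append the inequality as A_ub
        c_obj = np.zeros(n)
        c_obj[idx[model.objective_id]] = 1.0
        A_ub = -c_obj[None, :]
        b_ub = np.array([-objective_fraction * base.objective_value])
    else:
        A_ub = None
        b_ub = None

    ranges: dict[str, tuple[float, float]] = {}
    vectors: list[np.ndarray] = []
    for rid in targets:
        j = idx[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lohi = []
        for sign in (1.0, -1.0):  # min then max
            res = linprog(
                sign * c,
                A_eq=S if S.shape[0] else None,
                b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
                A_ub=A_ub,
                b_ub=b_ub,
                bounds=np.column_stack([lb, ub]),
                method="highs",
            )
            if res.status != 0:
                raise RuntimeError(
                    f"FVA LP for reaction {rid!r} failed with status {res.status} "
                    f"at objective fraction {objective_fraction}"
                )
            lohi.append(float(res.x[j]))
            if return_vectors:
                vectors.append(res.x.copy())
        lo, hi = min(lohi), max(lohi)
        ranges[rid] = (lo, hi)
    result = FvaResult(ranges=ranges, objective_fraction=objective_fraction)
    if return_vectors:
        return result, np.array(vectors)
    return result
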