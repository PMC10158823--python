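"""Independent oracles used by the tests.

These deliberately avoid the package's own solution paths: LP optima come
from cobra (optlang/GLPK), uniform polytope samples from rejection
sampling in the null-space parameterisation. Test-only code.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space

from kivdesign.model import MetabolicModel


def to_cobra(model: MetabolicModel):
    """Translate a MetabolicModel into a cobra model (oracle use only)."""
    import cobra

    cm = cobra.Model(model.name)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
            for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coeff for mid, coeff in r.stoichiometry.items()}
        )
    return cm


def cobra_optimum(model: MetabolicModel, objective: str, sense: str = "max"):
    """(status, objective value) from cobra/GLPK for the given objective."""
    cm = to_cobra(model)
    cm.objective = objective
    cm.objective_direction = "max" if sense == "max" else "min"
    sol = cm.optimize()
    return sol.status, sol.objective_value


def rejection_sample(model: MetabolicModel, n: int, seed: int,
                     batch: int = 200_000, max_batches: int = 500) -> np.ndarray:
    """Uniform samples from {v: Sv=0, lb<=v<=ub} by rejection.

    Coordinates that are constant over the polytope — whether fixed by
    their bounds or implied by the mass balance (FVA range of zero width)
    — are folded into the equality system, so the sampling space has the
    polytope's true dimension; proposals are uniform over the bounding box
    of the polytope's vertices in null-space coordinates.
    """
    from kivdesign.fba import run_fva
    from kivdesign.sampling import generate_warmup

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    fva = run_fva(model, 0.0)
    lo = np.array([fva.ranges[r][0] for r in model.reaction_ids])
    hi = np.array([fva.ranges[r][1] for r in model.reaction_ids])
    fixed = hi - lo < 1e-9
    lb = lb.copy()
    lb[fixed] = (lo[fixed] + hi[fixed]) / 2.0
    rows = [S] if S.shape[0] else []
    rhs = [np.zeros(S.shape[0])] if S.shape[0] else []
    if fixed.any():
        sel = np.eye(len(lb))[fixed]
        rows.append(sel)
        rhs.append(lb[fixed])
    if rows:
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        x0, *_ = np.linalg.lstsq(A, b, rcond=None)
        N = null_space(A)
    else:
        x0 = np.zeros(len(lb))
        N = np.eye(len(lb))
    if N.size == 0:
        return np.tile(x0, (n, 1))

    W = generate_warmup(model)
    Z = (W - x0) @ N
    zlo, zhi = Z.min(axis=0) - 1e-9, Z.max(axis=0) + 1e-9

    rng = np.random.default_rng(seed)
    out = []
    total = 0
    for _ in range(max_batches):
        z = rng.uniform(zlo, zhi, size=(batch, N.shape[1]))
        v = x0 + z @ N.T
        ok = ((v >= lb - 1e-9) & (v <= ub + 1e-9)).all(axis=1)
        out.append(v[ok])
        total += ok.sum()
        if total >= n:
            break
    else:
        raise RuntimeError("rejection sampler failed to reach target count")
    return np.vstack(out)[:n]


def random_network(rng: np.random.Generator, max_reactions: int = 20) -> MetabolicModel:
    """A random small stoichiometric network with a feasible (0 in box) LP."""
    from kivdesign.model import Metabolite, Reaction

    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(1, max(2, n // 2) + 1))
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(m)]
    rxns = []
    for j in range(n):
        coeffs = rng.integers(-2, 3, size=m)
        stoich = {f"m{i}": float(c) for i, c in enumerate(coeffs) if c != 0}
        lo = float(rng.choice([-10.0, -5.0, 0.0]))
        hi = float(rng.choice([0.0, 5.0, 10.0]))
        if lo > hi:
            lo, hi = hi, lo
        rxns.append(Reaction(f"r{j}", stoich, lo, hi, is_exchange=len(stoich) <= 1))
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_id=f"r{int(rng.integers(n))}",
                          compartment_chain=["c"], name="random")
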