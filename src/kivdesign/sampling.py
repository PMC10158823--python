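"""Monte Carlo sampling of the steady-state flux polytope.

The feasible set {v : S v = 0, lb <= v <= ub} is a bounded polytope inside
the null space of S. It is explored with artificially-centered hit-and-run
(ACHR): starting from the centroid of a warmup set (the flux vectors that
attain every reaction's variability minimum and maximum), each step picks a
random warmup point, takes the direction from the running center towards
it, projects that direction onto the null space, and moves a uniformly
random distance along the feasible segment. The running center is updated
incrementally, which biases directions towards long axes of the polytope
and mixes far faster than plain hit-and-run on the elongated, anisotropic
polytopes metabolic models produce. The chain is deterministic given the
seed.

Numerical guards: the chain state is kept in null-space coordinates (an
orthonormal basis of {z : S N z = 0}), so the steady-state residual stays
at machine precision over arbitrarily long chains and no re-projection or
clipping — both of which would bias the walk — is ever applied; step
lengths are bounded by the exact feasible segment, and coordinates with
lb == ub are pinned exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

from .fba import run_fva
from .model import MetabolicModel

#: Default chain length mirrors the published analysis protocol.
DEFAULT_N_POINTS = 35_000

_DIR_TOL = 1e-11  # direction coordinates below this do not limit the step
_SEG_TOL = 1e-12  # a feasible segment shorter than this counts as empty


@dataclass
class SampleSet:
    """Feasible flux vectors from one sampler chain, in model reaction order."""

    points: np.ndarray  # (n_samples, n_reactions)
    reaction_ids: list[str]
    seed: int
    thinning: int
    n_warmup: int

    def column(self, reaction_id: str) -> np.ndarray:
        return self.points[:, self.reaction_ids.index(reaction_id)]

    def save(self, path: str | Path) -> None:
        """Persist as a whitespace matrix plus a JSON sidecar of metadata."""
        path = Path(path)
        np.savetxt(path, self.points)
        sidecar = {
            "reaction_ids": self.reaction_ids,
            "seed": self.seed,
            "thinning": self.thinning,
            "n_warmup": self.n_warmup,
            "points_sha256": hashlib.sha256(self.points.tobytes()).hexdigest(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class FluxSummary:
    """Per-reaction location statistics and a normalized flux histogram."""

    mean: float
    median: float
    p5: float
    p95: float
    bin_edges: np.ndarray
    frequencies: np.ndarray  # sums to 1


def generate_warmup(model: MetabolicModel) -> np.ndarray:
    """Warmup points: the 2n flux vectors attaining each reaction's FVA
    minimum and maximum (objective fraction 0). All rows are feasible."""
    _, vectors = run_fva(model, objective_fraction=0.0, return_vectors=True)
    return vectors


def sample_achr(
    model: MetabolicModel,
    n_points: int,
    seed: int,
    thinning: int = 100,
    warmup: np.ndarray | None = None,
    max_retries: int = 100,
) -> SampleSet:
    """Draw ``n_points`` feasible flux vectors with ACHR.

    One point is recorded every ``thinning`` chain steps. Identical seeds
    give bit-identical output. Raises when the polytope is numerically
    empty (no usable direction after ``max_retries`` tries).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    if warmup is None:
        warmup = generate_warmup(model)

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if np.any(lb > ub):
        raise ValueError("infeasible bounds: lb > ub")

    # Coordinates that are constant over the polytope — fixed by their
    # bounds or implied by the mass balance (e.g. downstream of a knockout)
    # — are pinned and folded into the equality system, so the basis spans
    # exactly the polytope's affine hull. The warmup rows attain every
    # reaction's variability minimum and maximum, so a degenerate column
    # range identifies such coordinates without extra LP solves.
    w_lo, w_hi = warmup.min(axis=0), warmup.max(axis=0)
    fixed = w_hi - w_lo < 1e-9
    fixed_vals = (w_lo[fixed] + w_hi[fixed]) / 2.0

    eq_rows = [S] if S.shape[0] else []
    eq_rhs = [np.zeros(S.shape[0])] if S.shape[0] else []
    if fixed.any():
        eq_rows.append(np.eye(len(lb))[fixed])
        eq_rhs.append(fixed_vals)
    if eq_rows:
        A = np.vstack(eq_rows)
        b = np.concatenate(eq_rhs)
        x0, *_ = np.linalg.lstsq(A, b, rcond=None)
        N = null_space(A)
    else:
        A = np.empty((0, len(lb)))
        x0 = np.zeros(len(lb))
        N = np.eye(len(lb))
    if N.size == 0:
        raise RuntimeError(
            "flux polytope is numerically empty: every reaction is fixed "
            "(the feasible set is at most a single point)"
        )

    rng = np.random.default_rng(seed)
    n_warmup = warmup.shape[0]
    center = warmup.mean(axis=0)

    # The chain lives in null-space coordinates: with the orthonormal basis
    # N, x = x0 + N z satisfies the equalities to machine precision at
    # every step, so no clipping or re-projection is needed (either would
    # nudge the walk off the polytope and bias the stationary law).
    z = N.T @ (center - x0)
    x = x0 + N @ z
    x[fixed] = fixed_vals

    samples = np.empty((n_points, len(lb)))
    kept = 0
    steps = 0
    while kept < n_points:
        moved = False
        for _ in range(max_retries):
            w = warmup[rng.integers(n_warmup)]
            d = N.T @ (w - center)
            norm = np.linalg.norm(d)  # = |N d|: N has orthonormal columns
            if norm < _DIR_TOL:
                continue
            d /= norm
            u = N @ d
            active = np.abs(u) > _DIR_TOL
            lo = (lb[active] - x[active]) / u[active]
            hi = (ub[active] - x[active]) / u[active]
            a_low = np.where(u[active] > 0, lo, hi).max(initial=-np.inf)
            a_high = np.where(u[active] > 0, hi, lo).min(initial=np.inf)
            if not np.isfinite(a_low) or not np.isfinite(a_high):
                continue
            if a_high - a_low < _SEG_TOL:
                continue
            alpha = rng.uniform(a_low, a_high)
            z = z + alpha * d
            x = x0 + N @ z
            x[fixed] = fixed_vals
            moved = True
            break
        if not moved:
            raise RuntimeError(
                "flux polytope is numerically empty: no feasible direction "
                f"after {max_retries} retries"
            )

        steps += 1
        center = center + (x - center) / (n_warmup + steps)
        if steps % thinning == 0:
            samples[kept] = x
            kept += 1

    return SampleSet(
        points=samples,
        reaction_ids=model.reaction_ids,
        seed=seed,
        thinning=thinning,
        n_warmup=n_warmup,
    )


def summarize_reaction_flux(
    samples: SampleSet,
    reaction_ids: list[str],
    n_bins: int = 50,
) -> dict[str, FluxSummary]:
    """Histogram + location statistics per reaction, as plotted in flux
    frequency/variability panels.

    The histogram spans [observed min, observed max] with ``n_bins``
    equal-width bins and frequencies normalized to sum to 1. A constant
    column gets a unit-width support centred on its value (single occupied
    bin).
    """
    if samples.points.shape[0] == 0:
        raise ValueError("empty sample set")
    out: dict[str, FluxSummary] = {}
    for rid in reaction_ids:
        col = samples.column(rid)
        lo, hi = float(col.min()), float(col.max())
        if hi - lo < 1e-15:
            lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(col, bins=n_bins, range=(lo, hi))
        out[rid] = FluxSummary(
            mean=float(col.mean()),
            median=float(np.median(col)),
            p5=float(np.percentile(col, 5)),
            p95=float(np.percentile(col, 95)),
            bin_edges=edges,
            frequencies=counts / counts.sum(),
        )
    return out
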