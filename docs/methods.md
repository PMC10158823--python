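# Methods

This note documents the models, algorithms and numerical choices behind
`kivdesign`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions fell.

## Steady-state flux model

A metabolic network is held as an ordered metabolite list (rows of the
stoichiometric matrix S), an ordered reaction list (columns, each with box
bounds and an optional GPR rule) and one objective reaction. All matrix
indices derive from file order, so model construction is deterministic.
Flux balance analysis solves

    max / min  c'v    s.t.  S·v = 0,  lb ≤ v ≤ ub

with HiGHS (via `scipy.optimize.linprog`). Units are
mmol·gDCW⁻¹·h⁻¹ throughout, h⁻¹ for the biomass pseudo-reaction.
Alternate optima are not disambiguated: `solve_fba` returns whichever
vertex/face point the solver produces, and uniqueness claims are only ever
made through flux variability analysis (FVA), which reports each
reaction's attainable [min, max] at a stated objective fraction using 2n
LP solves.

Numerics: the solver's feasibility tolerance governs constraint
satisfaction (optimal solutions satisfy |S·v|∞ ≤ 1e-6·max(1, ‖v‖∞) and
box bounds to 1e-9 in the tests); reported fluxes and objective values
below 1e-9 in magnitude are snapped to exactly 0; solution agreement is
asserted at 1e-6 relative. Explicit infinities in SBML bounds are replaced
by ±1000, the constraint-based-modeling community's conventional finite
stand-in, which keeps every LP bounded.

Gene knockouts evaluate each reaction's GPR rule (grammar: identifiers,
`and`/`or`, parentheses, case-insensitive; the empty rule means
"unconditionally present") with deleted genes set false, and close the
disabled reactions by setting bounds to [0, 0] rather than deleting
columns. Preserving the matrix shape keeps flux vectors comparable across
scenarios, which the sampling comparisons rely on. Unknown gene ids are a
hard error so that a misspelled deletion can never silently become a
no-op.

Secretion augmentation appends one irreversible transport reaction per
compartment hop plus one terminal exchange (bounds [0, 1000]), creating
compartment-specific metabolite copies as needed; on a three-compartment
model (cytosol → periplasm → extracellular) this adds exactly three
reactions. Pre-existing reactions are never modified.

Media are expressed as bound overrides. No default medium is imposed
beyond the model's own bounds; the toy network carries a single carbon
source capped at 10 mmol·gDCW⁻¹·h⁻¹ uptake, the conventional glucose
default, and pipeline configs can override any exchange bound.

## Flux-polytope sampling

The feasible set {v : S·v = 0, lb ≤ v ≤ ub} is sampled with
artificially-centered hit-and-run (ACHR). Warmup points are the 2n FVA
argmin/argmax flux vectors. Each step draws a random warmup point, takes
the direction from the running center towards it, moves a uniformly
random distance along the feasible segment, and updates the running
center incrementally; directions thereby align with the polytope's long
axes, which mixes far better than isotropic hit-and-run on the elongated
polytopes metabolic networks produce. ACHR's center adaptation makes the
chain formally non-Markovian; on the desk-scale polytopes used here its
sampled moments agree with an independent uniform rejection sampler well
within Monte-Carlo error (checked in the tests), which is the accuracy
the scenario comparisons need.

Two numerical points matter:

* **The chain lives in null-space coordinates.** With an orthonormal
  basis N of the equality system's null space, the state z gives
  x = x0 + N·z, so the steady-state residual stays at machine precision
  over arbitrarily long chains. No per-step clipping or re-projection is
  applied — either would nudge the walk off the polytope and measurably
  bias the stationary distribution (this failure mode was observed and is
  guarded by the oracle-agreement test).
* **Implied equalities are pinned.** A knockout can force reactions to
  zero indirectly (e.g. everything downstream of an unreachable
  metabolite). Coordinates whose FVA range is degenerate (< 1e-9, read
  off the warmup columns at no extra cost) are fixed at their value and
  folded into the equality system, so the basis spans exactly the
  polytope's affine hull and proposals are never wasted on measure-zero
  faces.

Defaults mirror the study protocol: 35,000 points per chain, explicit
integer seeds everywhere (no wall-clock entropy), thinning 100 in the
pipelines. Tests and examples use 300–5,000 points with thinning 5–50,
sizes at which the toy network's sampled means are stable to ~2%.
Identical seeds give bit-identical sample matrices. Per-reaction summaries
report mean, median, 5th/95th percentiles and a histogram over
[observed min, observed max] with 50 equal-width bins by default (a
constant column gets a unit-width support so its single occupied bin is
well defined).

## Scenario evaluation and ranking

The default scenario set is the wild-type baseline plus the three minimal
mutants studied for this chassis: *aceF-mdh*, *ppc-mdh* and
*ldhA-pflB-adhE* — deletions chosen to block pyruvate drain (pyruvate
dehydrogenase; fermentative routes) or to perturb the NAD/NADP balance
(malate dehydrogenase). Canonical gene names map to model locus ids
through an editable table, since genome-scale reconstructions rarely use
gene names directly. Each scenario is evaluated by FBA (biomass and
product objectives) plus an ACHR sample summarised over its target
reactions (ACLS, DHAD, 2-KIV export, and byproduct exchanges where
present).

Ranking orders scenarios by a statistic of the target-reaction sample
(mean by default; median and 95th percentile available — which statistic
best reflects a flux-frequency comparison is genuinely underdetermined,
so it is a parameter rather than a baked-in choice) minus optional
penalty terms such as mean acetate secretion, with deterministic
alphabetical tie-breaking. Scores are compared only as order relations;
no attempt is made to reproduce figure-level frequency values.

## Batch kinetics

Growth is modeled as unrestricted exponential during the exponential
phase, so µ_max (1/h) is the OLS slope of ln X on t. The exponential
window is the contiguous stretch of ≥ `min_points` (default 4, the
smallest window where R² is meaningful) strictly positive biomass
readings maximising R²; ties within 1e-9 prefer longer windows, then
earlier ones, so a perfectly exponential curve returns its full range.
Flat stretches (lag/plateau) score R² = 0 — a constant is not growth —
which is what excludes the stationary phase. Yields are endpoint ratios
over the whole batch (matching how published totals are framed):
Y_X/S = ΔX/ΔS, Y_P/S = ΔP/ΔS, Y_P/X = ΔP/ΔX, with degenerate
denominators raising rather than returning infinities. OD600 converts to
dry cell weight at 0.452 g DCW/L per OD unit, the strain-specific
correlation for *E. coli* W; a generic least-squares calibration utility
covers external-standard curves, while the underlying chemistry is out of
scope.

Duncan's multiple range test uses the ANOVA pooled within-group mean
square as its error estimate (homoscedasticity assumed), harmonic-mean n
for unequal group sizes (a standard, documented approximation), and least
significant ranges q(1−α_p, p, df)·√(MSE/n_h) with the protection level
α_p = 1−(1−α)^(p−1) for a span of p ordered means. Critical values come
from `scipy.stats.studentized_range` quantiles (cached per (p, df, α)),
not from printed tables. The containment rule (no pair inside a
non-significant stretch is declared significant) plus the
maximal-stretch letter sweep guarantee a transitive-consistent letter
display. With k = 2 the procedure reduces exactly to Fisher's LSD, which
the tests verify against the pooled-t closed form, alongside a
1,000-replicate null simulation of the family error rate. Zero pooled
variance is handled explicitly: any nonzero mean difference is then
significant, equal means never are.

## Synthetic data

The toy network (15 reactions, 15 metabolites, cytosol + extracellular)
lumps glycolysis, the TCA cycle and oxidative phosphorylation but keeps
NAD(H), NADP(H) and ATP/ADP explicitly balanced, with a transhydrogenase
supplying KARA's NADPH — so redox supply constrains 2-KIV production in
the toy exactly as it does at genome scale. Per glucose: 2 pyruvate,
2 ATP, 2 NADH. The biomass drain consumes 0.5 pyruvate + 0.5 acetyl-CoA +
1 ATP per unit, so with uptake cap u the biomass optimum is exactly 2u
and the 2-KIV export optimum exactly u (two pyruvates per 2-KIV); both
scale linearly in u, which the tests exploit. Deleting *aceF* makes
acetyl-CoA unreachable: growth collapses to zero while the product branch
is untouched. Gene rules (PDH: *aceF*, TCA lump: *gltA*, ACLS: *alsS*,
KARA: *ilvC*, DHAD: *ilvD*) make the network a faithful desk-scale stand-in
for knockout studies. A byte-stable native-dialect copy ships with the
package and is kept in sync with the builder by a test.

The batch simulator generates X(t) = X0·e^(µt) until substrate
exhaustion, then constant; S(t) = max(0, S0 − (X−X0)/Y_X/S);
P(t) = Y_P/S·(S0 − S(t)). Defaults (X0 = 0.05 g/L, µ = 0.5 /h,
Y_X/S = 0.4, Y_P/S = 0.2, S0 = 10 g/L, hourly sampling over 24 h,
duplicate flasks in the examples) are typical of aerobic *E. coli*
shake-flask batches on ~1% sugar. Measurement noise is multiplicative
lognormal (sd on the log scale; concentrations stay positive), applied
independently per observation. What the simulator deliberately omits —
lag phases, diauxie on sugar mixtures, maintenance-driven yield drift,
autocorrelated instrument error — bounds what passing tests show about
real data: parameter recovery is demonstrated for clean single-substrate
exponential batches, not for curves needing lag/diauxie models. The
published-endpoint fixture carries the producer strain's three 24-h batch
rows (substrate uptake, 2-KIV titer, printed biomass yield) for endpoint
yield arithmetic; its biomass increments are reconstructed as
Y_X/S·ΔS because raw biomass endpoints are not published, and the
published Y_P/X values are not exactly recoverable from the rounded
printed columns — Y_P/X from this fixture is therefore approximate by
construction.

## Known limitations

* FBA and FVA are dense-matrix formulations; adequate up to
  genome-scale models (~2,500 reactions) but not tuned for much larger
  reconstructions.
* ACHR is not exactly uniform (no rounding transformation is applied);
  summaries are used comparatively, across scenarios sampled identically.
* The SBML reader covers the FBC subset (species, reactions, fbc bounds,
  fbc objective, geneProductAssociation) and rejects models needing other
  SBML packages; kinetic/ODE semantics are out of scope.
* Duncan's test assumes homoscedastic, approximately normal replicates;
  with two replicates per flask (the usual shake-flask duplicate) its
  power is minimal and letters should be read accordingly.
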