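"""Knockout scenario definition, evaluation and ranking.

The study conditions compare a wild-type baseline against three minimal
knockout strains — aceF-mdh, ppc-mdh and ldhA-pflB-adhE — chosen to block
pyruvate drain (pyruvate dehydrogenase, fermentative routes) or perturb
the NAD/NADP balance (malate dehydrogenase), and judge them by the flux
they leave available to the 2-ketoisovalerate branch (acetolactate
synthase -> dihydroxy-acid dehydratase -> 2-KIV export), optionally
penalising acetate secretion.

Gene names in the scenario table are canonical *E. coli* names; models
often use locus tags instead, so every scenario builder accepts an
editable gene map (name -> model gene id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba import apply_gene_knockouts, solve_fba
from .model import MetabolicModel
from .sampling import FluxSummary, sample_achr, summarize_reaction_flux

#: The published scenario set: wild type plus three minimal mutants.
DEFAULT_SCENARIO_DELETIONS: dict[str, tuple[str, ...]] = {
    "WT": (),
    "aceF-mdh": ("aceF", "mdh"),
    "ppc-mdh": ("ppc", "mdh"),
    "ldhA-pflB-adhE": ("ldhA", "pflB", "adhE"),
}

#: Central-metabolism reactions tracked per scenario (flux frequency and
#: variability panels); filtered to those present in the model at build time.
DEFAULT_TARGET_REACTIONS: tuple[str, ...] = (
    "ACLS",
    "DHAD",
    "EX_kiv_e",
    "EX_val_e",
    "ME1",
    "ME2",
    "EX_ac_e",
)


@dataclass
class DesignScenario:
    """One in-silico strain: gene deletions plus tracked target reactions."""

    name: str
    deletions: set[str] = field(default_factory=set)
    target_reactions: list[str] = field(default_factory=list)
    augmentations: list[str] = field(default_factory=list)  # e.g. "secrete:kiv_c"


@dataclass
class ScenarioResult:
    """Evaluation of one scenario on one model."""

    scenario: DesignScenario
    biomass_optimum: float
    product_optimum: float
    disabled_reactions: set[str]
    summaries: dict[str, FluxSummary]


@dataclass
class SamplingConfig:
    """Sampler settings shared across scenarios of one comparison."""

    n_points: int = 5000
    seed: int = 0
    thinning: int = 10
    product_reaction: str = "EX_kiv_e"


def build_default_scenarios(
    model: MetabolicModel,
    gene_map: dict[str, str] | None = None,
    target_reactions: list[str] | None = None,
    scenario_names: list[str] | None = None,
) -> list[DesignScenario]:
    """The wild-type baseline plus the three published knockout strains.

    ``gene_map`` translates canonical gene names to model gene ids
    (identity by default). A scenario naming a gene the model lacks (after
    mapping) raises, unless the scenario set is narrowed via
    ``scenario_names``.
    """
    gene_map = gene_map or {}
    names = scenario_names if scenario_names is not None else list(DEFAULT_SCENARIO_DELETIONS)
    if not names:
        raise ValueError("no scenarios requested")
    if target_reactions is None:
        target_reactions = [r for r in DEFAULT_TARGET_REACTIONS if model.has_reaction(r)]
    model_genes = model.genes
    scenarios = []
    for name in names:
        if name not in DEFAULT_SCENARIO_DELETIONS:
            raise KeyError(f"unknown scenario name {name!r}")
        mapped = set()
        for gene in DEFAULT_SCENARIO_DELETIONS[name]:
            gid = gene_map.get(gene, gene)
            if gid not in model_genes:
                raise KeyError(
                    f"scenario {name!r}: gene {gene!r} (model id {gid!r}) not in model"
                )
            mapped.add(gid)
        scenarios.append(
            DesignScenario(name=name, deletions=mapped, target_reactions=list(target_reactions))
        )
    return scenarios


def evaluate_scenario(
    model: MetabolicModel,
    scenario: DesignScenario,
    config: SamplingConfig | None = None,
) -> ScenarioResult:
    """Apply a scenario's knockouts and measure it by FBA and sampling.

    Reports the biomass and product FBA optima, the reactions the deletion
    disabled, and a flux summary per target reaction from an ACHR sample.
    A scenario that abolishes growth is reported with optimum 0, not an
    error.
    """
    config = config or SamplingConfig()
    mutant, ko = apply_gene_knockouts(model, scenario.deletions)
    biomass = solve_fba(mutant)
    product = solve_fba(mutant, objective=config.product_reaction)
    samples = sample_achr(
        mutant, n_points=config.n_points, seed=config.seed, thinning=config.thinning
    )
    targets = [r for r in scenario.target_reactions if mutant.has_reaction(r)]
    summaries = summarize_reaction_flux(samples, targets)
    return ScenarioResult(
        scenario=scenario,
        biomass_optimum=biomass.objective_value if biomass.status == "optimal" else 0.0,
        product_optimum=product.objective_value if product.status == "optimal" else 0.0,
        disabled_reactions=ko.disabled_reactions,
        summaries=summaries,
    )


def _statistic(summary: FluxSummary, statistic: str) -> float:
    try:
        return {"mean": summary.mean, "median": summary.median, "p95": summary.p95}[statistic]
    except KeyError:
        raise ValueError(f"unknown statistic {statistic!r}") from None


def rank_scenarios(
    results: list[ScenarioResult],
    target_reaction: str = "EX_kiv_e",
    statistic: str = "mean",
    penalties: dict[str, float] | None = None,
) -> list[tuple[str, float]]:
    """Order scenarios by a target-flux statistic minus byproduct penalties.

    Score = statistic(target) - sum_r penalties[r] * statistic(r).
    Descending score; ties break alphabetically by scenario name. The
    default (no penalties) reproduces a pure target-flux comparison; an
    acetate penalty expresses a preference for low acetate secretion.
    """
    penalties = penalties or {}
    scored = []
    for res in results:
        if target_reaction not in res.summaries:
            raise KeyError(
                f"scenario {res.scenario.name!r} has no summary for {target_reaction!r}"
            )
        score = _statistic(res.summaries[target_reaction], statistic)
        for rid, weight in penalties.items():
            if rid not in res.summaries:
                raise KeyError(
                    f"scenario {res.scenario.name!r} has no summary for penalty term {rid!r}"
                )
            score -= weight * _statistic(res.summaries[rid], statistic)
        scored.append((res.scenario.name, score))
    return sorted(scored, key=lambda item: (-item[1], item[0]))
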