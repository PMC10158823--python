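"""Flux balance analysis, knockouts, secretion augmentation and FVA."""

import numpy as np
import pytest

from kivdesign import (
    add_secretion_pathway,
    apply_gene_knockouts,
    make_toy_network,
    run_fva,
    solve_fba,
)
from kivdesign.synthetic import ToyNetworkSpec

from oracles import cobra_optimum, random_network


def assert_steady_state(model, solution, rtol=1e-6):
    S = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in model.reaction_ids])
    scale = max(1.0, np.abs(v).max())
    assert np.abs(S @ v).max() <= rtol * scale
    lb, ub = model.bounds_arrays()
    assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


class TestSolveFba:
    def test_toy_biomass_optimum(self, toy_model):
        sol = solve_fba(toy_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(20.0, rel=1e-6)
        assert_steady_state(toy_model, sol)

    def test_toy_kiv_optimum(self, toy_model):
        sol = solve_fba(toy_model, objective="EX_kiv_e")
        assert sol.objective_value == pytest.approx(10.0, rel=1e-6)
        assert_steady_state(toy_model, sol)

    def test_closed_system_has_zero_objective(self, toy_model):
        closed = {r.id: (0.0, 0.0) for r in toy_model.reactions if r.is_exchange}
        sol = solve_fba(toy_model, extra_bounds=closed)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_extra_bounds_do_not_mutate_model(self, toy_model):
        lb_before = toy_model.reaction("EX_glc_e").lower_bound
        solve_fba(toy_model, extra_bounds={"EX_glc_e": (0.0, 0.0)})
        assert toy_model.reaction("EX_glc_e").lower_bound == lb_before

    def test_infeasible_bounds_reported(self, toy_model):
        # force net glucose production from nothing
        sol = solve_fba(toy_model, extra_bounds={"EX_glc_e": (5.0, 10.0),
                                                 "GLCt": (0.0, 0.0)})
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_unbounded_objective_reported(self, toy_model):
        m = toy_model.copy()
        m.reaction("EX_glc_e").lower_bound = -np.inf
        for rid in ("GLCt", "EMP", "NOX", "ATPM", "PDH", "BIOMASS", "EX_co2_e"):
            m.reaction(rid).upper_bound = np.inf
        sol = solve_fba(m)  # growth scales with uptake, now uncapped
        assert sol.status == "unbounded"

    def test_unknown_extra_bound_rejected(self, toy_model):
        with pytest.raises(KeyError, match="NOPE"):
            solve_fba(toy_model, extra_bounds={"NOPE": (0, 0)})

    def test_agrees_with_independent_lp_oracle_on_random_networks(self, rng):
        """HiGHS-backed solutions match cobra/GLPK optima on random small
        networks (feasible by construction: 0 is always in the box)."""
        pytest.importorskip("cobra")
        for _ in range(25):
            model = random_network(rng)
            mine = solve_fba(model)
            status, value = cobra_optimum(model, model.objective_id)
            assert mine.status == "optimal" and status == "optimal"
            assert mine.objective_value == pytest.approx(value, rel=1e-6, abs=1e-6)
            assert_steady_state(model, mine)


class TestKnockouts:
    def test_aceF_deletion_closes_pdh_and_kills_growth(self, toy_model):
        mutant, ko = apply_gene_knockouts(toy_model, {"aceF"})
        assert ko.disabled_reactions == {"PDH"}
        pdh = mutant.reaction("PDH")
        assert (pdh.lower_bound, pdh.upper_bound) == (0.0, 0.0)
        sol = solve_fba(mutant)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_original_model_untouched(self, toy_model):
        before = toy_model.reaction("PDH").upper_bound
        apply_gene_knockouts(toy_model, {"aceF"})
        assert toy_model.reaction("PDH").upper_bound == before

    def test_empty_deletion_is_identity(self, toy_model):
        mutant, ko = apply_gene_knockouts(toy_model, set())
        assert ko.disabled_reactions == set()
        assert mutant.bounds_arrays()[1].tolist() == toy_model.bounds_arrays()[1].tolist()

    def test_unknown_gene_raises_listing_it(self, toy_model):
        with pytest.raises(KeyError, match="not_a_gene"):
            apply_gene_knockouts(toy_model, {"aceF", "not_a_gene"})

    def test_knockouts_are_monotone_in_objective(self, toy_model):
        """Enlarging the deletion set never increases the maximisation
        optimum (the feasible region only shrinks)."""
        genes = sorted(toy_model.genes)
        prev = solve_fba(toy_model, objective="EX_kiv_e").objective_value
        deleted: set[str] = set()
        for g in genes:
            deleted.add(g)
            mutant, _ = apply_gene_knockouts(toy_model, deleted)
            sol = solve_fba(mutant, objective="EX_kiv_e")
            value = sol.objective_value if sol.status == "optimal" else 0.0
            assert value <= prev + 1e-9
            prev = value


class TestSecretionPathway:
    def test_two_compartment_chain_adds_two_reactions(self, toy_model):
        # a cytosolic metabolite with no export: acetolactate
        n = len(toy_model.reactions)
        out = add_secretion_pathway(toy_model, "alac_c")
        assert len(out.reactions) == n + 2  # one transport + one exchange
        assert out.has_reaction("ALACtce")
        assert out.has_reaction("EX_alac_e")
        ex = out.reaction("EX_alac_e")
        assert (ex.lower_bound, ex.upper_bound) == (0.0, 1000.0)

    def test_three_compartment_chain_adds_three_reactions(self, toy_model):
        n = len(toy_model.reactions)
        out = add_secretion_pathway(toy_model, "alac_c", ["c", "p", "e"])
        assert len(out.reactions) == n + 3
        assert out.has_reaction("ALACtcp") and out.has_reaction("ALACtpe")
        assert out.has_metabolite("alac_p") and out.has_metabolite("alac_e")

    def test_preexisting_reactions_untouched(self, toy_model):
        out = add_secretion_pathway(toy_model, "alac_c")
        for r_old, r_new in zip(toy_model.reactions, out.reactions):
            assert r_old.id == r_new.id
            assert r_old.stoichiometry == r_new.stoichiometry
            assert (r_old.lower_bound, r_old.upper_bound) == (
                r_new.lower_bound, r_new.upper_bound)

    def test_existing_route_rejected(self, toy_model):
        with pytest.raises(ValueError, match="secretion route exists"):
            add_secretion_pathway(toy_model, "kiv_c")

    def test_missing_metabolite_rejected(self, toy_model):
        with pytest.raises(KeyError, match="nope_c"):
            add_secretion_pathway(toy_model, "nope_c")

    def test_new_route_is_functional(self, toy_model):
        out = add_secretion_pathway(toy_model, "alac_c")
        sol = solve_fba(out, objective="EX_alac_e")
        # one acetolactate per two pyruvates, ten pyruvate-pairs available
        assert sol.objective_value == pytest.approx(10.0, rel=1e-6)


class TestFva:
    def test_kiv_range_at_fraction_zero(self, toy_model):
        res = run_fva(toy_model, 0.0, reactions=["EX_kiv_e"])
        lo, hi = res.ranges["EX_kiv_e"]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(10.0, rel=1e-6)

    def test_fixed_reaction_has_degenerate_range(self, toy_model):
        m = toy_model.copy()
        r = m.reaction("ATPM")
        r.lower_bound = r.upper_bound = 3.0
        res = run_fva(m, 0.0, reactions=["ATPM"])
        assert res.ranges["ATPM"] == pytest.approx((3.0, 3.0))

    def test_biomass_range_collapses_at_full_fraction(self, toy_model):
        res = run_fva(toy_model, 1.0, reactions=["BIOMASS"])
        lo, hi = res.ranges["BIOMASS"]
        assert lo == pytest.approx(20.0, rel=1e-6)
        assert hi == pytest.approx(20.0, rel=1e-6)

    def test_ranges_within_bounds_and_ordered(self, toy_model):
        res = run_fva(toy_model, 0.5)
        lb, ub = toy_model.bounds_arrays()
        for rid, (lo, hi) in res.ranges.items():
            j = toy_model.reaction_ids.index(rid)
            assert lb[j] - 1e-7 <= lo <= hi <= ub[j] + 1e-7

    def test_matches_oracle_ranges(self, toy_model):
        """Cross-check FVA extrema against cobra's FVA on the toy model."""
        pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        from oracles import to_cobra

        cm = to_cobra(toy_model)
        cm.objective = "BIOMASS"
        df = flux_variability_analysis(cm, fraction_of_optimum=0.9)
        res = run_fva(toy_model, 0.9)
        for rid, (lo, hi) in res.ranges.items():
            assert lo == pytest.approx(df.loc[rid, "minimum"], abs=1e-5)
            assert hi == pytest.approx(df.loc[rid, "maximum"], abs=1e-5)

    def test_scaling_with_uptake_cap(self):
        for cap in (2.0, 10.0, 25.0):
            m = make_toy_network(ToyNetworkSpec(glucose_uptake_cap=cap))
            assert solve_fba(m).objective_value == pytest.approx(2 * cap, rel=1e-6)
            assert solve_fba(m, objective="EX_kiv_e").objective_value == pytest.approx(
                cap, rel=1e-6)
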