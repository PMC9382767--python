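"""FBA/FVA, merging, and subnetworks, cross-checked against independent LPs."""

import math

import numpy as np
import pytest
from scipy.optimize import linprog

import panefm as pf
from panefm.network import (
    GROWTH_EPS,
    Environment,
    MetabolicNetwork,
    Reaction,
    fba,
    fva_active_reactions,
    is_functional,
    merge_pan_reactome,
    subnetwork,
)


def scipy_fba(network, env, disabled=frozenset(), objective=None, maximize=True):
    """Independent FBA oracle built directly on scipy's HiGHS interior LP."""
    rids = list(network.reactions)
    mets = list(network.metabolites)
    midx = {m: i for i, m in enumerate(mets)}
    A = np.zeros((len(mets), len(rids)))
    bounds = []
    for j, rid in enumerate(rids):
        rxn = network.reactions[rid]
        for m, c in rxn.stoichiometry.items():
            A[midx[m], j] = c
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange:
            lb = -min(env.bound(rxn.exchange_metabolite), 1000.0)
        if rid in disabled:
            lb = ub = 0.0
        bounds.append((max(lb, -1000.0), min(ub, 1000.0)))
    c = np.zeros(len(rids))
    target = objective or network.biomass_reaction_id
    c[rids.index(target)] = -1.0 if maximize else 1.0
    res = linprog(c, A_eq=A, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return -res.fun if maximize else res.fun


class TestFBA:
    def test_toy_grows_in_rich_environment(self, toy, rich):
        sol = fba(toy, rich)
        assert sol.status == "optimal"
        assert sol.biomass_flux > GROWTH_EPS

    def test_no_uptake_means_no_growth(self, toy):
        empty = Environment({})
        assert fba(toy, empty).biomass_flux == pytest.approx(0.0, abs=1e-9)

    def test_linear_chain_flux_forced_by_uptake_bound(self, chain, chain_env):
        sol = fba(chain, chain_env)
        assert sol.biomass_flux == pytest.approx(5.0)
        # the imported compound shows a negative exchange flux
        assert sol.exchange_fluxes["A_e"] == pytest.approx(-5.0)
        assert sol.imported_metabolites == {"A_e"}

    def test_agrees_with_independent_highs_solver(self, toy, rich, growth_envs):
        for env in [rich] + growth_envs[:10]:
            expected = scipy_fba(toy, env) or 0.0
            assert fba(toy, env).biomass_flux == pytest.approx(expected, abs=1e-6)

    def test_agrees_with_cobra(self, toy, rich):
        from panefm.io import to_cobra

        model = to_cobra(toy)
        for rxn in model.exchanges:
            rxn.lower_bound = -1000.0
        assert model.optimize().objective_value == pytest.approx(
            fba(toy, rich).biomass_flux, rel=1e-6
        )

    def test_unbounded_objective_raises(self):
        net = MetabolicNetwork(
            [
                Reaction("make", {"A_i": 1}, 0, math.inf),
                Reaction("biomass", {"A_i": -1}, 0, math.inf),
            ],
            "biomass",
        )
        with pytest.raises(RuntimeError, match="bound"):
            net.evaluator().biomass_flux(Environment({}))

    def test_subnetwork_monotonicity(self, toy, rich, growth_envs, rng):
        """Restricting the reaction set can never increase biomass flux."""
        full = fba(toy, rich).biomass_flux
        ev = toy.evaluator()
        deletable = list(toy.deletable_reaction_ids)
        for _ in range(20):
            drop = frozenset(
                rng.choice(deletable, size=rng.integers(1, 6), replace=False)
            )
            assert ev.biomass_flux(rich, drop) <= full + 1e-9

    def test_doubling_uptake_preserves_feasibility(self, toy, growth_envs):
        ev = toy.evaluator()
        for env in growth_envs[:20]:
            doubled = Environment(
                {m: min(2 * b, 1000.0) for m, b in env.uptake_bounds.items()}
            )
            assert ev.biomass_flux(doubled) >= ev.biomass_flux(env) - 1e-9


class TestIsFunctional:
    def test_cutoff_zero_accepts_any_growth(self, toy, rich):
        assert is_functional(toy, rich, 0.0)

    def test_cutoff_is_a_strict_inequality(self, toy, rich):
        flux = fba(toy, rich).biomass_flux
        assert not is_functional(toy, rich, flux)

    def test_removing_a_universal_reaction_breaks_function(self, toy, rich):
        keep = set(toy.reactions) - {"R13"}
        assert not is_functional(subnetwork(toy, keep), rich, 0.0)


class TestFVA:
    def test_zero_bound_reaction_is_inactive(self):
        net = MetabolicNetwork(
            [
                Reaction("EX_A_e", {"A_e": -1}, -10, 1000, is_exchange=True),
                Reaction("T_A", {"A_e": -1, "A_i": 1}),
                Reaction("dead", {"A_i": -1, "B_i": 1}, 0, 0),
                Reaction("biomass", {"A_i": -1}),
            ],
            "biomass",
        )
        active = fva_active_reactions(net)
        assert "dead" not in active
        assert "biomass" in active

    def test_matches_per_reaction_lp_oracle(self, toy, rich):
        """Active set equals independent per-reaction max/min LPs."""
        active = fva_active_reactions(toy, rich)
        for rid in toy.reactions:
            lo = scipy_fba(toy, rich, objective=rid, maximize=False)
            hi = scipy_fba(toy, rich, objective=rid, maximize=True)
            oracle_active = (hi - lo > 1e-9) or abs(hi) > 1e-9 or abs(lo) > 1e-9
            assert (rid in active) == oracle_active, rid

    def test_infeasible_environment_raises(self, toy):
        with pytest.raises(ValueError, match="not functional"):
            fva_active_reactions(toy, Environment({}))


class TestMerge:
    def test_single_network_is_identity(self, toy):
        assert merge_pan_reactome([toy]) == toy

    def test_strain_reactomes_merge_to_pan(self, toy, strains):
        assert merge_pan_reactome(strains) == toy

    def test_idempotent_and_order_independent(self, strains):
        a = merge_pan_reactome(strains)
        b = merge_pan_reactome(strains[::-1])
        c = merge_pan_reactome([a, a])
        assert a == b == c

    def test_disjoint_reaction_sets_add_up(self):
        def net(prefix, n):
            rxns = [
                Reaction(f"{prefix}{k}", {f"{prefix}m{k}": -1, f"{prefix}m{k+1}": 1})
                for k in range(n - 1)
            ]
            rxns.append(Reaction(f"{prefix}{n-1}", {f"{prefix}m{n-1}": -1, "P_i": 1}))
            rxns.append(
                Reaction(f"EX_{prefix}m0", {f"{prefix}m0": -1}, -10, 10, is_exchange=True)
            )
            rxns.append(Reaction("biomass", {"P_i": -1}))
            return MetabolicNetwork(rxns, "biomass")

        a, b = net("a", 5), net("b", 7)
        merged = merge_pan_reactome([a, b])
        # 5 + 7 pathway reactions, plus one exchange each and the shared biomass
        assert len(merged) == len(a) + len(b) - 1 == 15

    def test_conflicting_stoichiometry_rejected(self):
        a = MetabolicNetwork(
            [
                Reaction("EX_A_e", {"A_e": -1}, -10, 10, is_exchange=True),
                Reaction("R", {"A_e": -1, "B_i": 1}),
                Reaction("biomass", {"B_i": -1}),
            ],
            "biomass",
        )
        b = MetabolicNetwork(
            [
                Reaction("EX_A_e", {"A_e": -1}, -10, 10, is_exchange=True),
                Reaction("R", {"A_e": -1, "B_i": 2}),
                Reaction("biomass", {"B_i": -1}),
            ],
            "biomass",
        )
        with pytest.raises(ValueError, match="conflicting stoichiometry"):
            merge_pan_reactome([a, b])

    def test_differing_biomass_rejected(self):
        a = MetabolicNetwork([Reaction("bm1", {"X_i": -1})], "bm1")
        b = MetabolicNetwork([Reaction("bm2", {"X_i": -1})], "bm2")
        with pytest.raises(ValueError, match="biomass"):
            merge_pan_reactome([a, b])


class TestSubnetwork:
    def test_keep_all_is_identity(self, toy):
        assert subnetwork(toy, set(toy.reactions)) == toy

    def test_biomass_must_be_kept(self, toy):
        with pytest.raises(ValueError, match="biomass"):
            subnetwork(toy, set(toy.reactions) - {"biomass"})

    def test_panefm_subnetwork_is_functional_and_minimal(
        self, toy, rich, toy_minimal_sets
    ):
        efm = sorted(toy_minimal_sets, key=sorted)[0]
        sub = subnetwork(toy, efm)
        assert is_functional(sub, rich, 0.0)
        for rid in sub.deletable_reaction_ids:
            smaller = subnetwork(sub, set(sub.reactions) - {rid})
            assert not is_functional(smaller, rich, 0.0), rid

    def test_dropping_an_essential_reaction_breaks_growth(self, toy, rich):
        sub = subnetwork(toy, set(toy.reactions) - {"R5"})
        assert fba(sub, rich).biomass_flux == pytest.approx(0.0, abs=1e-9)
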