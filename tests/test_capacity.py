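"""FVA, production/redox capacity, fold-changes, essentiality, coupling."""

import numpy as np
import pytest

from contextflux import (
    CapacityTable,
    ContextModel,
    FluxMeasurementSet,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    ReactionCategories,
    coupling_scan,
    essentiality_scan,
    fit_fluxes,
    make_toy_network,
    pathway_fold_change,
    production_capacity,
    redox_capacity,
    run_fva,
)

from conftest import knockout_bruteforce, lp_optimize, make_chain_network


class TestFVA:
    def test_single_path_ranges(self, chain_network):
        free = ContextModel.from_network(chain_network)
        ranges = {r.reaction_id: r for r in run_fva(free)}
        assert ranges["EX_A"].min_flux == pytest.approx(-10.0)
        assert ranges["EX_A"].max_flux == pytest.approx(0.0)
        for rid in ("AB", "EX_B"):
            assert ranges[rid].min_flux == pytest.approx(0.0)
            assert ranges[rid].max_flux == pytest.approx(10.0)

    def test_lock_propagates_through_chain(self, chain_network):
        ctx = fit_fluxes(
            chain_network, ReactionCategories({}), 0,
            FluxMeasurementSet({"EX_A": -5.0}),
        )
        ranges = {r.reaction_id: r for r in run_fva(ctx)}
        assert ranges["AB"].min_flux == pytest.approx(5.0, abs=1e-5)
        assert ranges["AB"].max_flux == pytest.approx(5.0, abs=1e-5)

    def test_endpoints_attained_and_samples_inside(self):
        scenario = make_toy_network(seed=13, n_decoy_chains=1)
        net = scenario.network
        free = ContextModel.from_network(net)
        ranges = {r.reaction_id: r for r in run_fva(free)}
        rng = np.random.default_rng(0)
        rxn_ids = [r.id for r in net.reactions]
        # endpoints certified by an explicit feasible vector (direct LP)
        for rid in rng.choice(rxn_ids, size=6, replace=False):
            for sense, endpoint in (
                ("min", ranges[rid].min_flux), ("max", ranges[rid].max_flux)
            ):
                value, flux = lp_optimize(net, {rid: 1.0}, sense)
                assert value == pytest.approx(endpoint, abs=1e-6)
                from contextflux import FluxVector

                assert net.check_flux(FluxVector(flux), tol=1e-5)
        # random feasible vertices all fall inside every range
        for _ in range(50):
            objective = {
                rid: float(rng.normal()) for rid in rng.choice(rxn_ids, 4)
            }
            _, flux = lp_optimize(net, objective, "max")
            for rid, v in flux.items():
                assert ranges[rid].min_flux - 1e-6 <= v <= ranges[rid].max_flux + 1e-6

    def test_order_independence(self, chain_network):
        free = ContextModel.from_network(chain_network)
        fwd = {r.reaction_id: (r.min_flux, r.max_flux) for r in run_fva(free)}
        rev_ids = [r.id for r in chain_network.reactions][::-1]
        rev = {r.reaction_id: (r.min_flux, r.max_flux)
               for r in run_fva(free, rev_ids)}
        assert fwd == rev


def _two_compartment_toy() -> MetabolicNetwork:
    """gsh producible at <=3 in [c] and <=4 in [m] simultaneously."""
    mets = [
        Metabolite(id="a[e]"), Metabolite(id="gsh[c]"), Metabolite(id="gsh[m]"),
    ]
    rxns = [
        Reaction("EX_a", {"a[e]": -1.0}, -100.0, 0.0, is_exchange=True),
        Reaction("P_c", {"a[e]": -1.0, "gsh[c]": 1.0}, 0.0, 3.0),
        Reaction("P_m", {"a[e]": -1.0, "gsh[m]": 1.0}, 0.0, 4.0),
    ]
    return MetabolicNetwork(mets, rxns)


class TestProductionCapacity:
    def test_single_compartment_single_producer(self, chain_network):
        free = ContextModel.from_network(chain_network)
        # B's sole producer AB is capped by EX_A uptake at 10
        assert production_capacity(free, "B") == pytest.approx(10.0)
        # cross-check: equals the producer's FVA max (single-producer case)
        (ab,) = run_fva(free, ["AB"])
        assert production_capacity(free, "B") == pytest.approx(ab.max_flux)

    def test_two_compartments_sum_jointly(self):
        free = ContextModel.from_network(_two_compartment_toy())
        assert production_capacity(free, "gsh") == pytest.approx(7.0)
        cap, infeasible, by_comp = production_capacity(
            free, "gsh", return_per_compartment=True
        )
        assert not infeasible
        assert by_comp["c"] + by_comp["m"] == pytest.approx(7.0)

    def test_joint_sum_matches_direct_lp_oracle(self):
        net = _two_compartment_toy()
        drained = net.with_reactions(
            added=[
                Reaction("D_c", {"gsh[c]": -1.0}, 0.0, 1000.0),
                Reaction("D_m", {"gsh[m]": -1.0}, 0.0, 1000.0),
            ]
        )
        value, _ = lp_optimize(drained, {"D_c": 1.0, "D_m": 1.0}, "max")
        free = ContextModel.from_network(net)
        assert production_capacity(free, "gsh") == pytest.approx(value)

    def test_absent_species_rejected(self, chain_network):
        with pytest.raises(ValueError, match="nosuch"):
            production_capacity(ContextModel.from_network(chain_network), "nosuch")

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_under_added_constraints(self, seed):
        scenario = make_toy_network(seed=seed, fh_knockout=seed % 2 == 0)
        free = ContextModel.from_network(scenario.network)
        base = production_capacity(free, "gsh")
        # tightening any bound can only lower the capacity
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        net = scenario.network.copy()
        j = int(rng.integers(0, net.n_reactions))
        r = net.reactions[j]
        net.reactions[j] = replace(
            r, upper_bound=r.lower_bound + 0.5 * (r.upper_bound - r.lower_bound)
        )
        tightened = production_capacity(ContextModel.from_network(net), "gsh")
        assert tightened <= base + 1e-6
        # measurement locks can only lower it too
        from contextflux import simulate_measurements

        meas = simulate_measurements(scenario, sigma=0.0, seed=0)
        ctx = fit_fluxes(scenario.network, ReactionCategories({}), 0, meas)
        assert production_capacity(ctx, "gsh") <= base + 1e-6


class TestRedoxCapacity:
    def test_ppp_like_yield(self):
        # 2 NADPH per glucose-like carbon, uptake capped at 1
        mets = [Metabolite(id=m) for m in ("glc[e]", "nadp[c]", "nadph[c]")]
        rxns = [
            Reaction("EX_glc", {"glc[e]": -1.0}, -1.0, 0.0, is_exchange=True),
            Reaction("PPP", {"glc[e]": -1.0, "nadp[c]": -2.0, "nadph[c]": 2.0},
                     0.0, 1000.0),
            Reaction("OX", {"nadph[c]": -1.0, "nadp[c]": 1.0}, 0.0, 1000.0),
        ]
        net = MetabolicNetwork(mets, rxns)
        free = ContextModel.from_network(net)
        with pytest.raises(ValueError, match="nadh"):
            redox_capacity(free)  # no NADH pool in this toy
        _, nadph = redox_capacity(free, nadh_pair=("nadph", "nadp"))
        assert nadph == pytest.approx(2.0)

    def test_no_producer_means_zero(self):
        mets = [Metabolite(id="nadp[c]"), Metabolite(id="nadph[c]"),
                Metabolite(id="x[e]")]
        rxns = [Reaction("EX_x", {"x[e]": -1.0}, -10.0, 10.0, is_exchange=True)]
        free = ContextModel.from_network(MetabolicNetwork(mets, rxns))
        nadh, nadph = redox_capacity(
            free, nadh_pair=("nadph", "nadp"), nadph_pair=("nadph", "nadp")
        )
        assert nadph == pytest.approx(0.0)


class TestPathwayFoldChange:
    def test_median_example(self):
        a = CapacityTable({"m1": 2.0, "m2": 4.0})
        b = CapacityTable({"m1": 1.0, "m2": 1.0})
        out = pathway_fold_change(a, b, {"m1": "p", "m2": "p"})
        assert out["p"]["median"] == pytest.approx(3.0)

    def test_zero_denominator_floored_and_flagged(self):
        a = CapacityTable({"m1": 2.0})
        b = CapacityTable({"m1": 0.0})
        out = pathway_fold_change(a, b, {"m1": "p"})
        assert out["p"]["flag"] == "floored"
        assert out["p"]["median"] == pytest.approx(2.0 / 1e-9)

    def test_both_below_floor_excluded(self):
        a = CapacityTable({"m1": 0.0, "m2": 3.0})
        b = CapacityTable({"m1": 0.0, "m2": 1.0})
        out = pathway_fold_change(a, b, {"m1": "p", "m2": "p"})
        assert out["p"]["n"] == 1
        empty = pathway_fold_change(a, b, {"m1": "q"})
        assert empty["q"]["flag"] == "undefined"

    def test_matches_median_of_ratios(self):
        rng = np.random.default_rng(3)
        keys = [f"m{i}" for i in range(20)]
        a = CapacityTable({k: float(rng.uniform(0.1, 5)) for k in keys})
        b = CapacityTable({k: float(rng.uniform(0.1, 5)) for k in keys})
        out = pathway_fold_change(a, b, {k: "p" for k in keys})
        want = float(np.median([a.capacities[k] / b.capacities[k] for k in keys]))
        assert out["p"]["median"] == pytest.approx(want)


class TestEssentiality:
    def test_single_path_all_essential(self, chain_network):
        free = ContextModel.from_network(chain_network)
        assert essentiality_scan(free, "EX_B") == {"EX_A", "AB"}

    def test_parallel_paths_not_essential(self):
        mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]")]
        rxns = [
            Reaction("EX_A", {"A[c]": -1.0}, -10.0, 0.0, is_exchange=True),
            Reaction("AB1", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0),
            Reaction("AB2", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0),
            Reaction("EX_B", {"B[c]": -1.0}, 0.0, 1000.0, is_exchange=True),
        ]
        free = ContextModel.from_network(MetabolicNetwork(mets, rxns))
        assert essentiality_scan(free, "EX_B") == {"EX_A"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_knockouts(self, seed):
        scenario = make_toy_network(
            seed=seed, n_decoy_chains=1, fh_knockout=True
        )
        free = ContextModel.from_network(scenario.network)
        got = essentiality_scan(free, "SINK_gsh_c")
        want = knockout_bruteforce(scenario.network, "SINK_gsh_c", 0.01)
        assert got == want


class TestCouplingScan:
    def test_forcing_nadph_consumer_lowers_capacity(self):
        scenario = make_toy_network(seed=1, fh_knockout=True)
        free = ContextModel.from_network(scenario.network)
        result = coupling_scan(
            free, "nadph", reactions=["CYS2R", "EX_dcy0"], eps_act=1.0
        )
        # CYS2R burns NADPH, so forcing it lowers the capacity ...
        assert result.per_reaction["CYS2R"] < result.reference_capacity - 0.5
        # ... while a stoichiometrically disconnected decoy leaves it unchanged
        assert result.per_reaction["EX_dcy0"] == pytest.approx(
            result.reference_capacity, abs=1e-6
        )

    def test_scan_matches_forced_lp_oracle(self, chain_network):
        free = ContextModel.from_network(chain_network)
        result = coupling_scan(free, "B", eps_act=2.0)
        for rid in ("EX_A", "AB", "EX_B"):
            r = chain_network.reaction(rid)
            candidates = []
            drained = chain_network.with_reactions(
                added=[Reaction("D", {"B[c]": -1.0}, 0.0, 1000.0)]
            )
            if r.upper_bound >= 2.0:
                res = lp_optimize(
                    drained, {"D": 1.0}, "max",
                    bound_overrides={rid: (max(r.lower_bound, 2.0), r.upper_bound)},
                )
                if res:
                    candidates.append(res[0])
            if r.lower_bound <= -2.0:
                res = lp_optimize(
                    drained, {"D": 1.0}, "max",
                    bound_overrides={rid: (r.lower_bound, min(r.upper_bound, -2.0))},
                )
                if res:
                    candidates.append(res[0])
            assert result.per_reaction[rid] == pytest.approx(max(candidates))

    def test_reference_comparison_fields(self):
        scenario = make_toy_network(seed=2, fh_knockout=True)
        from contextflux import SuccinationSpec, add_succination

        net = add_succination(scenario.network, SuccinationSpec(sink_min_flux=0.01))
        free = ContextModel.from_network(net)
        result = coupling_scan(
            free, "nadph", reference_reaction="SUCCGSH_SINK"
        )
        cmp = result.comparison
        assert cmp["method"] == "wilcoxon-ranksum"
        assert 0.0 < cmp["empirical_rank_p"] <= 1.0
        assert cmp["reference_decrease"] >= -1e-9
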