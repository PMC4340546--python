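"""Expression discretisation, iMAT and the measured-flux L1 fit."""

import numpy as np
import pytest

from contextflux import (
    ContextModel,
    FluxMeasurementSet,
    ReactionCategories,
    discretize_expression,
    fit_fluxes,
    make_toy_network,
    map_expression_to_reactions,
    run_fva,
    simulate_expression,
    simulate_measurements,
    solve_imat,
)
from contextflux.context import ContradictionError

from conftest import imat_bruteforce, make_chain_network, random_categories


class TestDiscretize:
    def test_three_gene_example(self):
        profile = discretize_expression({"g1": 10.0, "g2": 1.0, "g3": 5.0})
        assert profile.categories == {"g1": "HIGH", "g2": "LOW", "g3": "MODERATE"}

    def test_all_equal_values_are_moderate(self):
        profile = discretize_expression({f"g{i}": 2.0 for i in range(10)})
        assert set(profile.categories.values()) == {"MODERATE"}

    def test_counts_match_sort_oracle(self):
        rng = np.random.default_rng(0)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
        profile = discretize_expression(values, 0.25, 0.75)
        arr = np.sort(list(values.values()))
        lo, hi = np.quantile(arr, [0.25, 0.75])
        n_high = int((arr > hi).sum())
        n_low = int((arr < lo).sum())
        got = list(profile.categories.values())
        assert got.count("HIGH") == n_high
        assert got.count("LOW") == n_low
        assert got.count("MODERATE") == 200 - n_high - n_low

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discretize_expression({})


class TestReactionMapping:
    def test_and_or_and_empty_rules(self):
        scenario = make_toy_network(seed=0)
        profile = simulate_expression(scenario)
        cats = map_expression_to_reactions(scenario.network, profile)
        # complex (AND) takes the min of its subunits
        a = profile.categories["g_cys2r_a"]
        assert cats["CYS2R"] == a  # both subunits share a category
        # reactions without GPR are MODERATE
        assert cats["BIOMASS"] == "MODERATE"


class TestIMAT:
    def test_single_high_chain(self, chain_network):
        cats = ReactionCategories({"AB": "HIGH"})
        assignment, optimum = solve_imat(chain_network, cats, eps_act=1.0)
        assert optimum == 1
        assert assignment["AB"] == "ACTIVE_FWD"

    def test_single_low_is_silenceable(self, chain_network):
        cats = ReactionCategories({"AB": "LOW"})
        _, optimum = solve_imat(chain_network, cats, eps_act=1.0)
        assert optimum == 1  # nothing forces flux through the chain

    def test_all_moderate_scores_zero(self, chain_network):
        _, optimum = solve_imat(chain_network, ReactionCategories({}), 1.0)
        assert optimum == 0

    def test_conflicting_high_and_low_on_coupled_chain(self, chain_network):
        # EX_A and AB are flux-coupled; HIGH on one, LOW on the other
        # cannot both be satisfied
        cats = ReactionCategories({"AB": "HIGH", "EX_B": "LOW"})
        _, optimum = solve_imat(chain_network, cats, eps_act=1.0)
        assert optimum == 1
        assert optimum == imat_bruteforce(chain_network, cats.categories, 1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_labels(self, seed):
        rng = np.random.default_rng(seed)
        net = make_chain_network()
        cats = random_categories(net, rng, max_labels=3)
        _, optimum = solve_imat(net, ReactionCategories(cats), eps_act=1.0)
        assert optimum == imat_bruteforce(net, cats, 1.0)

    def test_bad_epsilon_rejected(self, chain_network):
        with pytest.raises(ValueError):
            solve_imat(chain_network, ReactionCategories({}), eps_act=0.0)


class TestFluxFit:
    def test_attainable_measurement_gives_zero_deviation(self, chain_network):
        meas = FluxMeasurementSet({"EX_B": 5.0})
        ctx = fit_fluxes(chain_network, ReactionCategories({}), 0, meas)
        assert ctx.deviation_optimum == pytest.approx(0.0, abs=1e-9)
        (rng,) = run_fva(ctx, ["EX_B"])
        assert rng.min_flux == pytest.approx(5.0, abs=1e-5)
        assert rng.max_flux == pytest.approx(5.0, abs=1e-5)

    def test_bound_clipped_measurement_gives_clip_distance(self):
        net = make_chain_network()
        capped = net.with_reactions()  # copy
        from dataclasses import replace

        capped.reactions[2] = replace(capped.reactions[2], upper_bound=3.0)
        meas = FluxMeasurementSet({"EX_B": 5.0})
        ctx = fit_fluxes(capped, ReactionCategories({}), 0, meas)
        assert ctx.deviation_optimum == pytest.approx(2.0, abs=1e-6)

    def test_jointly_unattainable_measurements_match_grid_oracle(self, chain_network):
        # steady state forces v_EX_A = -v_EX_B; measurements ask for
        # EX_A = -5 and EX_B = 3 simultaneously
        meas = FluxMeasurementSet({"EX_A": -5.0, "EX_B": 3.0})
        ctx = fit_fluxes(chain_network, ReactionCategories({}), 0, meas)
        # dense grid over the 1-D family v_EX_B = t, v_EX_A = -t
        ts = np.linspace(0.0, 10.0, 20001)
        oracle = np.min(np.abs(-ts - (-5.0)) + np.abs(ts - 3.0))
        assert ctx.deviation_optimum == pytest.approx(float(oracle), abs=1e-6)

    def test_deviation_monotone_in_measurements_and_bounds(self):
        scenario = make_toy_network(seed=4)
        profile = simulate_expression(scenario)
        cats = map_expression_to_reactions(scenario.network, profile)
        _, opt = solve_imat(scenario.network, cats)
        full = simulate_measurements(scenario, sigma=0.2, seed=9)
        items = sorted(full.measurements.items())
        d_prev = -1.0
        for k in (2, 4, len(items)):
            ctx = fit_fluxes(
                scenario.network, cats, opt, FluxMeasurementSet(dict(items[:k]))
            )
            assert ctx.deviation_optimum >= d_prev - 1e-9
            d_prev = ctx.deviation_optimum

    def test_linearization_exactness(self, chain_network):
        meas = FluxMeasurementSet({"EX_A": -5.0, "EX_B": 3.0})
        ctx = fit_fluxes(chain_network, ReactionCategories({}), 0, meas)
        prob = ctx.build_problem()
        dev_vars = {
            f"yplus_{r}": 1.0 for r in meas.measurements
        } | {f"yminus_{r}": 1.0 for r in meas.measurements}
        sol = prob.solve_or_raise(dev_vars, "min")
        total_y = sum(sol.values[v] for v in dev_vars)
        total_abs = sum(
            abs(sol.values[f"v_{r}"] - f) for r, f in meas.measurements.items()
        )
        assert total_y == pytest.approx(total_abs, abs=1e-8)
        assert total_y == pytest.approx(ctx.deviation_optimum, abs=1e-6)

    def test_measurement_on_missing_reaction_is_hard_error(self, chain_network):
        meas = FluxMeasurementSet({"EX_missing": 1.0})
        with pytest.raises(ValueError, match="EX_missing"):
            fit_fluxes(chain_network, ReactionCategories({}), 0, meas)

    def test_unattainable_imat_optimum_contradicts(self, chain_network):
        with pytest.raises(ContradictionError):
            fit_fluxes(
                chain_network, ReactionCategories({"AB": "HIGH"}), 99,
                FluxMeasurementSet({"EX_B": 5.0}),
            )


class TestLocking:
    def test_locked_ranges_subset_of_unlocked(self):
        scenario = make_toy_network(seed=5)
        profile = simulate_expression(scenario)
        cats = map_expression_to_reactions(scenario.network, profile)
        _, opt = solve_imat(scenario.network, cats)
        meas = simulate_measurements(scenario, sigma=0.0, seed=0)
        ctx = fit_fluxes(scenario.network, cats, opt, meas)
        free = ContextModel.from_network(scenario.network)
        locked = {r.reaction_id: r for r in run_fva(ctx)}
        unlocked = {r.reaction_id: r for r in run_fva(free)}
        for rid, lr in locked.items():
            ur = unlocked[rid]
            assert lr.min_flux >= ur.min_flux - 1e-6
            assert lr.max_flux <= ur.max_flux + 1e-6

    def test_relaxed_lock_recovers_unlocked_space(self, chain_network):
        meas = FluxMeasurementSet({"EX_B": 5.0})
        ctx = fit_fluxes(chain_network, ReactionCategories({}), 0, meas)
        relaxed = ContextModel(
            network=ctx.network,
            reaction_categories=ctx.reaction_categories,
            measurements=ctx.measurements,
            imat_optimum=ctx.imat_optimum,
            deviation_optimum=ctx.deviation_optimum,
            lock_abs_tol=1e9,
        )
        free = ContextModel.from_network(chain_network)
        for got, want in zip(run_fva(relaxed), run_fva(free)):
            assert got.min_flux == pytest.approx(want.min_flux, abs=1e-6)
            assert got.max_flux == pytest.approx(want.max_flux, abs=1e-6)

    def test_feasible_space_vertices_satisfy_locks(self):
        scenario = make_toy_network(seed=8, n_decoy_chains=2)
        profile = simulate_expression(scenario)
        cats = map_expression_to_reactions(scenario.network, profile)
        _, opt = solve_imat(scenario.network, cats)
        meas = simulate_measurements(scenario, sigma=0.0, seed=0)
        ctx = fit_fluxes(scenario.network, cats, opt, meas)
        rng = np.random.default_rng(1)
        rxn_ids = [r.id for r in scenario.network.reactions]
        for _ in range(10):
            objective = {
                f"v_{rid}": float(rng.normal()) for rid in rng.choice(rxn_ids, 5)
            }
            sol = ctx.build_problem().solve_or_raise(objective, "max")
            total_dev = sum(
                abs(sol.values[f"v_{r}"] - f)
                for r, f in meas.measurements.items()
            )
            assert total_dev <= ctx.deviation_lock + 1e-8
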