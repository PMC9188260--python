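import numpy as np
import pandas as pd
import pytest

import lpmgem as L
from lpmgem.fit import (
    FitConfig,
    FitTargets,
    ReactionPartition,
    map_expression_to_flux,
    select_associated,
    summarize_expression,
    total_discrepancy,
)


def summary_from(gbar: pd.DataFrame):
    return L.fit.ExpressionSummary(
        gbar=gbar, gmin=gbar.min(axis=1), gmax=gbar.max(axis=1)
    )


class TestSummarize:
    def test_gene_mean_per_condition(self):
        expr = pd.DataFrame({"A": [4.0, 6.0]}, index=["g1", "g2"])
        s = summarize_expression(expr, {"R1": ["g1", "g2"]}, ["R1"])
        assert s.gbar.loc["R1", "A"] == 5.0

    def test_single_condition_degenerate_range(self):
        expr = pd.DataFrame({"A": [4.0]}, index=["g1"])
        s = summarize_expression(expr, {"R1": ["g1"]}, ["R1"])
        assert s.gmin["R1"] == s.gmax["R1"] == 4.0

    def test_absent_gene_skipped_and_empty_reaction_dropped(self, caplog):
        expr = pd.DataFrame({"A": [4.0]}, index=["g1"])
        s = summarize_expression(
            expr, {"R1": ["g1", "ghost"], "R2": ["ghost"]}, ["R1", "R2"]
        )
        assert s.gbar.loc["R1", "A"] == 4.0
        assert s.dropped == ["R2"]

    def test_empty_reaction_set_rejected(self):
        with pytest.raises(ValueError):
            summarize_expression(pd.DataFrame(), {}, [])


class TestMapping:
    FVA = pd.DataFrame({"min": [0.0], "max": [10.0]}, index=["R1"])

    def map_one(self, gbar_values, conditions=("A", "B", "C")):
        gbar = pd.DataFrame([gbar_values], index=["R1"], columns=list(conditions))
        return map_expression_to_flux(summary_from(gbar), self.FVA)

    def test_endpoints_hit_flux_range_exactly(self):
        t = self.map_one([2.0, 3.0, 4.0])
        assert t.vfit.loc["R1", "A"] == pytest.approx(0.0, abs=1e-12)
        assert t.vfit.loc["R1", "C"] == pytest.approx(10.0, abs=1e-12)

    def test_midpoint_interpolates_linearly(self):
        t = self.map_one([2.0, 3.0, 4.0])
        assert t.vfit.loc["R1", "B"] == pytest.approx(5.0, abs=1e-12)

    def test_degenerate_expression_targets_flux_midpoint(self):
        fva = pd.DataFrame({"min": [-4.0], "max": [10.0]}, index=["R1"])
        gbar = pd.DataFrame({"A": [3.0], "B": [3.0]}, index=["R1"])
        t = map_expression_to_flux(summary_from(gbar), fva)
        assert (t.vfit.loc["R1"] == 3.0).all()  # (-4+10)/2

    def test_mapping_is_invertible_when_nondegenerate(self):
        """Affine map then inverse recovers the expression values."""
        g = np.array([2.0, 2.7, 3.9, 4.0])
        t = self.map_one(g, conditions=list("ABCD"))
        v = t.vfit.loc["R1"].to_numpy()
        g_back = 2.0 + (v - 0.0) * (4.0 - 2.0) / (10.0 - 0.0)
        np.testing.assert_allclose(g_back, g, atol=1e-9)

    def test_targets_stay_inside_flux_range(self):
        t = self.map_one([2.0, 3.0, 4.0])
        assert (t.vfit.loc["R1"] >= 0.0).all()
        assert (t.vfit.loc["R1"] <= 10.0).all()


class TestWeights:
    def test_core_weight_is_reciprocal_representative_bound(self):
        fva = pd.DataFrame({"min": [-4.0], "max": [6.0]}, index=["R1"])
        part = ReactionPartition(core=["R1"], associated=[], other=[])
        w = L.compute_weights(fva, part)
        assert w["R1"] == pytest.approx(1.0 / 6.0)

    def test_associated_weight_offset(self):
        fva = pd.DataFrame({"min": [-4.0], "max": [6.0]}, index=["R1"])
        part = ReactionPartition(core=[], associated=["R1"], other=[])
        w = L.compute_weights(fva, part)
        assert w["R1"] == pytest.approx(1.0 / 106.0)

    def test_zero_range_core_reaction_is_an_error(self):
        fva = pd.DataFrame({"min": [0.0], "max": [0.0]}, index=["R1"])
        part = ReactionPartition(core=["R1"], associated=[], other=[])
        with pytest.raises(ValueError, match="zero flux range"):
            L.compute_weights(fva, part)

    def test_blocked_reactions_discarded_from_partition(self, path_net):
        fva = pd.DataFrame(
            {"min": [0.0, 0.0], "max": [10.0, 0.0]}, index=["R1", "R2"]
        )
        part = ReactionPartition.from_sets(path_net, ["R1", "R2"], [], fva)
        assert part.fitted == ["R1"]
        assert "R2" in part.other


class TestSelectAssociated:
    def _frames(self, rng, n_null=50, shift=5.0, sd=1.0, n_rep=5):
        genes = [f"g{i}" for i in range(n_null)] + ["g_shift"]
        control = pd.DataFrame(
            rng.normal(5.0, sd, size=(len(genes), n_rep)),
            index=genes,
            columns=[f"ctl{i}" for i in range(n_rep)],
        )
        expr = pd.DataFrame(
            rng.normal(5.0, sd, size=(len(genes), n_rep)),
            index=genes,
            columns=[f"c{i}" for i in range(n_rep)],
        )
        expr.loc["g_shift"] += shift * sd
        return expr, control

    def test_identical_gene_not_selected(self):
        expr = pd.DataFrame({"c1": [5.0], "c2": [5.0]}, index=["g1"])
        ctl = pd.DataFrame({"k1": [5.0], "k2": [5.0]}, index=["g1"])
        got = select_associated(
            expr, ctl, ["R1"], {"R1": ["g1"]}, {"A": ["c1", "c2"]}
        )
        assert got == []

    def test_perfect_separation_selected(self):
        expr = pd.DataFrame({"c1": [9.0], "c2": [9.0]}, index=["g1"])
        ctl = pd.DataFrame({"k1": [2.0], "k2": [2.0]}, index=["g1"])
        got = select_associated(
            expr, ctl, ["R1"], {"R1": ["g1"]}, {"A": ["c1", "c2"]}
        )
        assert got == ["R1"]

    def test_too_few_replicates_rejected(self):
        expr = pd.DataFrame({"c1": [9.0]}, index=["g1"])
        ctl = pd.DataFrame({"k1": [2.0], "k2": [2.0]}, index=["g1"])
        with pytest.raises(ValueError, match="A"):
            select_associated(expr, ctl, ["R1"], {"R1": ["g1"]}, {"A": ["c1"]})

    def test_planted_shift_recovered_nulls_spared(self):
        """A 5-SD shift at n=5 is found while nulls stay mostly untouched.

        With five replicates per group the noncentral-t power of the test at
        the worst-case step-up threshold 0.05/51 is 0.967 (two-sample t,
        df = 8, ncp = 5/sqrt(2/5)), so the planted gene should be selected
        in well over 90% of repeats while the pooled null rejection rate
        stays within the 5% FDR target.
        """
        rng = np.random.default_rng(42)
        gpr = {"R_shift": ["g_shift"]}
        n_hit = 0
        null_rejections = 0
        n_nulls_total = 0
        for _ in range(200):
            expr, ctl = self._frames(rng)
            gpr_all = {**gpr, **{f"R{i}": [f"g{i}"] for i in range(50)}}
            got = select_associated(
                expr,
                ctl,
                list(gpr_all),
                gpr_all,
                {"A": list(expr.columns)},
                fdr=0.05,
            )
            n_hit += "R_shift" in got
            null_rejections += sum(1 for r in got if r != "R_shift")
            n_nulls_total += 50
        assert n_hit / 200 >= 0.9
        assert null_rejections / n_nulls_total <= 0.05


class TestSolveFit:
    def test_feasible_targets_give_zero_discrepancy(self, path_net):
        fva = L.run_fva(path_net, ["R1", "R2"])
        part = ReactionPartition.from_sets(path_net, ["R1", "R2"], [], fva)
        config = FitConfig(alpha=0.0, weights=L.compute_weights(fva, part))
        vfit = pd.DataFrame({"c1": [4.0, 4.0]}, index=["R1", "R2"])
        targets = FitTargets(vfit=vfit, vmin=fva["min"], vmax=fva["max"])
        sol, rep = L.solve_fit(path_net, targets, part, config)
        assert rep.total == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes.loc["R1", "c1"] == pytest.approx(4.0, abs=1e-9)

    def test_bound_clipped_target_residual_is_clip_distance(self, path_net):
        """Target 8 on a path capped at 5: optimum sits at the cap,
        residual = 3 (hand-solved one-path LP)."""
        fva = L.run_fva(path_net, ["R1"])  # range (0, 10)
        part = ReactionPartition.from_sets(path_net, ["R1"], [], fva)
        config = FitConfig(alpha=0.0, weights=L.compute_weights(fva, part))
        targets = FitTargets(
            vfit=pd.DataFrame({"c1": [8.0]}, index=["R1"]),
            vmin=fva["min"],
            vmax=fva["max"],
        )
        capped = path_net.with_bounds({"EX_in": (-5.0, 0.0)})
        sol, rep = L.solve_fit(capped, targets, part, config)
        assert sol.fluxes.loc["R1", "c1"] == pytest.approx(5.0, abs=1e-8)
        assert rep.total == pytest.approx(3.0, abs=1e-8)
        # weighted objective = w * residual
        assert sol.objective["c1"] == pytest.approx(3.0 / 10.0, abs=1e-8)

    def test_large_alpha_silences_free_cycle(self, loop_net):
        fva_all = L.run_fva(loop_net, ["R1", "R2"])
        part = ReactionPartition.from_sets(loop_net, ["R1", "R2"], [], fva_all)
        config = FitConfig(alpha=10.0, weights=L.compute_weights(fva_all, part))
        targets = FitTargets(
            vfit=pd.DataFrame({"c1": [5.0, 5.0]}, index=["R1", "R2"]),
            vmin=fva_all["min"],
            vmax=fva_all["max"],
        )
        sol, _ = L.solve_fit(loop_net, targets, part, config)
        assert abs(sol.fluxes.loc["C1", "c1"]) <= 1e-8

    def test_infeasible_condition_reported_not_silent(self, path_net):
        fva = L.run_fva(path_net, ["R1"])
        part = ReactionPartition.from_sets(path_net, ["R1"], [], fva)
        config = FitConfig(
            alpha=0.0,
            weights=L.compute_weights(fva, part),
            biomass_floors={"c1": 99.0},
        )
        targets = FitTargets(
            vfit=pd.DataFrame({"c1": [5.0]}, index=["R1"]),
            vmin=fva["min"],
            vmax=fva["max"],
        )
        sol, _ = L.solve_fit(path_net, targets, part, config)
        assert sol.status["c1"] == "infeasible"


class TestAlphaTradeoff:
    def test_fit_term_rises_penalty_falls_with_alpha(self, loop_scenario, loop_fit_inputs):
        inputs = loop_fit_inputs
        net = loop_scenario.network
        targets = L.map_expression_to_flux(inputs.summary, inputs.fva)
        fit_terms, penalties = [], []
        for alpha in [0.0, 0.01, 0.1, 1.0, 10.0]:
            config = FitConfig(alpha=alpha, weights=inputs.config.weights)
            sol, _ = L.solve_fit(net, targets, inputs.partition, config)
            assert sol.all_optimal()
            fit_terms.append(sum(sol.fit_term.values()))
            penalties.append(sum(sol.penalty_term.values()))
        tol = 1e-7
        assert all(a <= b + tol for a, b in zip(fit_terms, fit_terms[1:]))
        assert all(a >= b - tol for a, b in zip(penalties, penalties[1:]))


class TestRecovery:
    def test_noiseless_affine_expression_recovers_planted_fluxes(self):
        sc = L.make_multicarbon_scenario(seed=7, noise_sd=0.0)
        inputs = L.prepare_fit(sc.network, sc.expression, sc.gpr, sc.core, alpha=0.0)
        targets = L.map_expression_to_flux(inputs.summary, inputs.fva)
        sol, _ = L.solve_fit(sc.network, targets, inputs.partition, inputs.config)
        fitted = inputs.partition.fitted
        pred = sol.fluxes.loc[fitted].to_numpy().ravel()
        plant = sc.planted.loc[fitted].to_numpy().ravel()
        assert np.corrcoef(pred, plant)[0, 1] >= 0.99


class TestDiscrepancy:
    def _simple(self, v, vfit):
        sol = L.FluxSolution(fluxes=pd.DataFrame(v), status={"c": "optimal"})
        targets = FitTargets(
            vfit=pd.DataFrame(vfit),
            vmin=pd.Series(dtype=float),
            vmax=pd.Series(dtype=float),
        )
        return total_discrepancy(sol, targets)

    def test_perfect_fit_is_zero(self):
        rep = self._simple({"c": {"R1": 3.0}}, {"c": {"R1": 3.0}})
        assert rep.total == 0.0

    def test_single_residual(self):
        rep = self._simple({"c": {"R1": 3.0}}, {"c": {"R1": 5.0}})
        assert rep.total == 2.0

    def test_additivity_across_conditions(self):
        rep = self._simple(
            {"a": {"R1": 1.0}, "b": {"R1": 0.0}},
            {"a": {"R1": 0.0}, "b": {"R1": 2.0}},
        )
        assert rep.total == 3.0

    def test_reported_total_matches_independent_recomputation(self, loop_scenario, loop_fit_inputs):
        inputs = loop_fit_inputs
        targets = L.map_expression_to_flux(inputs.summary, inputs.fva)
        sol, rep = L.solve_fit(
            loop_scenario.network, targets, inputs.partition, inputs.config
        )
        manual = 0.0
        for cond in sol.conditions:
            for rid in inputs.partition.fitted:
                manual += abs(
                    sol.fluxes.loc[rid, cond] - targets.vfit.loc[rid, cond]
                )
        assert rep.total == pytest.approx(manual, abs=1e-8)
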