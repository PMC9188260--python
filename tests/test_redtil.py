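import numpy as np
import pandas as pd
import pytest

import lpmgem as L
from lpmgem.model import MetabolicNetwork
from lpmgem.redtil import _enumerate_balanced_cycles
from lpmgem.synthetic import make_random_fit_case

from conftest import riding_cycle_case


def two_and_three_cycle_net():
    """A 2-cycle (forward/backward pair on A↔B) plus a 3-cycle A→B→C→A."""
    mets = ["A", "B", "C"]
    rids = ["F", "Rv", "C1", "C2", "C3"]
    cols = [
        {"A": -1, "B": 1},
        {"B": -1, "A": 1},
        {"A": -1, "B": 1},
        {"B": -1, "C": 1},
        {"C": -1, "A": 1},
    ]
    S = np.zeros((3, 5))
    for j, c in enumerate(cols):
        for m, v in c.items():
            S[mets.index(m), j] = v
    return MetabolicNetwork(
        mets, rids, S, np.zeros(5), np.full(5, 10.0),
        np.zeros(5, bool), np.zeros(5, bool),
    )


class TestSupport:
    def test_all_zero_solution_empty_support(self, loop_net):
        v = pd.Series(0.0, index=loop_net.reaction_ids)
        assert L.support_set(v, loop_net) == []

    def test_exchanges_excluded_and_signs_tagged(self, loop_net):
        v = pd.Series(0.0, index=loop_net.reaction_ids)
        v["C1"], v["C2"], v["EX_in"] = 0.5, -0.5, -10.0
        assert L.support_set(v, loop_net, 0.01) == [("C1", 1), ("C2", -1)]

    def test_threshold_filters_small_fluxes(self, loop_net):
        v = pd.Series(0.0, index=loop_net.reaction_ids)
        v["C1"], v["C2"] = 0.5, -0.5
        assert L.support_set(v, loop_net, 0.6) == []


class TestDetectMinLoop:
    def test_canonical_three_cycle_found(self, loop_net):
        cut = L.detect_min_loop(loop_net, [("C1", 1), ("C2", 1), ("C3", 1)])
        assert cut is not None
        assert cut.k == 3
        assert {r for r, _ in cut.members} == {"C1", "C2", "C3"}

    def test_acyclic_support_returns_none(self, loop_net):
        assert L.detect_min_loop(loop_net, [("R1", 1), ("R2", 1)]) is None

    def test_empty_support_returns_none(self, loop_net):
        assert L.detect_min_loop(loop_net, []) is None

    def test_smallest_cycle_preferred(self):
        """With a 2-cycle and a 3-cycle both in support, the MILP picks k=2 —
        verified against exhaustive cycle enumeration."""
        net = two_and_three_cycle_net()
        support = [(r, 1) for r in net.reaction_ids]
        cut = L.detect_min_loop(net, support)
        assert cut.k == 2
        assert {r for r, _ in cut.members} == {"F", "Rv"}
        cycles = _enumerate_balanced_cycles(net, support)
        assert min(len(c) for c in cycles) == 2
        assert tuple(sorted(r for r, _ in cut.members)) in cycles

    def test_two_cycle_is_minimal_possible(self):
        net = L.make_loop_network(cycle_len=2, attach_to_path=False)
        cut = L.detect_min_loop(net, [("C1", 1), ("C2", 1)])
        assert cut.k == 2


class TestRunRedtil:
    def test_loop_free_solution_is_fixpoint(self, path_net):
        fva = L.run_fva(path_net, ["R1", "R2"])
        part = L.ReactionPartition.from_sets(path_net, ["R1", "R2"], [], fva)
        config = L.FitConfig(alpha=0.01, weights=L.compute_weights(fva, part))
        targets = L.FitTargets(
            vfit=pd.DataFrame({"c1": [4.0, 4.0]}, index=["R1", "R2"]),
            vmin=fva["min"],
            vmax=fva["max"],
        )
        plain, _ = L.solve_fit(path_net, targets, part, config)
        res = L.run_redtil(path_net, targets, part, config)
        assert res.cuts == {"c1": []}
        pd.testing.assert_frame_equal(res.solution.fluxes, plain.fluxes, atol=1e-9)

    def test_riding_cycle_removed_path_preserved(self):
        """The fit optimum initially rides the 3-cycle at 600; afterwards the
        cycle is sub-threshold and the path carries the hand-computed
        loopless optimum (flux 5)."""
        net, targets, partition, config = riding_cycle_case(alpha=0.0)
        before, _ = L.solve_fit(net, targets, partition, config)
        assert before.fluxes.loc["C1", "c1"] == pytest.approx(600.0, abs=1e-6)
        res = L.run_redtil(net, targets, partition, config)
        assert sum(len(c) for c in res.cuts.values()) >= 1
        assert abs(res.solution.fluxes.loc["C1", "c1"]) < 0.01
        for rid in ["R1", "R2", "EX_out"]:
            assert res.solution.fluxes.loc[rid, "c1"] == pytest.approx(5.0, abs=1e-6)
        ok, _ = L.loopless_check(res.solution.fluxes["c1"], net)
        assert ok

    def test_high_threshold_means_no_cuts(self):
        net, targets, partition, config = riding_cycle_case(alpha=0.0)
        res = L.run_redtil(net, targets, partition, config, threshold=1e4)
        assert res.cuts["c1"] == []

    def test_cut_log_records_members(self):
        net, targets, partition, config = riding_cycle_case(alpha=0.0)
        res = L.run_redtil(net, targets, partition, config)
        assert not res.log.empty
        assert set(res.log.columns) == {"condition", "iteration", "k", "members", "objective"}


class TestLooplessCheck:
    def test_planted_unit_cycle_flagged_with_certificate(self, loop_net):
        v = pd.Series(0.0, index=loop_net.reaction_ids)
        v[["C1", "C2", "C3"]] = 1.0
        ok, cert = L.loopless_check(v, loop_net)
        assert not ok
        assert ("C1", "C2", "C3") in cert

    def test_empty_support_is_loopless(self, loop_net):
        v = pd.Series(0.0, index=loop_net.reaction_ids)
        ok, cert = L.loopless_check(v, loop_net)
        assert ok and cert == []

    def test_oracles_agree_on_random_networks_after_redtil(self):
        """MILP infeasibility and cycle enumeration must agree before and
        after loop removal on random loop-prone networks."""
        for seed in range(25):
            net, targets, partition, config = make_random_fit_case(seed)
            sol, _ = L.solve_fit(net, targets, partition, config)
            for cond in sol.conditions:
                L.loopless_check(sol.fluxes[cond], net)  # agreement or raise
            res = L.run_redtil(net, targets, partition, config)
            for cond in res.solution.conditions:
                ok, _ = L.loopless_check(res.solution.fluxes[cond], net)
                assert ok, (seed, cond)


class TestFullLooplessReference:
    def test_loop_free_network_matches_plain_fit(self, path_net):
        fva = L.run_fva(path_net, ["R1", "R2"])
        part = L.ReactionPartition.from_sets(path_net, ["R1", "R2"], [], fva)
        config = L.FitConfig(alpha=0.01, weights=L.compute_weights(fva, part))
        targets = L.FitTargets(
            vfit=pd.DataFrame({"c1": [4.0, 4.0]}, index=["R1", "R2"]),
            vmin=fva["min"],
            vmax=fva["max"],
        )
        plain, _ = L.solve_fit(path_net, targets, part, config)
        ref = L.full_loopless_reference(path_net, targets, part, config)
        assert ref.objective["c1"] == pytest.approx(plain.objective["c1"], abs=1e-8)

    def test_objective_matches_redtil_on_cycle_fixture(self):
        net, targets, partition, config = riding_cycle_case(alpha=0.01)
        res = L.run_redtil(net, targets, partition, config)
        ref = L.full_loopless_reference(net, targets, partition, config)
        assert res.solution.objective["c1"] == pytest.approx(
            ref.objective["c1"], abs=1e-6
        )

    def test_fitted_fluxes_correlate_across_random_seeds(self):
        preds, refs = [], []
        for seed in range(10):
            net, targets, partition, config = make_random_fit_case(seed)
            res = L.run_redtil(net, targets, partition, config)
            ref = L.full_loopless_reference(net, targets, partition, config)
            for cond in res.solution.conditions:
                preds.extend(res.solution.fluxes.loc[partition.fitted, cond])
                refs.extend(ref.fluxes.loc[partition.fitted, cond])
        r = np.corrcoef(preds, refs)[0, 1]
        assert r >= 0.95

    def test_size_guard(self):
        net = L.make_loop_network()
        with pytest.raises(ValueError, match="guard"):
            L.full_loopless_reference(
                net, None, None, None, max_reactions=net.n_reactions - 1
            )
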