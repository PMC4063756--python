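"""Self-reputation awareness policy: classification and strategy adjustment."""

import numpy as np
import pytest

from sracipd.evolution import EvolutionParams, generation_update
from sracipd.game import compute_fitness
from sracipd.network import build_lattice
from sracipd.reputation import Level, ReputationReport, build_report
from sracipd.srac import (
    Action,
    DEFAULT_POLICY,
    InteractionCell,
    PolicyTable,
    adjust_strategy,
    classify,
)


def make_report(self_rep_raw, rel_fit_raw, af=None, threshold=0.5):
    """Hand-build a minimal report from per-agent raw scores."""
    raw_r = np.asarray(self_rep_raw, dtype=float)
    raw_f = np.asarray(rel_fit_raw, dtype=float)
    if af is None:
        af = np.zeros_like(raw_r)

    def levels(raw):
        lv = np.zeros(len(raw), dtype=np.int8)
        lv[raw >= threshold] = int(Level.HIGH)
        lv[raw <= -threshold] = int(Level.LOW)
        return lv

    empty = np.array([], dtype=np.int64)
    return ReputationReport(
        observer=empty, opponent=empty, coop=np.array([]), z=np.array([]),
        af=np.asarray(af, dtype=float),
        self_rep_raw=raw_r, self_rep_level=levels(raw_r),
        rel_fit_raw=raw_f, rel_fit_level=levels(raw_f),
        threshold=threshold,
    )


class TestPolicyTable:
    def test_has_nine_cells(self):
        assert len(DEFAULT_POLICY.to_dict()) == 9

    def test_villain_cell_requires_adjustment(self):
        # high fitness earned with a low reputation = exploitative profile
        cell = DEFAULT_POLICY.cell(Level.HIGH, Level.LOW)
        assert cell.action != Action.KEEP
        assert cell.action == Action.IMITATE_REPUTABLE

    @pytest.mark.parametrize(
        "fit, rep, action",
        [
            (Level.MEDIUM, Level.MEDIUM, Action.KEEP),
            (Level.HIGH, Level.HIGH, Action.KEEP),
            (Level.LOW, Level.LOW, Action.IMITATE_REPUTABLE),
            (Level.LOW, Level.MEDIUM, Action.IMITATE_FIT_AND_REPUTABLE),
            (Level.LOW, Level.HIGH, Action.IMITATE_FIT_AND_REPUTABLE),
            (Level.HIGH, Level.MEDIUM, Action.KEEP),
        ],
    )
    def test_default_actions(self, fit, rep, action):
        assert DEFAULT_POLICY[(fit, rep)] == action

    def test_round_trip(self):
        d = DEFAULT_POLICY.to_dict()
        assert PolicyTable.from_dict(d).to_dict() == d

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PolicyTable({(Level.LOW, Level.LOW): Action.KEEP})


class TestClassify:
    def test_returns_cell_for_agent_levels(self):
        report = make_report([0.9, -0.9], [0.0, 0.9])
        cell = classify(1, report)
        assert cell == InteractionCell(Level.HIGH, Level.LOW,
                                       Action.IMITATE_REPUTABLE)

    def test_missing_agent_rejected(self):
        report = make_report([0.0], [0.0])
        with pytest.raises(KeyError):
            classify(5, report)


class TestAdjustStrategy:
    def test_keep_returns_own(self, rng):
        report = make_report([0.0, 0.9], [0.0, 0.0])
        cell = InteractionCell(Level.MEDIUM, Level.MEDIUM, Action.KEEP)
        out = adjust_strategy(0, cell, [1], report, np.array([15, 5]), rng)
        assert out == 15

    def test_imitates_most_reputable_neighbor(self, rng):
        # villain at node 0; node 2 is the high-reputation TFT exemplar
        report = make_report([-1.0, 0.0, 1.2, 0.3], [1.0, 0.0, 0.0, 0.0])
        cell = classify(0, report)
        out = adjust_strategy(0, cell, [1, 2, 3], report,
                              np.array([15, 8, 5, 9]), rng)
        assert out == 5

    def test_reputation_tie_broken_by_fitness_then_id(self, rng):
        report = make_report([-1.0, 0.8, 0.8, 0.8], [0.0, 0.0, 0.0, 0.0],
                             af=[0.0, 1.0, 2.0, 2.0])
        cell = InteractionCell(Level.LOW, Level.LOW, Action.IMITATE_REPUTABLE)
        out = adjust_strategy(0, cell, [1, 2, 3], report,
                              np.array([15, 1, 2, 3]), rng)
        assert out == 2  # nodes 2 and 3 tie on reputation and af; lower id wins

    def test_combined_fit_and_reputation_argmax(self, rng):
        report = make_report([0.0, 0.6, 0.4], [-1.0, 0.1, 0.6])
        cell = InteractionCell(Level.LOW, Level.MEDIUM,
                               Action.IMITATE_FIT_AND_REPUTABLE)
        # node 2 wins: 0.4 + 0.6 > 0.6 + 0.1
        out = adjust_strategy(0, cell, [1, 2], report, np.array([15, 7, 11]), rng)
        assert out == 11

    def test_explore_falls_back_when_all_low(self, rng):
        report = make_report([0.0, -1.0, -2.0], [0.0, 0.0, 0.0])
        cell = InteractionCell(Level.MEDIUM, Level.MEDIUM, Action.EXPLORE)
        out = adjust_strategy(0, cell, [1, 2], report, np.array([4, 15, 15]), rng)
        assert out == 4

    def test_never_adopts_low_reputation_strategy(self, rng):
        """Under every action the model neighbor must not be low-reputation."""
        v = 10
        for trial in range(200):
            raw_rep = rng.normal(size=v)
            report = make_report(raw_rep, rng.normal(size=v), af=rng.random(v))
            strategies = np.arange(v)  # unique: the adopted index names its source
            agent = int(rng.integers(v))
            nb = [j for j in range(v) if j != agent]
            for action in Action:
                cell = InteractionCell(Level.LOW, Level.LOW, action)
                out = adjust_strategy(agent, cell, nb, report, strategies, rng)
                if out != agent:
                    assert report.self_rep_level[out] != int(Level.LOW)

    def test_empty_neighborhood_rejected(self, rng):
        report = make_report([0.0], [0.0])
        cell = InteractionCell(Level.MEDIUM, Level.MEDIUM, Action.KEEP)
        with pytest.raises(ValueError, match="empty neighborhood"):
            adjust_strategy(0, cell, [], report, np.array([0]), rng)


class TestClusterInvasion:
    def test_srac_scoundrels_adjacent_to_cluster_convert(self):
        """Defectors bordering a reputable tit-for-tat cluster switch to the
        cluster strategy within one generation.  The conversion is forced for
        the cells facing a cluster side (three TFT neighbors, so enough of
        their observers witness the cluster for their own reputation to read
        low); defectors deep in the all-defect sea see no reputation gradient
        and keep their strategy."""
        net = build_lattice(10, 10)
        strategies = np.full(100, 15)
        cluster = [33, 34, 35, 43, 44, 45, 53, 54, 55]  # 3x3 TFT block
        strategies[cluster] = 5
        ft = compute_fitness(net, strategies, q=50)
        report = build_report(net, ft)
        new = generation_update(
            net, strategies, ft, EvolutionParams(), np.ones(100, dtype=bool),
            report, seed=1, generation=0,
        )
        side_centers = [24, 42, 46, 64]  # one cell off each cluster face
        assert np.all(new[side_centers] == 5)
        # every change is a conversion toward the cluster strategy, and only
        # cells adjacent to the cluster change at all
        changed = np.flatnonzero(new != strategies)
        boundary = {j for i in cluster for j in net.neighbors(i)} - set(cluster)
        assert set(changed) <= boundary
        assert np.all(new[changed] == 5)
        deep_sea = [0, 1, 9, 90, 99, 77]
        assert np.all(new[deep_sea] == 15)

    def test_policy_deterministic_given_seed(self):
        net = build_lattice(8, 8)
        rng = np.random.default_rng(0)
        strategies = rng.integers(0, 16, size=64)
        ft = compute_fitness(net, strategies, q=20)
        report = build_report(net, ft)
        srac = np.ones(64, dtype=bool)
        a = generation_update(net, strategies, ft, EvolutionParams(), srac,
                              report, seed=9, generation=0)
        b = generation_update(net, strategies, ft, EvolutionParams(), srac,
                              report, seed=9, generation=0)
        assert np.array_equal(a, b)
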