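"""Genetic-algorithm operators and the synchronous generation update."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sracipd.evolution import (
    EvolutionParams,
    agent_rng,
    crossover,
    crossover_index,
    generation_update,
    mutate,
    mutate_index,
    select_parent,
)
from sracipd.game import compute_fitness
from sracipd.network import build_lattice
from sracipd.reputation import build_report
from sracipd.strategy import Strategy


class TestParams:
    def test_defaults(self):
        p = EvolutionParams()
        assert (p.Pc, p.Pm, p.max_g) == (0.7, 0.01, 100)

    @pytest.mark.parametrize(
        "kwargs", [dict(Pc=1.5), dict(Pm=-0.1), dict(max_g=0), dict(selection="rank")]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvolutionParams(**kwargs)


class TestSelectParent:
    def test_uniform_when_fitness_equal(self, rng):
        from scipy.stats import chisquare

        af = {i: 2.0 for i in range(5)}
        draws = np.array(
            [select_parent(0, [1, 2, 3, 4], af, rng) for _ in range(10_000)]
        )
        counts = np.bincount(draws, minlength=5)
        assert chisquare(counts).pvalue > 1e-3

    def test_dominant_candidate_wins(self, rng):
        af = {0: 0.0, 1: 3.0, 2: 0.0}
        draws = [select_parent(0, [1, 2], af, rng) for _ in range(2000)]
        assert np.mean(np.array(draws) == 1) > 0.99

    def test_result_is_a_candidate(self, rng):
        af = {i: float(i) for i in range(4)}
        for _ in range(50):
            assert select_parent(3, [0, 1], af, rng) in {0, 1, 3}

    def test_tournament_picks_fittest_of_sample(self, rng):
        af = {0: 1.0, 1: 5.0}
        # k large enough that the fit candidate is almost surely sampled
        draws = [
            select_parent(0, [1], af, rng, selection="tournament", tournament_k=8)
            for _ in range(500)
        ]
        assert np.mean(np.array(draws) == 1) > 0.95

    def test_empty_neighborhood_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_parent(0, [], {0: 1.0}, rng)


class TestCrossover:
    @pytest.mark.parametrize("cut, expected", [(1, "CDDD"), (2, "CCDD"), (3, "CCCD")])
    def test_one_point_cut(self, cut, expected):
        out = crossover_index(0b0000, 0b1111, cut)
        assert Strategy.from_index(out) == Strategy.from_string(expected)

    def test_pc_zero_returns_first_parent(self, rng):
        a, b = Strategy.from_index(3), Strategy.from_index(12)
        assert all(crossover(a, b, 0.0, rng) == a for _ in range(20))

    def test_identical_parents_idempotent(self, rng):
        a = Strategy.from_index(9)
        assert all(crossover(a, a, 1.0, rng) == a for _ in range(20))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            crossover(Strategy.from_index(0), Strategy.from_index(0, memory=2),
                      1.0, rng)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(1, 3))
    def test_index_route_matches_tuple_route(self, ia, ib, cut):
        a, b = Strategy.from_index(ia), Strategy.from_index(ib)
        expected = Strategy(a.responses[:cut] + b.responses[cut:])
        assert crossover_index(ia, ib, cut) == expected.index


class TestMutate:
    def test_pm_zero_unchanged(self, rng):
        s = Strategy.from_index(10)
        assert all(mutate(s, 0.0, rng) == s for _ in range(20))

    def test_pm_one_flips_everything(self, rng):
        assert mutate(Strategy.from_index(0), 1.0, rng).index == 15

    def test_flip_rate_matches_binomial(self, rng):
        n = 100_000
        s = Strategy.from_index(0)
        flipped = sum(bin(mutate(s, 0.01, rng).index).count("1") for _ in range(n))
        mean, sd = n * 4 * 0.01, np.sqrt(n * 4 * 0.01 * 0.99)
        assert abs(flipped - mean) < 4 * sd

    def test_mutate_index_msb_first(self):
        # flipping locus 0 toggles the S_cc bit (most significant)
        assert mutate_index(0, np.array([True, False, False, False])) == 8


class TestGenerationUpdate:
    def _setup(self, v_side=6, q=10, seed=0):
        net = build_lattice(v_side, v_side)
        rng = np.random.default_rng(seed)
        strategies = rng.integers(0, 16, size=net.v)
        ft = compute_fitness(net, strategies, q=q)
        report = build_report(net, ft)
        return net, strategies, ft, report

    def test_no_novel_strategies_without_variation(self):
        net, strategies, ft, report = self._setup()
        params = EvolutionParams(Pc=0.0, Pm=0.0)
        new = generation_update(net, strategies, ft, params,
                                np.zeros(net.v, dtype=bool), None,
                                seed=5, generation=0)
        assert set(new) <= set(strategies)

    def test_homogeneous_stays_homogeneous(self):
        net = build_lattice(6, 6)
        strategies = np.full(net.v, 6)
        ft = compute_fitness(net, strategies, q=10)
        params = EvolutionParams(Pm=0.0)
        new = generation_update(net, strategies, ft, params,
                                np.zeros(net.v, dtype=bool), None,
                                seed=5, generation=0)
        assert np.all(new == 6)

    def test_all_srac_keep_policy_freezes_population(self):
        from sracipd.reputation import Level
        from sracipd.srac import Action, PolicyTable

        net, strategies, ft, report = self._setup()
        keep_all = PolicyTable({(f, r): Action.KEEP for f in Level for r in Level})
        new = generation_update(net, strategies, ft, EvolutionParams(),
                                np.ones(net.v, dtype=bool), report,
                                seed=5, generation=0, policy=keep_all)
        assert np.array_equal(new, strategies)

    def test_missing_report_with_srac_rejected(self):
        net, strategies, ft, _ = self._setup()
        with pytest.raises(ValueError, match="reputation report"):
            generation_update(net, strategies, ft, EvolutionParams(),
                              np.ones(net.v, dtype=bool), None,
                              seed=5, generation=0)

    def test_replay_bit_identical(self):
        net, strategies, ft, report = self._setup()
        srac = np.zeros(net.v, dtype=bool)
        srac[:10] = True
        args = (net, strategies, ft, EvolutionParams(), srac, report)
        a = generation_update(*args, seed=11, generation=3)
        b = generation_update(*args, seed=11, generation=3)
        assert np.array_equal(a, b)

    def test_substreams_distinct_across_agents_and_generations(self):
        draws = {
            (g, i): tuple(agent_rng(seed=2, generation=g, agent=i).random(3))
            for g in range(3)
            for i in range(5)
        }
        assert len(set(draws.values())) == len(draws)

    def test_mutation_reaches_every_strategy(self):
        """With Pm > 0 all sixteen strategies appear over a modest run."""
        import sracipd as sp

        cfg = sp.SimulationConfig(W=20, H=20, q=10, max_g=60, seed=8)
        res = sp.run(cfg)
        seen = set()
        for m in res.metrics:
            seen |= set(np.flatnonzero(m.strategy_counts))
        assert seen == set(range(16))
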