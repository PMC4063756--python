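"""Genetic-algorithm strategy update.

Non-SRAC agents evolve by a local genetic algorithm each generation: two
parents are drawn from the agent's neighborhood plus itself with
probability proportional to fitness (shifted to be non-negative), the
parents recombine by one-point crossover at rate Pc, and each locus of the
child mutates (C <-> D flip) independently at rate Pm.  All agents update
synchronously from the current generation's state, and every agent draws
from its own counter-based RNG substream keyed by (master seed,
generation, agent id), so results are independent of processing order and
bit-identical on replay.

The selection scheme itself is a design choice of this package (local
fitness-proportional roulette, with a tournament alternative behind
config); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .game import FitnessTable
from .network import SocialNetwork
from .reputation import ReputationReport
from .srac import DEFAULT_POLICY, PolicyTable, adjust_strategy, classify
from .strategy import Strategy

__all__ = [
    "EvolutionParams",
    "select_parent",
    "crossover",
    "mutate",
    "generation_update",
    "agent_rng",
]

ROULETTE_EPS = 1e-6


@dataclass(frozen=True)
class EvolutionParams:
    """Evolutionary-computation parameters.

    Pc is the crossover rate, Pm the per-locus mutation rate and max_g the
    number of generations per experiment.
    """

    Pc: float = 0.7
    Pm: float = 0.01
    max_g: int = 100
    selection: str = "roulette"  # or "tournament"
    tournament_k: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.Pc <= 1.0:
            raise ValueError(f"crossover rate Pc must be in [0, 1], got {self.Pc}")
        if not 0.0 <= self.Pm <= 1.0:
            raise ValueError(f"mutation rate Pm must be in [0, 1], got {self.Pm}")
        if self.max_g < 1:
            raise ValueError(f"max_g must be >= 1, got {self.max_g}")
        if self.selection not in ("roulette", "tournament"):
            raise ValueError(
                f"selection must be 'roulette' or 'tournament', got {self.selection!r}"
            )
        if self.tournament_k < 1:
            raise ValueError(f"tournament_k must be >= 1, got {self.tournament_k}")


def agent_rng(seed: int, generation: int, agent: int) -> np.random.Generator:
    """Independent counter-based substream for one (generation, agent)."""
    return np.random.Generator(
        np.random.Philox(key=[seed, (generation << 32) | agent])
    )


def select_parent(
    agent: int,
    neighborhood: Sequence[int],
    af_table: FitnessTable | Mapping[int, float],
    rng: np.random.Generator,
    selection: str = "roulette",
    tournament_k: int = 3,
) -> int:
    """Draw one parent from neighborhood ∪ {agent}, fitness-weighted.

    Roulette weights are af - min(af) + eps so the least-fit candidate
    retains a vanishing chance and uniform fitness degrades to uniform
    choice; the tournament variant picks the fittest of k uniform draws
    (ties to the lower node id).
    """
    if len(neighborhood) == 0:
        raise ValueError(f"agent {agent} has an empty neighborhood")
    candidates = np.asarray(list(neighborhood) + [agent], dtype=np.int64)
    af = np.array([af_table[int(j)] for j in candidates], dtype=float)
    if selection == "roulette":
        w = af - af.min() + ROULETTE_EPS
        p = w / w.sum()
        return int(candidates[rng.choice(len(candidates), p=p)])
    if selection == "tournament":
        picks = rng.integers(0, len(candidates), size=tournament_k)
        sub_af = af[picks]
        best = picks[np.lexsort((candidates[picks], -sub_af))[0]]
        return int(candidates[best])
    raise ValueError(f"unknown selection scheme {selection!r}")


def crossover_index(ia: int, ib: int, cut: int, length: int = 4) -> int:
    """One-point crossover on canonical indices: a's prefix + b's suffix."""
    if not 1 <= cut <= length - 1:
        raise ValueError(f"cut must be in 1..{length - 1}, got {cut}")
    suffix_bits = length - cut
    mask_lo = (1 << suffix_bits) - 1
    return (ia & ~mask_lo) | (ib & mask_lo)


def crossover(
    a: Strategy, b: Strategy, Pc: float, rng: np.random.Generator
) -> Strategy:
    """With probability Pc, one-point crossover of a and b; else a unchanged."""
    if a.length != b.length:
        raise ValueError(
            f"cannot cross strategies of different length: {a.length} vs {b.length}"
        )
    if rng.random() >= Pc:
        return a
    cut = int(rng.integers(1, a.length))
    return Strategy.from_index(
        crossover_index(a.index, b.index, cut, a.length), memory=a.memory
    )


def mutate_index(index: int, flips: np.ndarray, length: int = 4) -> int:
    """Flip the loci marked in the boolean array ``flips`` (MSB first)."""
    mask = 0
    for k, f in enumerate(flips):
        if f:
            mask |= 1 << (length - 1 - k)
    return index ^ mask


def mutate(s: Strategy, Pm: float, rng: np.random.Generator) -> Strategy:
    """Flip each locus independently with probability Pm."""
    flips = rng.random(s.length) < Pm
    if not flips.any():
        return s
    return Strategy.from_index(mutate_index(s.index, flips, s.length), memory=s.memory)


def generation_update(
    net: SocialNetwork,
    strategies: np.ndarray,
    fitness: FitnessTable,
    params: EvolutionParams,
    srac_set: np.ndarray,
    report: ReputationReport | None,
    seed: int,
    generation: int,
    policy: PolicyTable = DEFAULT_POLICY,
    srac_mode: str = "replace_ga",
    strategy_length: int = 4,
) -> np.ndarray:
    """Compute every agent's next strategy synchronously.

    Non-SRAC agents update by select/crossover/mutate; SRAC agents apply
    the reputation-driven self-adjustment, which by default replaces the
    genetic update for them (``srac_mode="replace_ga"``); with
    ``"after_ga"`` a SRAC agent first evolves genetically and the
    self-adjustment then overrides the result whenever its cell's action
    prescribes a change.
    """
    if srac_mode not in ("replace_ga", "after_ga"):
        raise ValueError(f"srac_mode must be 'replace_ga' or 'after_ga', got {srac_mode!r}")
    strategies = np.asarray(strategies)
    v = net.v
    if np.any(srac_set) and report is None:
        raise ValueError("a reputation report is required when SRAC agents exist")
    new = np.empty(v, dtype=np.int64)
    length = strategy_length
    for i in range(v):
        rng = agent_rng(seed, generation, i)
        nb = net.neighbors(i)
        is_srac = bool(srac_set[i])
        if not is_srac or srac_mode == "after_ga":
            p1 = select_parent(i, nb, fitness, rng, params.selection,
                               params.tournament_k)
            p2 = select_parent(i, nb, fitness, rng, params.selection,
                               params.tournament_k)
            child = int(strategies[p1])
            if rng.random() < params.Pc:
                cut = int(rng.integers(1, length))
                child = crossover_index(child, int(strategies[p2]), cut, length)
            flips = rng.random(length) < params.Pm
            if flips.any():
                child = mutate_index(child, flips, length)
            new[i] = child
        if is_srac:
            cell = classify(i, report, policy)
            adjusted = adjust_strategy(i, cell, nb, report, strategies, rng)
            if srac_mode == "replace_ga":
                new[i] = adjusted
            elif adjusted != int(strategies[i]):
                # self-adjustment overrides the genetic child
                new[i] = adjusted
    return new
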