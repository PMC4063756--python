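"""IPD match engine: payoffs, q-round matches, and per-generation fitness.

Matches between memory-1 deterministic strategies are fully deterministic:
both players start with the memory state CC (so every strategy's first move
is its S_cc entry, which makes tit-for-tat open with cooperation), and each
round updates both memories with the joint outcome.  The joint-state map is
a deterministic function on four states, so every match enters a cycle of
length at most 4 after a transient of at most 4 rounds;
:func:`cycle_average_payoff` exploits this to give the exact long-run
per-round payoff, which serves as an analytic cross-check of the
round-by-round engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SocialNetwork
from .strategy import Strategy

__all__ = [
    "PayoffMatrix",
    "MatchResult",
    "FitnessTable",
    "play_round",
    "play_match",
    "cycle_average_payoff",
    "compute_fitness",
    "MatchTable",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """The four prisoner's-dilemma payoffs.

    R rewards mutual cooperation, T is the temptation to defect against a
    cooperator, S the sucker's payoff and P the punishment for mutual
    defection.  A dilemma requires T > R > P > S (defection dominates a
    single round) and 2R > T + S (alternating betrayal pays less than
    sustained cooperation); violating matrices are rejected.
    """

    R: float = 3.0
    T: float = 5.0
    S: float = 0.0
    P: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"not a prisoner's dilemma: requires T > R > P > S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if not (2 * self.R > self.T + self.S):
            raise ValueError(
                f"not a prisoner's dilemma: requires 2R > T + S, got "
                f"2R={2 * self.R}, T+S={self.T + self.S}"
            )

    def payoff_pair(self, move_a: int, move_b: int) -> tuple[float, float]:
        """Payoffs (A, B) for one round; moves are 0 (C) / 1 (D)."""
        if move_a == 0:
            return (self.R, self.R) if move_b == 0 else (self.S, self.T)
        return (self.T, self.S) if move_b == 0 else (self.P, self.P)


DEFAULT_PAYOFFS = PayoffMatrix()


@dataclass(frozen=True)
class MatchResult:
    """Accumulated outcome of one q-round match."""

    total_a: float
    total_b: float
    coop_a: int
    coop_b: int
    rounds: int


def play_round(move_a, move_b, pm: PayoffMatrix = DEFAULT_PAYOFFS) -> tuple[float, float]:
    """Payoffs (A's first) for a single simultaneous round."""
    return pm.payoff_pair(int(move_a), int(move_b))


def _joint_moves(strat_a: Strategy, strat_b: Strategy, state: int) -> tuple[int, int]:
    """Next moves from the joint state (A's move, B's move of last round)."""
    a_move = int(strat_a.responses[state])
    # B sees the mirrored state: own move is the low... B's own move is the
    # second component, so swap the two bits.
    b_state = ((state & 1) << 1) | (state >> 1)
    b_move = int(strat_b.responses[b_state])
    return a_move, b_move


def play_match(
    strat_a: Strategy,
    strat_b: Strategy,
    q: int,
    pm: PayoffMatrix = DEFAULT_PAYOFFS,
) -> MatchResult:
    """Play ``q`` rounds between two memory-1 strategies.

    Both players start remembering CC.  Entirely deterministic.
    """
    if q < 1:
        raise ValueError(f"number of rounds q must be >= 1, got {q}")
    state = 0  # CC
    total_a = total_b = 0.0
    coop_a = coop_b = 0
    for _ in range(q):
        a, b = _joint_moves(strat_a, strat_b, state)
        pa, pb = pm.payoff_pair(a, b)
        total_a += pa
        total_b += pb
        coop_a += 1 - a
        coop_b += 1 - b
        state = (a << 1) | b
    return MatchResult(total_a, total_b, coop_a, coop_b, q)


def cycle_average_payoff(
    strat_a: Strategy,
    strat_b: Strategy,
    pm: PayoffMatrix = DEFAULT_PAYOFFS,
) -> tuple[float, float]:
    """Exact long-run per-round average payoff for an ordered strategy pair.

    The joint-state trajectory (starting from CC) is followed until a state
    repeats; payoffs are averaged over the resulting cycle.  Transient and
    cycle each have length <= 4, so this terminates within 5 steps.
    """
    state = 0
    seen: dict[int, int] = {}
    states: list[int] = []
    while state not in seen:
        seen[state] = len(states)
        states.append(state)
        a, b = _joint_moves(strat_a, strat_b, state)
        state = (a << 1) | b
    cycle = states[seen[state]:]
    pa_sum = pb_sum = 0.0
    for s in cycle:
        a, b = _joint_moves(strat_a, strat_b, s)
        pa, pb = pm.payoff_pair(a, b)
        pa_sum += pa
        pb_sum += pb
    n = len(cycle)
    return pa_sum / n, pb_sum / n


class MatchTable:
    """Precomputed 16x16 match outcomes for a fixed (q, payoff matrix).

    Because matches are deterministic, a generation's ~10,000 dyadic matches
    reduce to table lookups over ordered strategy-index pairs.
    """

    def __init__(self, q: int, pm: PayoffMatrix = DEFAULT_PAYOFFS):
        if q < 1:
            raise ValueError(f"number of rounds q must be >= 1, got {q}")
        self.q = q
        self.pm = pm
        from .strategy import ALL_MEMORY_ONE

        self.total_a = np.empty((16, 16))
        self.total_b = np.empty((16, 16))
        self.coop_a = np.empty((16, 16), dtype=np.int64)
        self.coop_b = np.empty((16, 16), dtype=np.int64)
        for i, sa in enumerate(ALL_MEMORY_ONE):
            for j, sb in enumerate(ALL_MEMORY_ONE):
                r = play_match(sa, sb, q, pm)
                self.total_a[i, j] = r.total_a
                self.total_b[i, j] = r.total_b
                self.coop_a[i, j] = r.coop_a
                self.coop_b[i, j] = r.coop_b


@dataclass
class FitnessTable:
    """Per-agent fitness plus the dyadic cooperation counts that produced it.

    ``af[i]`` is agent i's mean per-round payoff over all matches it played
    this generation (its fitness).  The directed arrays record, for each
    ordered neighbor pair, how many cooperative moves the opponent made in
    its match against the observer — the raw material of reputation scoring.
    """

    af: np.ndarray
    observer: np.ndarray = field(repr=False)
    opponent: np.ndarray = field(repr=False)
    coop_by_opponent: np.ndarray = field(repr=False)

    def __getitem__(self, agent: int) -> float:
        return float(self.af[agent])

    def witnessed_coop(self, observer: int) -> dict[int, int]:
        """Cooperation counts observer saw from each of its opponents."""
        mask = self.observer == observer
        return {
            int(o): int(c)
            for o, c in zip(self.opponent[mask], self.coop_by_opponent[mask])
        }


def compute_fitness(
    net: SocialNetwork,
    strategies: np.ndarray,
    q: int,
    pm: PayoffMatrix = DEFAULT_PAYOFFS,
    table: MatchTable | None = None,
) -> FitnessTable:
    """Play every edge's q-round match once and average payoffs per agent.

    ``strategies`` is an integer array of canonical strategy indices, one
    per node.  Each edge is played once with both endpoints credited;
    ``af[i]`` is agent i's total payoff divided by (degree_i * q).
    """
    strategies = np.asarray(strategies)
    if strategies.shape != (net.v,):
        raise ValueError(
            f"need one strategy per node: expected shape ({net.v},), "
            f"got {strategies.shape}"
        )
    deg = net.degrees()
    if np.any(deg == 0):
        bad = int(np.flatnonzero(deg == 0)[0])
        raise ValueError(f"agent {bad} has no opponents; fitness is undefined")
    if table is None or table.q != q or table.pm != pm:
        table = MatchTable(q, pm)

    u, w = net.edges[:, 0], net.edges[:, 1]
    su, sw = strategies[u], strategies[w]
    totals = np.zeros(net.v)
    np.add.at(totals, u, table.total_a[su, sw])
    np.add.at(totals, w, table.total_b[su, sw])
    af = totals / (deg * q)

    # directed dyads: each edge contributes both (u sees w) and (w sees u)
    observer = np.concatenate([u, w])
    opponent = np.concatenate([w, u])
    coop = np.concatenate([table.coop_b[su, sw], table.coop_a[su, sw]])
    return FitnessTable(af=af, observer=observer, opponent=opponent,
                        coop_by_opponent=coop)
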