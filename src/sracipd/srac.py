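"""Self-reputation awareness component (SRAC).

An SRAC agent crosses its relative-fitness level with its self-reputation
level, giving nine interaction cells, and each cell prescribes an action.
The motivating cell is high fitness / low reputation: a "villain" profile
(typically always-defect) that prospers at its neighbors' expense; such an
agent must learn that this damages its reputation and imitate a socially
approved neighbor instead.  The default table generalizes that intent:

* low self-reputation (any fitness) — imitate the most reputable neighbor;
* low fitness with medium/high reputation — imitate the neighbor that best
  combines fitness and reputation;
* otherwise — keep the current strategy (no discrepancy to reduce).

An ``explore`` action (copy a uniformly random non-low-reputation
neighbor) is available for custom tables.  Under every action an SRAC
agent never adopts the strategy of a neighbor whose self-reputation level
is low; if no acceptable model exists the agent keeps its strategy.  The
per-cell prescriptions beyond the villain cell are the package's own
reconstruction and are configurable (see docs/methods.md).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .reputation import Level, ReputationReport

__all__ = [
    "Action",
    "InteractionCell",
    "PolicyTable",
    "DEFAULT_POLICY",
    "classify",
    "adjust_strategy",
]


class Action(enum.Enum):
    """What an SRAC agent does in a given interaction cell."""

    KEEP = "keep"
    IMITATE_REPUTABLE = "imitate_reputable"
    IMITATE_FIT_AND_REPUTABLE = "imitate_fit_and_reputable"
    EXPLORE = "explore"


@dataclass(frozen=True)
class InteractionCell:
    """One of the nine (fitness level x self-reputation level) cells."""

    fitness_level: Level
    reputation_level: Level
    action: Action


class PolicyTable:
    """Mapping from the nine (fitness, reputation) cells to actions."""

    def __init__(self, table: Mapping[tuple[Level, Level], Action]):
        cells = {(f, r) for f in Level for r in Level}
        missing = cells - set(table)
        if missing:
            raise ValueError(f"policy table missing cells: {sorted(missing)}")
        extra = set(table) - cells
        if extra:
            raise ValueError(f"policy table has unknown cells: {sorted(extra)}")
        self._table = dict(table)

    def __getitem__(self, key: tuple[Level, Level]) -> Action:
        return self._table[key]

    def cell(self, fitness_level: Level, reputation_level: Level) -> InteractionCell:
        return InteractionCell(fitness_level, reputation_level,
                               self._table[(fitness_level, reputation_level)])

    def to_dict(self) -> dict[str, str]:
        """Serializable {"fitness,reputation": action} form for configs."""
        return {
            f"{f.name.lower()},{r.name.lower()}": a.value
            for (f, r), a in sorted(self._table.items())
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "PolicyTable":
        table = {}
        for key, action in d.items():
            f_name, r_name = (part.strip().upper() for part in key.split(","))
            table[(Level[f_name], Level[r_name])] = Action(action)
        return cls(table)


def _default_action(fit: Level, rep: Level) -> Action:
    if rep == Level.LOW:
        return Action.IMITATE_REPUTABLE
    if fit == Level.LOW:  # rep medium or high
        return Action.IMITATE_FIT_AND_REPUTABLE
    return Action.KEEP


DEFAULT_POLICY = PolicyTable(
    {(f, r): _default_action(f, r) for f in Level for r in Level}
)


def classify(
    agent: int, report: ReputationReport, policy: PolicyTable = DEFAULT_POLICY
) -> InteractionCell:
    """The interaction cell an agent occupies this generation."""
    if not 0 <= agent < len(report.self_rep_raw):
        raise KeyError(f"agent {agent} not present in the reputation report")
    fit, rep = report.level_of(agent)
    return policy.cell(fit, rep)


def adjust_strategy(
    agent: int,
    cell: InteractionCell,
    neighborhood: Sequence[int],
    report: ReputationReport,
    strategies: Mapping[int, int] | np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Next-generation strategy index chosen by an SRAC agent.

    Candidates for imitation are the neighbors whose self-reputation level
    is not low; if none exist the agent keeps its strategy (fallback for
    every action).  Ties in the imitation criteria break by higher fitness
    then by lower node id, keeping the policy deterministic given the
    report and the seed.
    """
    if len(neighborhood) == 0:
        raise ValueError(f"agent {agent} has an empty neighborhood")
    own = int(strategies[agent])
    if cell.action == Action.KEEP:
        return own

    nb = np.asarray(neighborhood, dtype=np.int64)
    candidates = nb[report.self_rep_level[nb] != int(Level.LOW)]
    if len(candidates) == 0:
        return own

    if cell.action == Action.IMITATE_REPUTABLE:
        # lexicographic argmax: self-reputation, then af, then lower id
        key = np.stack([report.self_rep_raw[candidates],
                        report.af[candidates],
                        -candidates.astype(float)])
        best = candidates[np.lexsort(key[::-1])[-1]]
        return int(strategies[int(best)])

    if cell.action == Action.IMITATE_FIT_AND_REPUTABLE:
        score = report.rel_fit_raw[candidates] + report.self_rep_raw[candidates]
        key = np.stack([score, -candidates.astype(float)])
        best = candidates[np.lexsort(key[::-1])[-1]]
        return int(strategies[int(best)])

    if cell.action == Action.EXPLORE:
        pick = candidates[int(rng.integers(0, len(candidates)))]
        return int(strategies[int(pick)])

    raise ValueError(f"unknown action {cell.action!r}")
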