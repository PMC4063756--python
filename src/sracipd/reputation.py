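"""Relative reputation evaluation.

At the end of each generation every agent scores each of its opponents by
how cooperative that opponent was, standardized within the observer's own
opponent list: z_j = (coop_j - mean) / sd, using the population standard
deviation over the observer's opponents (z = 0 everywhere when sd = 0).
Reputation is therefore purely local and relative — an agent is reputable
insofar as it cooperates more than the other agents its observer meets.

Two per-agent summaries feed the self-awareness policy:

* self-reputation — the mean of the z-scores an agent received from its
  opponents, i.e. how cooperative its neighborhood considers it;
* relative fitness — the z-score of the agent's fitness within the set
  {its neighbors} ∪ {itself}.

Both raw values are discretized into high / medium / low by a symmetric
threshold (default ±0.5 z-units, boundary values assigned to the extreme
category).  Cooperation counts are dyadic by default (the moves opponent j
made in its match against observer i — what i actually witnessed); a
global variant (j's cooperative moves over all its matches) is available
behind a switch.

The discretization threshold and the aggregation conventions here are the
package's own documented choices; see docs/methods.md.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .game import FitnessTable
from .network import SocialNetwork

__all__ = [
    "Level",
    "ReputationReport",
    "score_opponents",
    "categorize_level",
    "self_reputation",
    "relative_fitness",
    "build_report",
    "DEFAULT_LEVEL_THRESHOLD",
]

DEFAULT_LEVEL_THRESHOLD = 0.5


class Level(enum.IntEnum):
    """Discrete high/medium/low category of a standardized score."""

    LOW = -1
    MEDIUM = 0
    HIGH = 1

    def __str__(self) -> str:
        return self.name.lower()


def categorize_level(z: float, threshold: float = DEFAULT_LEVEL_THRESHOLD) -> Level:
    """Map a z-score to high (z >= +t), low (z <= -t) or medium."""
    if threshold <= 0:
        raise ValueError(f"level threshold must be positive, got {threshold}")
    if z >= threshold:
        return Level.HIGH
    if z <= -threshold:
        return Level.LOW
    return Level.MEDIUM


def _zscores(values: np.ndarray) -> np.ndarray:
    """Population z-scores; all-zero when the spread is zero."""
    values = np.asarray(values, dtype=float)
    sd = values.std()  # population sd
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def score_opponents(
    observer: int, coop_counts: Mapping[int, int]
) -> dict[int, float]:
    """Relative reputation scores one observer gives its opponents.

    ``coop_counts`` maps each opponent to the number of cooperative moves
    the observer witnessed from it this generation.
    """
    if not coop_counts:
        raise ValueError(f"observer {observer} has no opponents to score")
    opponents = list(coop_counts)
    z = _zscores(np.array([coop_counts[o] for o in opponents], dtype=float))
    return {o: float(s) for o, s in zip(opponents, z)}


def self_reputation(
    agent: int,
    received_scores: Sequence[float],
    threshold: float = DEFAULT_LEVEL_THRESHOLD,
) -> Level:
    """Self-reputation level: mean of the scores the agent received."""
    if len(received_scores) == 0:
        raise ValueError(f"agent {agent} received no reputation scores")
    return categorize_level(float(np.mean(received_scores)), threshold)


def relative_fitness(
    agent: int,
    af_table: FitnessTable | Mapping[int, float],
    neighborhood: Sequence[int],
    threshold: float = DEFAULT_LEVEL_THRESHOLD,
) -> Level:
    """Fitness level of ``agent`` relative to its neighborhood ∪ itself."""
    if len(neighborhood) == 0:
        raise ValueError(f"agent {agent} has an empty neighborhood")
    context = list(neighborhood) + [agent]
    af = np.array([af_table[j] for j in context], dtype=float)
    z = _zscores(af)
    return categorize_level(float(z[-1]), threshold)


@dataclass
class ReputationReport:
    """Population-wide reputation summary for one generation.

    Directed dyad arrays (``observer``, ``opponent``, ``coop``, ``z``) hold
    one entry per ordered neighbor pair; per-agent arrays hold the raw and
    discretized self-reputation and relative-fitness summaries plus the
    fitness values themselves (used for tie-breaking by the policy).
    """

    observer: np.ndarray
    opponent: np.ndarray
    coop: np.ndarray
    z: np.ndarray
    af: np.ndarray
    self_rep_raw: np.ndarray
    self_rep_level: np.ndarray  # int8 Level values
    rel_fit_raw: np.ndarray
    rel_fit_level: np.ndarray
    threshold: float

    def level_of(self, agent: int) -> tuple[Level, Level]:
        """(relative fitness level, self-reputation level) of an agent."""
        return (Level(int(self.rel_fit_level[agent])),
                Level(int(self.self_rep_level[agent])))


def _categorize_array(raw: np.ndarray, threshold: float) -> np.ndarray:
    levels = np.zeros(len(raw), dtype=np.int8)
    levels[raw >= threshold] = int(Level.HIGH)
    levels[raw <= -threshold] = int(Level.LOW)
    return levels


def build_report(
    net: SocialNetwork,
    fitness: FitnessTable,
    threshold: float = DEFAULT_LEVEL_THRESHOLD,
    coop_scope: str = "dyadic",
) -> ReputationReport:
    """Compute the full reputation report for one generation (vectorized).

    ``coop_scope`` selects what an observer's score of opponent j is based
    on: ``"dyadic"`` (default) uses only the cooperative moves j made
    against that observer; ``"global"`` uses j's total cooperative moves
    over all its matches this generation.
    """
    if threshold <= 0:
        raise ValueError(f"level threshold must be positive, got {threshold}")
    if coop_scope not in ("dyadic", "global"):
        raise ValueError(f"coop_scope must be 'dyadic' or 'global', got {coop_scope!r}")
    v = net.v
    obs = fitness.observer
    opp = fitness.opponent
    deg = np.bincount(obs, minlength=v).astype(float)
    if np.any(deg == 0):
        bad = int(np.flatnonzero(deg == 0)[0])
        raise ValueError(f"agent {bad} has no opponents; reputation is undefined")

    if coop_scope == "dyadic":
        coop = fitness.coop_by_opponent.astype(float)
    else:
        total_coop = np.bincount(opp, weights=fitness.coop_by_opponent, minlength=v)
        coop = total_coop[opp]

    # per-observer mean and population sd of opponent cooperation counts
    mean = np.bincount(obs, weights=coop, minlength=v) / deg
    var = np.bincount(obs, weights=coop**2, minlength=v) / deg - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd[obs] > 0, (coop - mean[obs]) / sd[obs], 0.0)

    # self-reputation: mean of scores received (indexed by the scored agent)
    received = np.bincount(opp, weights=z, minlength=v)
    self_rep_raw = received / np.bincount(opp, minlength=v)

    # relative fitness within neighborhood ∪ self
    af = fitness.af
    n_ctx = deg + 1.0
    ctx_sum = np.bincount(obs, weights=af[opp], minlength=v) + af
    ctx_mean = ctx_sum / n_ctx
    ctx_sq = np.bincount(obs, weights=af[opp] ** 2, minlength=v) + af**2
    ctx_var = ctx_sq / n_ctx - ctx_mean**2
    ctx_sd = np.sqrt(np.maximum(ctx_var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_fit_raw = np.where(ctx_sd > 0, (af - ctx_mean) / ctx_sd, 0.0)

    return ReputationReport(
        observer=obs,
        opponent=opp,
        coop=coop,
        z=z,
        af=af,
        self_rep_raw=self_rep_raw,
        self_rep_level=_categorize_array(self_rep_raw, threshold),
        rel_fit_raw=rel_fit_raw,
        rel_fit_level=_categorize_array(rel_fit_raw, threshold),
        threshold=threshold,
    )
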