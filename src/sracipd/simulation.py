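"""Simulation orchestrator: the four-step generational flow.

A run (1) resets parameters, (2) builds the social interaction network,
(3) assigns every agent a random strategy and, once, its SRAC membership,
then (4) loops for max_g generations: play all q-round matches along the
edges, compute fitness, compute the reputation report, record metrics and
snapshots, and update strategies synchronously (genetic algorithm for
ordinary agents, reputation-driven self-adjustment for SRAC agents).
Everything is reproducible bit-for-bit from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .evolution import EvolutionParams, generation_update
from .game import MatchTable, PayoffMatrix, compute_fitness
from .network import SocialNetwork, build_lattice, rewire_to_small_world
from .reputation import DEFAULT_LEVEL_THRESHOLD, build_report
from .srac import DEFAULT_POLICY, PolicyTable
from .strategy import Strategy

__all__ = [
    "SimulationConfig",
    "GenerationMetrics",
    "GridSnapshot",
    "SimulationResult",
    "EnsembleResult",
    "StageReport",
    "run",
    "run_ensemble",
    "stage_detector",
]

N_STRATEGIES = 16
DEFAULT_SNAPSHOT_GENERATIONS = (0, 3, 10, 20, 21, 40, 99)


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set of one simulation run.

    Defaults are the simulator's standard demonstration settings:
    q=100 rounds per opponent, memory capacity c=1 (strategy length l=4),
    a 50x50 Moore/periodic lattice (v=2500, e=10000), crossover rate
    Pc=0.7, mutation rate Pm=0.01, max_g=100 generations, and edge
    rewiring probability rho=0.01 when the small-world type is selected.
    """

    q: int = 100
    c: int = 1
    W: int = 50
    H: int = 50
    pattern: str = "moore"
    net_type: str = "cellular_automata"
    rho: float = 0.01
    Pc: float = 0.7
    Pm: float = 0.01
    max_g: int = 100
    srac_fraction: float = 0.0
    srac_mode: str = "replace_ga"
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)
    seed: int = 0
    level_threshold: float = DEFAULT_LEVEL_THRESHOLD
    selection: str = "roulette"
    tournament_k: int = 3
    coop_scope: str = "dyadic"
    srac_policy: PolicyTable = field(default=DEFAULT_POLICY, compare=False)
    init_strategy: int | str | None = None
    snapshot_generations: tuple[int, ...] = DEFAULT_SNAPSHOT_GENERATIONS

    @property
    def l(self) -> int:  # noqa: E743 - the field's standard symbol
        """Strategy length l = 4**c."""
        return 4**self.c

    @property
    def v(self) -> int:
        return self.W * self.H

    def validate(self) -> "SimulationConfig":
        errors = []
        if self.q < 1:
            errors.append(f"q: rounds per opponent must be >= 1, got {self.q}")
        if self.c != 1:
            errors.append(f"c: only memory capacity 1 is supported, got {self.c}")
        if self.W < 5 or self.H < 5:
            errors.append(f"W,H: lattice must be at least 5x5, got {self.W}x{self.H}")
        if self.pattern != "moore":
            errors.append(f"pattern: only 'moore' is implemented, got {self.pattern!r}")
        if self.net_type not in ("cellular_automata", "small_world"):
            errors.append(
                "net_type: must be 'cellular_automata' or 'small_world', "
                f"got {self.net_type!r}"
            )
        if not 0.0 <= self.rho <= 1.0:
            errors.append(f"rho: rewiring probability must be in [0,1], got {self.rho}")
        if not 0.0 <= self.Pc <= 1.0:
            errors.append(f"Pc: crossover rate must be in [0,1], got {self.Pc}")
        if not 0.0 <= self.Pm <= 1.0:
            errors.append(f"Pm: mutation rate must be in [0,1], got {self.Pm}")
        if self.max_g < 1:
            errors.append(f"max_g: must be >= 1, got {self.max_g}")
        if not 0.0 <= self.srac_fraction <= 1.0:
            errors.append(
                f"srac_fraction: must be in [0,1], got {self.srac_fraction}"
            )
        if self.srac_mode not in ("replace_ga", "after_ga"):
            errors.append(f"srac_mode: unknown mode {self.srac_mode!r}")
        if self.level_threshold <= 0:
            errors.append(
                f"level_threshold: must be positive, got {self.level_threshold}"
            )
        if self.selection not in ("roulette", "tournament"):
            errors.append(f"selection: unknown scheme {self.selection!r}")
        if self.coop_scope not in ("dyadic", "global"):
            errors.append(f"coop_scope: must be 'dyadic' or 'global', got {self.coop_scope!r}")
        if not 0 <= self.seed < 2**63:
            errors.append(f"seed: must be a non-negative 63-bit integer, got {self.seed}")
        if self.init_strategy is not None:
            try:
                self.resolved_init_strategy()
            except (ValueError, TypeError) as exc:
                errors.append(f"init_strategy: {exc}")
        if errors:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
        return self

    def resolved_init_strategy(self) -> int | None:
        """init_strategy as a canonical index (accepts "CDCD"-style strings)."""
        if self.init_strategy is None:
            return None
        if isinstance(self.init_strategy, str):
            return Strategy.from_string(self.init_strategy).index
        return Strategy.from_index(int(self.init_strategy), memory=self.c).index

    def evolution_params(self) -> EvolutionParams:
        return EvolutionParams(
            Pc=self.Pc, Pm=self.Pm, max_g=self.max_g,
            selection=self.selection, tournament_k=self.tournament_k,
        )

    def to_dict(self) -> dict:
        pm = self.payoffs
        return {
            "q": self.q, "c": self.c, "l": self.l, "W": self.W, "H": self.H,
            "v": self.v, "e": 4 * self.v,
            "pattern": self.pattern, "net_type": self.net_type, "rho": self.rho,
            "Pc": self.Pc, "Pm": self.Pm, "max_g": self.max_g,
            "srac_fraction": self.srac_fraction, "srac_mode": self.srac_mode,
            "payoffs": {"R": pm.R, "T": pm.T, "S": pm.S, "P": pm.P},
            "seed": self.seed, "level_threshold": self.level_threshold,
            "selection": self.selection, "tournament_k": self.tournament_k,
            "coop_scope": self.coop_scope,
            "srac_policy": self.srac_policy.to_dict(),
            "init_strategy": self.init_strategy,
            "snapshot_generations": list(self.snapshot_generations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for derived in ("l", "v", "e"):
            d.pop(derived, None)
        if "payoffs" in d and isinstance(d["payoffs"], dict):
            d["payoffs"] = PayoffMatrix(**d["payoffs"])
        if "srac_policy" in d and isinstance(d["srac_policy"], dict):
            d["srac_policy"] = PolicyTable.from_dict(d["srac_policy"])
        if "snapshot_generations" in d:
            d["snapshot_generations"] = tuple(d["snapshot_generations"])
        if "srac_fraction" in d and isinstance(d["srac_fraction"], str):
            d["srac_fraction"] = parse_fraction(d["srac_fraction"])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d).validate()


def parse_fraction(text: str | float) -> float:
    """Parse a fraction given as a decimal ("0.1") or percentage ("10%")."""
    if isinstance(text, (int, float)):
        return float(text)
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


@dataclass(frozen=True)
class GenerationMetrics:
    """Per-generation population summary."""

    generation: int
    strategy_counts: np.ndarray  # 16-vector
    mean_payoff: float
    per_strategy_mean_payoff: np.ndarray  # 16-vector, NaN where absent
    srac_counts_by_strategy: np.ndarray  # 16-vector

    def count(self, strategy_index: int) -> int:
        return int(self.strategy_counts[strategy_index])


@dataclass(frozen=True)
class GridSnapshot:
    """Spatial distribution of strategies at one generation (H x W)."""

    generation: int
    matrix: np.ndarray


@dataclass
class SimulationResult:
    """Everything a single run produced."""

    config: SimulationConfig
    metrics: list[GenerationMetrics]
    snapshots: list[GridSnapshot]
    network: SocialNetwork
    srac_set: np.ndarray
    final_strategies: np.ndarray  # state at the last played generation

    def mean_payoff_series(self) -> np.ndarray:
        return np.array([m.mean_payoff for m in self.metrics])

    def counts_matrix(self) -> np.ndarray:
        """(max_g, 16) array of strategy counts."""
        return np.stack([m.strategy_counts for m in self.metrics])


def _record_metrics(
    g: int, strategies: np.ndarray, af: np.ndarray, srac_set: np.ndarray
) -> GenerationMetrics:
    counts = np.bincount(strategies, minlength=N_STRATEGIES)
    per_strategy = np.full(N_STRATEGIES, np.nan)
    for s in np.flatnonzero(counts):
        per_strategy[s] = af[strategies == s].mean()
    srac_counts = np.bincount(strategies[srac_set], minlength=N_STRATEGIES)
    return GenerationMetrics(
        generation=g,
        strategy_counts=counts,
        mean_payoff=float(af.mean()),
        per_strategy_mean_payoff=per_strategy,
        srac_counts_by_strategy=srac_counts,
    )


def build_network(config: SimulationConfig) -> SocialNetwork:
    """Build the configured social interaction network (seeded)."""
    lattice = build_lattice(config.W, config.H, config.pattern)
    if config.net_type == "small_world":
        rng = np.random.Generator(np.random.Philox(key=[config.seed, 1]))
        return rewire_to_small_world(lattice, config.rho, rng)
    return lattice


def run(config: SimulationConfig) -> SimulationResult:
    """Execute one full simulation run."""
    config.validate()
    net = build_network(config)
    v = net.v

    init_rng = np.random.Generator(np.random.Philox(key=[config.seed, 0]))
    forced = config.resolved_init_strategy()
    if forced is None:
        strategies = init_rng.integers(0, 2**config.l, size=v)
    else:
        strategies = np.full(v, forced, dtype=np.int64)
    n_srac = int(round(config.srac_fraction * v))
    srac_set = np.zeros(v, dtype=bool)
    if n_srac > 0:
        srac_set[init_rng.choice(v, size=n_srac, replace=False)] = True

    table = MatchTable(config.q, config.payoffs)
    params = config.evolution_params()
    snapshot_at = set(config.snapshot_generations)
    metrics: list[GenerationMetrics] = []
    snapshots: list[GridSnapshot] = []

    last_played = strategies
    for g in range(config.max_g):
        fitness = compute_fitness(net, strategies, config.q, config.payoffs, table)
        report = build_report(net, fitness, config.level_threshold,
                              config.coop_scope)
        metrics.append(_record_metrics(g, strategies, fitness.af, srac_set))
        if g in snapshot_at:
            snapshots.append(GridSnapshot(
                generation=g,
                matrix=strategies.reshape(config.H, config.W).copy(),
            ))
        last_played = strategies
        strategies = generation_update(
            net, strategies, fitness, params, srac_set, report,
            seed=config.seed, generation=g, policy=config.srac_policy,
            srac_mode=config.srac_mode, strategy_length=config.l,
        )
    return SimulationResult(config=config, metrics=metrics, snapshots=snapshots,
                            network=net, srac_set=srac_set,
                            final_strategies=last_played)


@dataclass
class EnsembleResult:
    """Across-seed aggregation of per-generation metrics."""

    config: SimulationConfig
    seeds: list[int]
    runs: list[SimulationResult]
    mean_payoff: np.ndarray  # (max_g,) mean over seeds
    sd_payoff: np.ndarray
    mean_counts: np.ndarray  # (max_g, 16)
    sd_counts: np.ndarray


def run_ensemble(
    config: SimulationConfig,
    n_seeds: int,
    keep_runs: bool = True,
) -> EnsembleResult:
    """Replicate a run over seeds config.seed, config.seed+1, ...

    Aggregates the per-generation mean payoff and strategy counts as mean
    and (population) standard deviation across seeds.
    """
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    seeds = [config.seed + k for k in range(n_seeds)]
    runs, payoffs, counts = [], [], []
    for s in seeds:
        res = run(replace(config, seed=s))
        payoffs.append(res.mean_payoff_series())
        counts.append(res.counts_matrix())
        if keep_runs:
            runs.append(res)
    payoffs = np.stack(payoffs)
    counts = np.stack(counts).astype(float)
    return EnsembleResult(
        config=config, seeds=seeds, runs=runs,
        mean_payoff=payoffs.mean(axis=0), sd_payoff=payoffs.std(axis=0),
        mean_counts=counts.mean(axis=0), sd_counts=counts.std(axis=0),
    )


@dataclass(frozen=True)
class StageReport:
    """Detected landmarks of the evolutionary dynamics (None = not seen)."""

    peak_scoundrel_generation: int | None
    tft_over_scoundrel_generation: int | None
    wsls_plurality_generation: int | None
    stability_onset_generation: int | None


def stage_detector(
    metrics: Sequence[GenerationMetrics],
    stability_window: int = 10,
    stability_tol: float = 1e-3,
) -> StageReport:
    """Locate the landmark generations of the five-stage dynamics.

    Reports (i) the generation of the scoundrel-count peak (None when the
    count never rises above its initial value), (ii) the first generation
    where tit-for-tat outnumbers scoundrel after the scoundrel surge,
    (iii) the first generation where win-stay/lose-shift is the strict
    plurality strategy, and (iv) the onset of dynamic stability, taken as
    the first generation where the rolling variance of mean payoff over
    ``stability_window`` generations drops below ``stability_tol``.
    """
    if len(metrics) < 40:
        raise ValueError(
            f"stage detection needs at least 40 generations, got {len(metrics)}"
        )
    counts = np.stack([m.strategy_counts for m in metrics])
    payoff = np.array([m.mean_payoff for m in metrics])
    s_count, tft_count, wsls_count = counts[:, 15], counts[:, 5], counts[:, 6]

    peak: int | None = int(np.argmax(s_count))
    if s_count[peak] <= s_count[0]:
        peak = None

    tft_cross: int | None = None
    if peak is not None:
        after = np.flatnonzero(tft_count[peak:] > s_count[peak:])
        if after.size:
            tft_cross = int(peak + after[0])

    wsls_plural: int | None = None
    top = counts.max(axis=1)
    plural = np.flatnonzero(
        (wsls_count == top) & (counts.argmax(axis=1) == 6)
        & ((counts == top[:, None]).sum(axis=1) == 1)
    )
    if plural.size:
        wsls_plural = int(plural[0])

    stability: int | None = None
    w = stability_window
    if len(payoff) >= w:
        roll_var = np.array([payoff[i:i + w].var() for i in range(len(payoff) - w + 1)])
        hits = np.flatnonzero(roll_var < stability_tol)
        if hits.size:
            stability = int(hits[0])

    return StageReport(
        peak_scoundrel_generation=peak,
        tft_over_scoundrel_generation=tft_cross,
        wsls_plurality_generation=wsls_plural,
        stability_onset_generation=stability,
    )
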