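# Methods

`sracipd` simulates an evolving society of agents playing the iterated
prisoner's dilemma (IPD) on a spatial interaction network, with an optional
self-reputation awareness component (SRAC) that lets a fraction of the
agents adjust their strategies toward socially approved neighbors instead
of evolving genetically.  This note records the model, its parameters, the
numerical conventions, and the design choices made where the published
description of the mechanism leaves the details open.

## Game and strategies

Each round, two agents simultaneously cooperate (C) or defect (D) and
receive payoffs from the standard PD matrix (defaults R=3, T=5, S=0, P=1).
Matrices must satisfy T > R > P > S and 2R > T + S; violations are rejected
at configuration load.

Agents use memory-1 deterministic strategies: a fixed response table over
the four joint outcomes of the previous round, ordered CC, CD, DC, DD with
the agent's own move first.  A strategy is named by the integer formed by
its responses as bits (C→0, D→1, CC response most significant), so there
are 16 strategies S_0..S_15, including yes-man (S_0, always cooperate),
tit-for-tat (S_5), win-stay/lose-shift (S_6) and the scoundrel (S_15,
always defect).  The memory state is the *joint* previous outcome, not the
opponent's move alone: that is the only reading under which the S_5 table
behaves as tit-for-tat (its DC entry, "I defected, opponent cooperated →
cooperate", is imitation of the opponent) and S_6 as win-stay/lose-shift.
Generic memory-c tables (length 4^c) are supported but only c=1 is
exercised.

Both players enter round 1 remembering CC, so every strategy's first move
is its CC entry; this reproduces the convention that tit-for-tat always
opens with cooperation, without a special case.  Matches are therefore
fully deterministic, and the joint-state map has a transient and a cycle of
length ≤ 4 each.  `cycle_average_payoff` computes the exact long-run
per-round payoff from that cycle and serves as an analytic cross-check of
the round-by-round engine: the two agree within 4·(T−S)/q for q-round
matches.  Because matches are deterministic, a generation's matches reduce
to lookups in a precomputed 16×16 table of match outcomes — an exact
optimization, not an approximation.

## Networks

The base topology is a W×H lattice where each cell connects to its eight
Moore neighbors with periodic boundaries (a torus): every node has degree
8 and e = 4v.  Node ids are row-major, 0-based.  Lattices smaller than 5×5
are rejected.  The small-world variant visits each lattice edge and, with
probability ρ (default 0.01), keeps one uniformly chosen endpoint and
replaces the other with a uniformly drawn node; draws that would create a
self-loop or duplicate edge are redrawn, so node and edge counts are
conserved exactly and the two network types are directly comparable.
Which endpoint is kept is a uniform coin — the mechanism's published
description says only that one of the two is discarded.

## Generations

One generation consists of: (4a) every edge plays one q-round match
(default q=100) and each agent's fitness af_i is its mean per-round payoff
over all its matches; (4b) reputation evaluation; (4c) synchronous strategy
update — genetic for ordinary agents, self-adjustment for SRAC agents.
Metrics (strategy counts, mean payoff, per-strategy mean payoffs, SRAC
counts) are recorded from the generation's play before the update; grid
snapshots default to generations {0, 3, 10, 20, 21, 40, 99}.

## Reputation (reconstructed conventions)

Each observer scores each opponent by the number of cooperative moves it
witnessed, standardized within its own opponent list:
z = (count − mean)/sd with the population standard deviation; sd = 0 gives
z = 0 for all.  An agent's *self-reputation* raw value is the unweighted
mean of the scores it received; its *relative fitness* raw value is the
z-score of its fitness within {neighbors} ∪ {self}.  Both are discretized
into high (z ≥ +0.5), low (z ≤ −0.5) or medium, with boundary values going
to the extreme category; the threshold is configurable.

The original appendices containing the reputation pseudo-code are not
publicly printed, so several conventions here are this package's
documented reconstruction of the in-text description:

* cooperation counts are **dyadic** (the moves opponent j made against
  observer i — what i actually witnessed); a global variant (j's total
  cooperative moves this generation) is available via `coop_scope`;
* population rather than sample standard deviation, with the sd = 0 case
  mapped to the neutral (medium) category;
* the ±0.5 z-unit level threshold, chosen so that in a standardized
  three-way split the extreme categories require a clearly
  above/below-average score;
* received scores aggregate by unweighted mean.

Reputation is recomputed from scratch each generation; there is no decay
or memory across generations.

## SRAC policy

Crossing the three fitness levels with the three self-reputation levels
gives nine interaction cells.  The published account specifies only the
intent of the high-fitness/low-reputation "villain" cell (an exploitative
agent must learn to imitate socially approved neighbors); the full default
action table is this package's reconstruction and is configurable
(`srac_policy`):

| fitness \ reputation | low                | medium                     | high |
|----------------------|--------------------|----------------------------|------|
| low                  | imitate_reputable  | imitate_fit_and_reputable  | imitate_fit_and_reputable |
| medium               | imitate_reputable  | keep                       | keep |
| high                 | imitate_reputable  | keep                       | keep |

`imitate_reputable` copies the neighbor with the highest self-reputation
raw score (ties: higher fitness, then lower node id);
`imitate_fit_and_reputable` copies the neighbor maximizing the sum of its
relative-fitness and self-reputation raw scores; `explore` (unused in the
default table) copies a uniformly random acceptable neighbor.  Under every
action the candidate set excludes neighbors whose self-reputation level is
low, and the agent keeps its strategy when no acceptable model exists.
This table is the main free parameter affecting quantitative reproduction
of the mixing experiments.

SRAC membership is drawn once at initialization (uniform without
replacement, `srac_fraction` of v agents) and never changes.  By default
SRAC self-adjustment *replaces* the genetic update for SRAC agents
(`srac_mode="replace_ga"`); an `"after_ga"` variant lets the genetic child
be overridden only when the cell prescribes a change.

## Genetic update

Ordinary agents evolve synchronously: two parents are drawn from
{neighbors} ∪ {self} with probability proportional to af − min(af) + ε
(ε = 10⁻⁶), the child is the first parent, replaced with probability
Pc = 0.7 by a one-point crossover (uniform cut in 1..3) of the two
parents, and each of the 4 loci then flips with probability Pm = 0.01.
The selection scheme is not part of the published description; local
fitness-proportional roulette was chosen for consistency with the spatial
clustering the model is meant to exhibit, and a k-tournament alternative
is available (`selection="tournament"`).  Shifting by the minimum makes
uniform-fitness neighborhoods select uniformly while giving strong
selection when payoff spreads are large.

Every (generation, agent) pair draws from its own Philox substream keyed
by the master seed, so the update is independent of agent processing
order and replays are bit-identical.

## Synthetic study conditions

There is no external data: the simulator's initial conditions are the
study conditions.  Defaults are q=100, c=1, l=4, W=H=50 (v=2500,
e=10000), Moore/periodic pattern, Pc=0.7, Pm=0.01, max_g=100, ρ=0.01,
with strategies drawn uniformly over the 16 tables.  The acceptance script
and stochastic tests use scaled conditions (q=20; 30×30 lattices and
15–45 generations for ensemble sweeps; 10–20 seeds), sizes at which the
qualitative regimes — the defection surge, the tit-for-tat recovery, the
slow win-stay/lose-shift growth, and the SRAC mixing effects — are already
stable across seeds.  What passing tests show is that the *mechanisms*
reproduce: the defection surge peaks and is suppressed faster and at lower
amplitude as the SRAC fraction grows, scoundrels vanish within a few
generations at 100% SRAC and never re-emerge (with no mutation acting on
SRAC agents, extinct strategies cannot reappear by imitation), and mean
payoff over the surge window is non-decreasing in the SRAC fraction.
Exact landmark timings (e.g. the generation at which tit-for-tat first
outnumbers the scoundrels) depend on the reconstructed selection scheme
and SRAC table and are therefore checked as orderings and windows, not
point values; with this package's defaults the full dynamics run roughly
2–4× faster in generation count than the published account of the original
simulator, whose selection internals are unknown.

## Numerical and degenerate-input conventions

* Payoffs accumulate exactly (integers with the default matrix); fitness
  is reported as a floating average.
* Population mean payoff is always within [P, R] because each dyad's
  per-round pair sum lies in {2P, T+S, 2R}.
* Zero-variance neighborhoods (homogeneous strategies) give z = 0
  everywhere, i.e. medium levels and, for SRAC agents, `keep`.
* Isolated nodes (possible only in imported edge lists) make fitness
  undefined and are rejected with an error rather than defaulted.
* Dynamic stability is operationalized as the rolling variance of mean
  payoff over a 10-generation window falling below 10⁻³ (the term is used
  informally in the field; any fixed small tolerance serves).
* Metrics CSVs are written with 17 significant digits and parsed with
  round-trip float precision, so write→read is exact.

## Known limitations

* The reconstructed reputation conventions and SRAC action table make
  quantitative landmark values (peak counts, crossing generations)
  reproducible only qualitatively; published point values such as
  peak-count differences between mixes are not point targets here.
* Only the Moore neighborhood pattern is implemented; the neighborhood
  parameter exists in configuration for forward compatibility.
* Strategies are deterministic; stochastic (probabilistic) strategies and
  noise/trembling-hand moves are out of scope.
* The per-agent Python update loop targets lattices up to ~10⁴ agents;
  the match engine itself is table-driven and scales further.
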