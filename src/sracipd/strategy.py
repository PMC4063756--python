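"""Memory-one (and generically memory-c) deterministic IPD strategies.

A memory-c deterministic strategy is a fixed response table over the
``4**c`` possible joint outcomes of the previous c rounds.  For the default
``c = 1`` the table has four entries, one per joint outcome of the last
round, canonically ordered CC, CD, DC, DD where the first letter is the
agent's own previous move and the second the opponent's.  A strategy is
identified by the integer formed by reading its responses as bits
(C -> 0, D -> 1) with the CC response most significant, giving the sixteen
strategies S_0 .. S_15.  Four of them carry standard names:

=========  =====  ==============  ==========================
index      tuple  name            behaviour
=========  =====  ==============  ==========================
0          CCCC   yes-man         always cooperate
5          CDCD   tit-for-tat     copy opponent's last move
6          CDDC   win-stay/lose-shift  repeat after R or T, switch after S or P
15         DDDD   scoundrel       always defect
=========  =====  ==============  ==========================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Move",
    "MemoryState",
    "Strategy",
    "decode_strategy",
    "encode_strategy",
    "respond",
    "random_strategy",
    "YES_MAN",
    "TFT",
    "WSLS",
    "SCOUNDREL",
    "NAMED_STRATEGIES",
]


class Move(enum.IntEnum):
    """A single IPD move: cooperate or defect."""

    C = 0
    D = 1

    def __str__(self) -> str:  # "C" / "D" rather than "Move.C"
        return self.name

    @classmethod
    def from_char(cls, ch: str) -> "Move":
        try:
            return cls[ch.upper()]
        except KeyError:
            raise ValueError(f"move must be 'C' or 'D', got {ch!r}") from None


@dataclass(frozen=True)
class MemoryState:
    """Joint outcome of the previous round from one player's perspective.

    ``own_prev`` is the move this agent made, ``opp_prev`` the move its
    opponent made.  The four states are canonically ordered CC, CD, DC, DD
    (index 0..3), own move first.
    """

    own_prev: Move
    opp_prev: Move

    @property
    def index(self) -> int:
        return (int(self.own_prev) << 1) | int(self.opp_prev)

    @classmethod
    def from_index(cls, idx: int) -> "MemoryState":
        if not 0 <= idx <= 3:
            raise ValueError(f"memory-1 state index must be in 0..3, got {idx}")
        return cls(Move(idx >> 1), Move(idx & 1))

    def __str__(self) -> str:
        return f"{self.own_prev}{self.opp_prev}"


# Canonical state order for c=1.
STATES = tuple(MemoryState.from_index(i) for i in range(4))


@dataclass(frozen=True)
class Strategy:
    """A deterministic response table indexed by memory state.

    ``responses[k]`` is the move played when the previous round's joint
    outcome has canonical index ``k``.  Length is ``4**c``; the default
    memory capacity c=1 gives the familiar four-value tuple
    (S_cc, S_cd, S_dc, S_dd).
    """

    responses: tuple[Move, ...]

    def __post_init__(self) -> None:
        n = len(self.responses)
        # length must be a power of 4 (4**c for some c >= 1)
        c = 0
        m = n
        while m > 1 and m % 4 == 0:
            m //= 4
            c += 1
        if m != 1 or c < 1:
            raise ValueError(
                f"response table length must be 4**c for integer c >= 1, got {n}"
            )
        object.__setattr__(self, "responses", tuple(Move(r) for r in self.responses))

    @property
    def length(self) -> int:
        """Strategy length l = 4**c (number of table entries)."""
        return len(self.responses)

    @property
    def memory(self) -> int:
        """Memory capacity c."""
        n, c = len(self.responses), 0
        while n > 1:
            n //= 4
            c += 1
        return c

    @property
    def index(self) -> int:
        """Canonical integer index (first response most significant bit)."""
        idx = 0
        for r in self.responses:
            idx = (idx << 1) | int(r)
        return idx

    def respond(self, state: MemoryState | int) -> Move:
        k = state if isinstance(state, int) else state.index
        return self.responses[k]

    @classmethod
    def from_index(cls, index: int, memory: int = 1) -> "Strategy":
        length = 4**memory
        if not isinstance(index, (int, np.integer)):
            raise TypeError(f"strategy index must be an integer, got {type(index)}")
        if not 0 <= index < 2**length:
            raise ValueError(
                f"memory-{memory} strategy index must be in 0..{2**length - 1}, "
                f"got {index}"
            )
        bits = [(index >> (length - 1 - k)) & 1 for k in range(length)]
        return cls(tuple(Move(b) for b in bits))

    @classmethod
    def from_string(cls, s: str) -> "Strategy":
        """Parse a response string such as ``"CDCD"`` (tit-for-tat)."""
        return cls(tuple(Move.from_char(ch) for ch in s))

    def __str__(self) -> str:
        return "".join(str(r) for r in self.responses)

    def __repr__(self) -> str:
        return f"Strategy({self}, index={self.index})"


def decode_strategy(index: int, memory: int = 1) -> Strategy:
    """Return the strategy whose canonical index is ``index``."""
    return Strategy.from_index(index, memory=memory)


def encode_strategy(responses: Sequence[Move] | Iterable[Move] | str) -> int:
    """Canonical integer index of a response table (inverse of decode)."""
    if isinstance(responses, str):
        return Strategy.from_string(responses).index
    return Strategy(tuple(responses)).index


def respond(strategy: Strategy, state: MemoryState) -> Move:
    """The move ``strategy`` plays given last round's joint outcome."""
    return strategy.respond(state)


def random_strategy(rng: np.random.Generator, memory: int = 1) -> Strategy:
    """Draw a strategy uniformly over all 2**(4**c) response tables."""
    length = 4**memory
    return Strategy.from_index(int(rng.integers(0, 2**length)), memory=memory)


YES_MAN = Strategy.from_index(0)
TFT = Strategy.from_index(5)
WSLS = Strategy.from_index(6)
SCOUNDREL = Strategy.from_index(15)

NAMED_STRATEGIES = {
    "yes_man": YES_MAN,
    "tft": TFT,
    "wsls": WSLS,
    "scoundrel": SCOUNDREL,
}

#: All sixteen memory-1 strategies, indexed by canonical index.
ALL_MEMORY_ONE = tuple(Strategy.from_index(i) for i in range(16))
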