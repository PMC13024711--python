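"""Finite-state model of the collaborative Balance Beam task.

Two students (roles ``A`` and ``B``) share four weights (50, 100, 300 and
500 g) and a beam with four equally spaced hanging positions on each side.
Each weight occupies exactly one of ten slots: held by A, held by B, or hung
at one of the eight lever positions (A1..A4, B1..B4).  A state is the slot
assignment of the four weights, giving 10^4 = 10,000 distinct problem
states.  Four move types change one weight's slot at a time:

* ``PASS``   — the holder hands a held weight to the partner;
* ``HANG``   — the holder hangs a held weight on *their own* side;
* ``REMOVE`` — a student takes a weight off their own side, back into
  their own hand;
* ``SHIFT``  — a student moves a weight between two positions on their
  own side.

Every move is reversible, so the 168,000 directed transitions form a
symmetric relation.  The task is solved when exactly one weight hangs on
each side and the torques balance (mass_A x position_A = mass_B x
position_B); the remaining two weights may be held by either student.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterator

__all__ = [
    "WEIGHTS",
    "N_STATES",
    "N_TRANSITIONS",
    "Slot",
    "MoveKind",
    "Move",
    "ProblemState",
    "IllegalMoveError",
    "StateCodecError",
    "encode_state",
    "decode_state",
    "enumerate_states",
    "legal_moves",
    "apply_move",
    "is_target",
    "enumerate_targets",
    "mirror_state",
    "mirror_move",
    "build_transition_graph",
    "TransitionGraph",
    "action_code",
    "collapsed_vocabulary_size",
]

#: The four weight masses in grams, in codec order.
WEIGHTS: tuple[int, int, int, int] = (50, 100, 300, 500)

N_SLOTS = 10
N_STATES = 10_000
#: Directed legal transitions over the full state space.
N_TRANSITIONS = 168_000

_POSITIONS = (1, 2, 3, 4)


class Slot(IntEnum):
    """One of the ten places a weight can be.

    The integer values define the digit used by the mixed-radix state
    codec: held slots first, then side A positions 1-4, then side B.
    """

    HELD_A = 0
    HELD_B = 1
    A1 = 2
    A2 = 3
    A3 = 4
    A4 = 5
    B1 = 6
    B2 = 7
    B3 = 8
    B4 = 9

    @property
    def held(self) -> bool:
        return self <= Slot.HELD_B

    @property
    def side(self) -> str:
        """Which student owns this slot ('A' or 'B')."""
        if self == Slot.HELD_A:
            return "A"
        if self == Slot.HELD_B:
            return "B"
        return "A" if self <= Slot.A4 else "B"

    @property
    def position(self) -> int | None:
        """Lever position 1-4 (distance index from the fulcrum), or None if held."""
        if self.held:
            return None
        return (int(self) - int(Slot.A1)) % 4 + 1


def _hand(role: str) -> Slot:
    return Slot.HELD_A if role == "A" else Slot.HELD_B


def _hang_slot(role: str, position: int) -> Slot:
    base = Slot.A1 if role == "A" else Slot.B1
    return Slot(int(base) + position - 1)


def _other(role: str) -> str:
    return "B" if role == "A" else "A"


class MoveKind(str, Enum):
    PASS = "PASS"
    HANG = "HANG"
    REMOVE = "REMOVE"
    SHIFT = "SHIFT"


@dataclass(frozen=True)
class Move:
    """A single legal transition: one weight changes slot by one actor."""

    actor: str
    kind: MoveKind
    weight: int
    src: Slot
    dst: Slot

    def describe(self) -> str:
        """Human-readable rendering, e.g. ``'B hangs the 500 g weight at position 2'``."""
        w = self.weight
        if self.kind is MoveKind.PASS:
            return f"{self.actor} passes the {w} g weight to partner"
        if self.kind is MoveKind.HANG:
            return f"{self.actor} hangs the {w} g weight at position {self.dst.position}"
        if self.kind is MoveKind.REMOVE:
            return f"{self.actor} removes the {w} g weight from position {self.src.position}"
        return (
            f"{self.actor} shifts the {w} g weight from position "
            f"{self.src.position} to position {self.dst.position}"
        )


@dataclass(frozen=True)
class ProblemState:
    """Slot of each weight, ordered as :data:`WEIGHTS` (50, 100, 300, 500 g)."""

    slots: tuple[Slot, Slot, Slot, Slot]

    @classmethod
    def initial(cls) -> "ProblemState":
        """The task's start state: Student A holds all four weights."""
        return cls((Slot.HELD_A,) * 4)

    def slot_of(self, weight: int) -> Slot:
        return self.slots[WEIGHTS.index(weight)]

    def replace(self, weight: int, slot: Slot) -> "ProblemState":
        i = WEIGHTS.index(weight)
        slots = list(self.slots)
        slots[i] = slot
        return ProblemState(tuple(slots))

    def hung(self) -> list[tuple[int, Slot]]:
        """(weight, slot) pairs for the weights currently on the beam."""
        return [(w, s) for w, s in zip(WEIGHTS, self.slots) if not s.held]


class StateCodecError(ValueError):
    """Raised for integer codes outside [0, 9999]."""


class IllegalMoveError(ValueError):
    """Raised when a move violates a task rule; the message names the rule."""


# ---------------------------------------------------------------------------
# State codec: mixed-radix base-10 over the weight order (50, 100, 300, 500).


def encode_state(state: ProblemState) -> int:
    """Bijective code in [0, 9999]; digit i is the slot of WEIGHTS[i]."""
    return sum(int(s) * 10**i for i, s in enumerate(state.slots))


def decode_state(code: int) -> ProblemState:
    if not 0 <= code < N_STATES:
        raise StateCodecError(f"state code {code} outside [0, {N_STATES - 1}]")
    slots = tuple(Slot(code // 10**i % 10) for i in range(4))
    return ProblemState(slots)


def enumerate_states() -> Iterator[ProblemState]:
    """All 10,000 problem states, in codec order."""
    for slots in itertools.product(tuple(Slot), repeat=4):
        yield ProblemState((slots[3], slots[2], slots[1], slots[0]))


# ---------------------------------------------------------------------------
# Moves


def legal_moves(state: ProblemState) -> list[Move]:
    """All legal moves from ``state``.

    A held weight affords 5 moves to its holder (1 pass + 4 hangs); a hung
    weight affords 4 to the owner of its side (1 remove + 3 shifts), so the
    out-degree is 16 + (number of held weights) and lies in [16, 20].
    """
    moves: list[Move] = []
    for w, s in zip(WEIGHTS, state.slots):
        if s.held:
            holder = s.side
            moves.append(Move(holder, MoveKind.PASS, w, s, _hand(_other(holder))))
            for p in _POSITIONS:
                moves.append(Move(holder, MoveKind.HANG, w, s, _hang_slot(holder, p)))
        else:
            owner = s.side
            moves.append(Move(owner, MoveKind.REMOVE, w, s, _hand(owner)))
            for q in _POSITIONS:
                if q != s.position:
                    moves.append(Move(owner, MoveKind.SHIFT, w, s, _hang_slot(owner, q)))
    return moves


def _check_move(state: ProblemState, move: Move) -> None:
    if move.weight not in WEIGHTS:
        raise IllegalMoveError(f"unknown weight {move.weight} g")
    if move.actor not in ("A", "B"):
        raise IllegalMoveError(f"unknown actor {move.actor!r}")
    if state.slot_of(move.weight) != move.src:
        raise IllegalMoveError(
            f"the {move.weight} g weight is at {state.slot_of(move.weight).name}, "
            f"not at the move's source {move.src.name}"
        )
    k, src, dst, actor = move.kind, move.src, move.dst, move.actor
    if k is MoveKind.PASS:
        if not (src.held and dst.held and src != dst):
            raise IllegalMoveError("PASS must move a weight between the two hands")
        if src.side != actor:
            raise IllegalMoveError("PASS may only be made by the student holding the weight")
    elif k is MoveKind.HANG:
        if not src.held or src.side != actor:
            raise IllegalMoveError("HANG requires the acting student to hold the weight")
        if dst.held or dst.side != actor:
            raise IllegalMoveError("HANG destination must be a position on the actor's own side")
    elif k is MoveKind.REMOVE:
        if src.held or src.side != actor:
            raise IllegalMoveError("REMOVE source must be a position on the actor's own side")
        if dst != _hand(actor):
            raise IllegalMoveError("REMOVE returns the weight to the acting student's hand")
    elif k is MoveKind.SHIFT:
        if src.held or dst.held or src.side != actor or dst.side != actor or src == dst:
            raise IllegalMoveError(
                "SHIFT must move a weight between two distinct positions on the actor's own side"
            )
    else:  # pragma: no cover - enum is exhaustive
        raise IllegalMoveError(f"unknown move kind {k!r}")


def apply_move(state: ProblemState, move: Move) -> ProblemState:
    """Apply a legal move; raises :class:`IllegalMoveError` naming the violated rule."""
    _check_move(state, move)
    return state.replace(move.weight, move.dst)


# ---------------------------------------------------------------------------
# Targets


def is_target(state: ProblemState) -> bool:
    """True iff exactly one weight hangs per side and the torques balance."""
    hung = state.hung()
    if len(hung) != 2:
        return False
    (w1, s1), (w2, s2) = hung
    if s1.side == s2.side:
        return False
    # integer torque product: mass x lever position
    return w1 * s1.position == w2 * s2.position


def enumerate_targets() -> set[ProblemState]:
    """All balanced target states (closed under :func:`mirror_state`)."""
    return {s for s in enumerate_states() if is_target(s)}


# ---------------------------------------------------------------------------
# Mirror (role/side) symmetry


_MIRROR = {
    Slot.HELD_A: Slot.HELD_B,
    Slot.HELD_B: Slot.HELD_A,
    Slot.A1: Slot.B1,
    Slot.A2: Slot.B2,
    Slot.A3: Slot.B3,
    Slot.A4: Slot.B4,
    Slot.B1: Slot.A1,
    Slot.B2: Slot.A2,
    Slot.B3: Slot.A3,
    Slot.B4: Slot.A4,
}


def mirror_state(state: ProblemState) -> ProblemState:
    """Swap the two students' sides and hands; an involution and a graph automorphism."""
    return ProblemState(tuple(_MIRROR[s] for s in state.slots))


def mirror_move(move: Move) -> Move:
    return Move(_other(move.actor), move.kind, move.weight, _MIRROR[move.src], _MIRROR[move.dst])


# ---------------------------------------------------------------------------
# Transition graph


@dataclass
class TransitionGraph:
    """The full directed transition graph over integer state codes.

    ``adj[code]`` lists ``(dst_code, move)`` pairs; ``edges`` flattens them
    as ``(src_code, move, dst_code)``.
    """

    n_states: int
    adj: list[list[tuple[int, Move]]]

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adj)

    def edges(self) -> Iterator[tuple[int, Move, int]]:
        for src, out in enumerate(self.adj):
            for dst, move in out:
                yield src, move, dst

    def out_degree(self, code: int) -> int:
        return len(self.adj[code])

    def to_networkx(self):
        """Export as a :class:`networkx.DiGraph` with move attributes on edges."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_states))
        for src, move, dst in self.edges():
            g.add_edge(
                src,
                dst,
                actor=move.actor,
                kind=move.kind.value,
                weight_g=move.weight,
                src_slot=move.src.name,
                dst_slot=move.dst.name,
            )
        return g


def build_transition_graph() -> TransitionGraph:
    """Enumerate all states and legal moves (10,000 nodes, 168,000 directed edges)."""
    adj: list[list[tuple[int, Move]]] = []
    for code in range(N_STATES):
        state = decode_state(code)
        out = []
        for move in legal_moves(state):
            out.append((encode_state(state.replace(move.weight, move.dst)), move))
        adj.append(out)
    return TransitionGraph(N_STATES, adj)


# ---------------------------------------------------------------------------
# Raw-action vocabulary

# Actor-relative move-type offsets within one weight's block of 21 codes:
#   0        pass to partner
#   1..4     hang at position p
#   5..8     remove from position p
#   9..20    shift p -> q (12 ordered pairs)
_N_TYPES_PER_WEIGHT = 21


def _shift_index(p: int, q: int) -> int:
    # ordered pairs (p, q), p != q, enumerated row-major over p then q
    return (p - 1) * 3 + (q - 1 if q < p else q - 2)


def action_code(move: Move, role_mode: str = "collapsed") -> int | str:
    """Code for a move's type.

    ``collapsed`` returns an integer in 1..84: the actor-relative move type
    (weight x {pass, hang@p, remove-from-p, ordered shift pair}), identical
    for mirror-image moves by the two roles.  ``tagged`` returns the
    human-readable role-prefixed description (up to 168 distinct strings).
    """
    if role_mode == "tagged":
        return move.describe()
    if role_mode != "collapsed":
        raise ValueError(f"role_mode must be 'tagged' or 'collapsed', got {role_mode!r}")
    wi = WEIGHTS.index(move.weight)
    k = move.kind
    if k is MoveKind.PASS:
        offset = 0
    elif k is MoveKind.HANG:
        offset = move.dst.position
    elif k is MoveKind.REMOVE:
        offset = 4 + move.src.position
    else:  # SHIFT
        offset = 9 + _shift_index(move.src.position, move.dst.position)
    return wi * _N_TYPES_PER_WEIGHT + offset + 1


def collapsed_vocabulary_size() -> int:
    """Distinct collapsed codes over every legal move of every state."""
    codes = set()
    for code in range(N_STATES):
        for move in legal_moves(decode_state(code)):
            codes.add(action_code(move, "collapsed"))
    return len(codes)
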