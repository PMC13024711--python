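"""Distance-based effectiveness indicators and sequence re-representation.

The *state effectiveness* ``d_s`` of a problem state is the minimum number
of transitions needed to reach any balanced target state — a multi-source
BFS distance over the transition graph (all transitions cost 1).  The
*transition effectiveness* of a move ``s -> s'`` is ``Δd = d_s - d_s'``;
because every transition is reversible, Δd is always -1, 0 or +1: a step
toward the target, a neutral step, or a step away.

Action sequences can then be re-represented in three formats:

* ``RAW``        — the action itself (tagged human-readable token, or the
  collapsed 1..84 ordinal code for numeric use);
* ``DELTA``      — the Δd of each transition;
* ``STATE_PAIR`` — the ``d -> d'`` pair of state effectiveness values
  around each transition (for numeric use, the post-transition ``d``
  series; the optimal solution of the task reads ``2, 1, 0``).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .task_model import (
    Move,
    N_STATES,
    ProblemState,
    TransitionGraph,
    action_code,
    apply_move,
    encode_state,
    enumerate_targets,
    is_target,
)

__all__ = [
    "EffectivenessMap",
    "Representation",
    "EncodedSequence",
    "SequenceSummary",
    "IllegalWalkError",
    "compute_state_effectiveness",
    "transition_delta",
    "walk_states",
    "encode_sequence",
    "summarize_sequence",
]


class IllegalWalkError(ValueError):
    """A move sequence left the set of legal walks; reports the offending step."""

    def __init__(self, step: int, reason: str):
        self.step = step
        super().__init__(f"illegal move at step {step}: {reason}")


@dataclass
class EffectivenessMap:
    """``d_s`` for every state, indexed by integer state code."""

    d: np.ndarray

    def __getitem__(self, key: int | ProblemState) -> int:
        if isinstance(key, ProblemState):
            key = encode_state(key)
        return int(self.d[key])

    @property
    def max_d(self) -> int:
        return int(self.d.max())


def compute_state_effectiveness(
    graph: TransitionGraph, targets: set[ProblemState] | None = None
) -> EffectivenessMap:
    """Multi-source BFS distance from the balanced target set.

    Distances are computed over reversed edges (equivalently forward ones,
    since the edge relation is symmetric), so ``d[s]`` is the minimum
    number of transitions from ``s`` to the nearest target.
    """
    if targets is None:
        targets = enumerate_targets()
    if not targets:
        raise ValueError("target set is empty; cannot define state effectiveness")
    # reverse adjacency (defensive: the task graph happens to be symmetric)
    rev: list[list[int]] = [[] for _ in range(graph.n_states)]
    for src, _move, dst in graph.edges():
        rev[dst].append(src)
    d = np.full(graph.n_states, -1, dtype=np.int64)
    queue: deque[int] = deque()
    for t in targets:
        code = encode_state(t)
        d[code] = 0
        queue.append(code)
    while queue:
        u = queue.popleft()
        du = d[u]
        for v in rev[u]:
            if d[v] < 0:
                d[v] = du + 1
                queue.append(v)
    if (d < 0).any():
        raise ValueError("some states cannot reach any target state")
    return EffectivenessMap(d)


def transition_delta(state: ProblemState, move: Move, eff: EffectivenessMap) -> int:
    """``Δd = d(s) - d(s')`` for the given move; always in {-1, 0, +1}."""
    return eff[state] - eff[apply_move(state, move)]


class Representation(str, Enum):
    RAW = "raw"
    DELTA = "delta"
    STATE_PAIR = "state-pair"

    @classmethod
    def coerce(cls, value: "Representation | str") -> "Representation":
        if isinstance(value, cls):
            return value
        aliases = {"state_pair": "state-pair", "state-d": "state-pair", "d": "state-pair"}
        v = str(value).lower()
        return cls(aliases.get(v, v))


@dataclass
class EncodedSequence:
    """An action sequence rendered under one representation.

    ``tokens`` are strings in tagged mode (for n-gram analysis) or scalars
    in collapsed mode (numeric series for DTW); ``states`` is the visited
    state-code series including the initial state, so ``len(states) ==
    len(tokens) + 1``.
    """

    group_id: str
    representation: Representation
    role_mode: str
    tokens: list = field(default_factory=list)
    states: list[int] = field(default_factory=list)
    success: bool = False

    def __len__(self) -> int:
        return len(self.tokens)


def walk_states(moves: list[Move], start: ProblemState | None = None) -> list[ProblemState]:
    """Replay a move list from the initial state; raises IllegalWalkError on the first bad step."""
    state = ProblemState.initial() if start is None else start
    states = [state]
    for i, move in enumerate(moves):
        try:
            state = apply_move(state, move)
        except ValueError as exc:
            raise IllegalWalkError(i, str(exc)) from exc
        states.append(state)
    return states


def encode_sequence(
    moves: list[Move],
    representation: Representation | str,
    role_mode: str = "tagged",
    eff: EffectivenessMap | None = None,
    group_id: str = "g0",
    start: ProblemState | None = None,
) -> EncodedSequence:
    """Re-represent a legal move sequence as tokens.

    Tagged tokens carry the actor role (``"B: 2→3"``); collapsed tokens are
    the numeric series used for DTW (raw ordinal code, Δd value, or the
    post-transition ``d`` for the state-pair representation).
    """
    representation = Representation.coerce(representation)
    if role_mode not in ("tagged", "collapsed"):
        raise ValueError(f"role_mode must be 'tagged' or 'collapsed', got {role_mode!r}")
    if representation is not Representation.RAW and eff is None:
        raise ValueError(f"{representation.value} representation requires an effectiveness map")
    states = walk_states(moves, start)
    tokens: list = []
    for i, move in enumerate(moves):
        if representation is Representation.RAW:
            tokens.append(action_code(move, role_mode))
            continue
        d0, d1 = eff[states[i]], eff[states[i + 1]]
        if representation is Representation.DELTA:
            tokens.append(f"{move.actor}: {d0 - d1}" if role_mode == "tagged" else d0 - d1)
        else:  # STATE_PAIR
            tokens.append(f"{move.actor}: {d0}→{d1}" if role_mode == "tagged" else d1)
    return EncodedSequence(
        group_id=group_id,
        representation=representation,
        role_mode=role_mode,
        tokens=tokens,
        states=[encode_state(s) for s in states],
        success=is_target(states[-1]),
    )


@dataclass
class SequenceSummary:
    """Sequence-level effectiveness statistics."""

    group_id: str
    length: int
    mean_delta: float
    prop_forward: float
    prop_still: float
    prop_backward: float
    mean_d: float
    success: bool


def summarize_sequence(
    seq: EncodedSequence,
    eff: EffectivenessMap,
    success_rule: str = "terminal",
) -> SequenceSummary:
    """Length, mean Δd, Δd-category proportions, mean post-move d, success.

    ``success_rule='terminal'`` labels a sequence successful when its final
    state is balanced; ``'ever'`` when any visited state is.  The mean Δd
    telescopes to ``(d_initial - d_final) / length``.
    """
    if success_rule not in ("terminal", "ever"):
        raise ValueError(f"unknown success_rule {success_rule!r}")
    d_series = np.asarray([eff[c] for c in seq.states], dtype=float)
    if success_rule == "terminal":
        success = d_series[-1] == 0
    else:
        success = bool((d_series == 0).any())
    n = len(seq.states) - 1
    if n == 0:
        return SequenceSummary(seq.group_id, 0, math.nan, math.nan, math.nan, math.nan, math.nan, bool(success))
    deltas = -np.diff(d_series)
    return SequenceSummary(
        group_id=seq.group_id,
        length=n,
        mean_delta=float(deltas.mean()),
        prop_forward=float((deltas == 1).mean()),
        prop_still=float((deltas == 0).mean()),
        prop_backward=float((deltas == -1).mean()),
        mean_d=float(d_series[1:].mean()),
        success=bool(success),
    )
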