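"""Synthetic cohorts of collaborative Balance Beam action logs.

Groups are random walkers on the task's transition graph with a planted
ability parameter ``theta``: at each step the probability of a legal move
is proportional to ``exp(theta * Δd)``, where Δd is the move's transition
effectiveness.  ``theta = 0`` is a uniform random walker; large ``theta``
follows a shortest path to a balanced state.  A walk stops when it reaches
a target (absorbing rule, optionally continuing with a fixed probability
to model post-success fiddling) or when it hits the maximum length.  The
defaults emulate the study conditions the pipeline is meant for: 422
groups, ``theta ~ Normal(0.8, 0.5)``, at most 120 actions per group, which
yields intermediate-length sequences and a completion rate strictly
between 0 and 1.

Every emitted sequence is legal by construction and the root seed fully
determines the cohort (per-group child RNG streams).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effectiveness import EffectivenessMap, compute_state_effectiveness
from .task_model import (
    Move,
    ProblemState,
    TransitionGraph,
    build_transition_graph,
    encode_state,
    legal_moves,
    apply_move,
)

__all__ = [
    "SimulationConfig",
    "SimulatedGroup",
    "softmax_policy",
    "simulate_group",
    "simulate_cohort",
    "cohort_truth_table",
]


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    ``theta`` fixes one ability for every group; otherwise abilities are
    drawn from ``Normal(theta_mean, theta_sd)``.  ``stop_rule`` is
    ``"absorb"`` (stop at the first balanced state) or ``"continue"``
    (at a balanced state, keep acting with probability ``continue_prob``).
    """

    n_groups: int = 422
    theta_mean: float = 0.8
    theta_sd: float = 0.5
    theta: float | None = None
    max_len: int = 120
    stop_rule: str = "absorb"
    continue_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.max_len < 3:
            raise ValueError("max_len must be >= 3 (the optimal solution length)")
        if self.stop_rule not in ("absorb", "continue"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass
class SimulatedGroup:
    group_id: str
    theta: float
    moves: list[Move]
    success: bool
    final_d: int = 0


def softmax_policy(
    state: ProblemState, theta: float, eff: EffectivenessMap
) -> tuple[list[Move], np.ndarray]:
    """Move distribution ``P(move) ∝ exp(theta * Δd(move))`` at a state."""
    moves = legal_moves(state)
    d0 = eff[state]
    deltas = np.array([d0 - eff[apply_move(state, m)] for m in moves], dtype=float)
    logits = theta * deltas
    logits -= logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    return moves, probs


def _walk(
    code: int,
    theta: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    graph: TransitionGraph,
    d: np.ndarray,
) -> tuple[list[int], list[Move]]:
    path_moves: list[Move] = []
    codes = [code]
    while len(path_moves) < config.max_len:
        if d[code] == 0:
            if config.stop_rule == "absorb" or rng.random() >= config.continue_prob:
                break
        out = graph.adj[code]
        deltas = np.array([d[code] - d[dst] for dst, _ in out], dtype=float)
        logits = theta * deltas
        logits -= logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        i = int(rng.choice(len(out), p=probs))
        code = out[i][0]
        path_moves.append(out[i][1])
        codes.append(code)
    return codes, path_moves


def simulate_group(
    theta: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    graph: TransitionGraph | None = None,
    eff: EffectivenessMap | None = None,
    group_id: str = "g0",
) -> SimulatedGroup:
    """One group's walk from the initial state under the softmax policy."""
    if graph is None:
        graph = build_transition_graph()
    if eff is None:
        eff = compute_state_effectiveness(graph)
    start = encode_state(ProblemState.initial())
    codes, moves = _walk(start, theta, config, rng, graph, eff.d)
    final_d = int(eff.d[codes[-1]])
    return SimulatedGroup(group_id, theta, moves, final_d == 0, final_d)


def simulate_cohort(
    config: SimulationConfig,
    graph: TransitionGraph | None = None,
    eff: EffectivenessMap | None = None,
) -> list[SimulatedGroup]:
    """Independent groups under one root seed; reproducible per group."""
    if graph is None:
        graph = build_transition_graph()
    if eff is None:
        eff = compute_state_effectiveness(graph)
    root = np.random.SeedSequence(config.seed)
    theta_ss, walk_ss = root.spawn(2)
    theta_rng = np.random.default_rng(theta_ss)
    if config.theta is not None:
        thetas = np.full(config.n_groups, float(config.theta))
    else:
        thetas = theta_rng.normal(config.theta_mean, config.theta_sd, size=config.n_groups)
    cohort = []
    for i, child in enumerate(walk_ss.spawn(config.n_groups)):
        rng = np.random.default_rng(child)
        cohort.append(
            simulate_group(float(thetas[i]), config, rng, graph, eff, group_id=f"g{i:04d}")
        )
    return cohort


def cohort_truth_table(cohort: Sequence[SimulatedGroup]) -> pd.DataFrame:
    """Planted per-group truth for recovery tests: theta, success, length."""
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in cohort],
            "theta": [g.theta for g in cohort],
            "success": [g.success for g in cohort],
            "length": [len(g.moves) for g in cohort],
            "final_d": [g.final_d for g in cohort],
        }
    )
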