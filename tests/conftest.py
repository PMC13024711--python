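"""Shared fixtures: the task graph, effectiveness map, and planted cohorts.

The transition graph and BFS map are deterministic and moderately costly
(a few seconds), so they are built once per session.  The planted cohort
mixes a low-ability and a high-ability subpopulation (theta 0.1 vs 1.5,
30 groups each, at most 60 actions) — large enough for the qualitative
pipeline checks, small enough to keep the suite fast.
"""

import numpy as np
import pytest
from hypothesis import settings

from procfx.effectiveness import compute_state_effectiveness, encode_sequence
from procfx.simulate import SimulationConfig, simulate_cohort
from procfx.task_model import (
    Move,
    MoveKind,
    ProblemState,
    Slot,
    build_transition_graph,
    enumerate_targets,
)

settings.register_profile("suite", database=None, deadline=None)
settings.load_profile("suite")

# The optimal three-step solution used by several examples:
# hang 50 g at A2, pass the 100 g, hang it at B1 (torque 100 = 100).
OPTIMAL_MOVES = [
    Move("A", MoveKind.HANG, 50, Slot.HELD_A, Slot.A2),
    Move("A", MoveKind.PASS, 100, Slot.HELD_A, Slot.HELD_B),
    Move("B", MoveKind.HANG, 100, Slot.HELD_B, Slot.B1),
]

# Table-style worked states: a unigram context (100 g at B1, 300 g at B2,
# A holding 50 and 500 g) and a bigram context (500 g at A2, A holding 50
# and 100 g, B holding 300 g).
UNIGRAM_STATE = ProblemState((Slot.HELD_A, Slot.B1, Slot.B2, Slot.HELD_A))
BIGRAM_STATE = ProblemState((Slot.HELD_A, Slot.HELD_A, Slot.HELD_B, Slot.A2))


@pytest.fixture(scope="session")
def graph():
    return build_transition_graph()


@pytest.fixture(scope="session")
def eff(graph):
    return compute_state_effectiveness(graph)


@pytest.fixture(scope="session")
def targets():
    return enumerate_targets()


@pytest.fixture(scope="session")
def planted_cohort(graph, eff):
    """Two-component cohort: 30 low-theta + 30 high-theta groups."""
    low = SimulationConfig(n_groups=30, theta=0.1, max_len=60, seed=11)
    high = SimulationConfig(n_groups=30, theta=1.5, max_len=60, seed=12)
    return simulate_cohort(low, graph, eff) + simulate_cohort(high, graph, eff)


@pytest.fixture(scope="session")
def planted_corpora(planted_cohort, eff):
    """Tagged token corpora of the planted cohort under each representation."""
    out = {}
    for rep in ("raw", "delta", "state-pair"):
        out[rep] = [
            encode_sequence(g.moves, rep, "tagged", eff, group_id=g.group_id)
            for g in planted_cohort
        ]
    return out


@pytest.fixture(scope="session")
def planted_series(planted_cohort, eff):
    """Numeric DTW series of the planted cohort under each representation."""
    out = {}
    for rep in ("raw", "delta", "state-pair"):
        out[rep] = [
            np.asarray(
                encode_sequence(g.moves, rep, "collapsed", eff).tokens, dtype=float
            )
            for g in planted_cohort
        ]
    return out
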