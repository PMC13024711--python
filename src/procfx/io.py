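"""Action-log and result IO with replay validation.

Logs are CSV (header required) or JSON-lines with one record per action:
``group_id, step, actor, weight, src_slot, dst_slot[, timestamp]``.  Slots
are serialized as strings (``HELD_A``, ``A1`` .. ``B4``); timestamps are
carried through but never used by the analyses, which are order-based.

Reading replays each group's moves from the initial state through the task
model, so the validator is the single source of legality.  In ``filter``
mode records that violate legality or step continuity are dropped and
tallied in a report (mirroring how aberrant actions are discarded from
empirical logs); in ``strict`` mode the first violation raises.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .task_model import (
    IllegalMoveError,
    Move,
    MoveKind,
    ProblemState,
    Slot,
    WEIGHTS,
    apply_move,
    is_target,
)

__all__ = [
    "LogParseError",
    "LoadedSequence",
    "FilterReport",
    "move_from_record",
    "read_log",
    "write_log",
    "write_results",
    "sequences_to_frame",
]

LOG_COLUMNS = ["group_id", "step", "actor", "weight", "src_slot", "dst_slot"]


class LogParseError(ValueError):
    """Malformed log file; the message carries the offending line/record."""


@dataclass
class LoadedSequence:
    group_id: str
    moves: list[Move]
    success: bool


@dataclass
class FilterReport:
    """Counts of dropped records per reason, per group."""

    dropped: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _infer_kind(src: Slot, dst: Slot) -> MoveKind:
    if src.held and dst.held:
        return MoveKind.PASS
    if src.held:
        return MoveKind.HANG
    if dst.held:
        return MoveKind.REMOVE
    return MoveKind.SHIFT


def move_from_record(record: dict, line: int | None = None) -> Move:
    """Build a Move from one log record; raises LogParseError on bad vocabulary."""
    where = f" (record {line})" if line is not None else ""
    try:
        actor = str(record["actor"]).strip()
        weight = int(record["weight"])
        src = Slot[str(record["src_slot"]).strip()]
        dst = Slot[str(record["dst_slot"]).strip()]
    except KeyError as exc:
        raise LogParseError(f"missing field or unknown slot {exc}{where}") from exc
    except (TypeError, ValueError) as exc:
        raise LogParseError(f"malformed record{where}: {exc}") from exc
    if weight not in WEIGHTS:
        raise LogParseError(f"unknown weight {weight} g{where}")
    if actor not in ("A", "B"):
        raise LogParseError(f"unknown actor {actor!r}{where}")
    return Move(actor, _infer_kind(src, dst), weight, src, dst)


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".json", ".jsonl", ".ndjson"):
        records = []
        with open(path, encoding="utf-8") as fh:
            for i, raw in enumerate(fh, 1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    records.append(json.loads(raw))
                except json.JSONDecodeError as exc:
                    raise LogParseError(f"invalid JSON at line {i}: {exc}") from exc
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogParseError(f"log is missing required columns {missing}")
    return df


def read_log(
    path: str | Path, mode: str = "filter", success_rule: str = "terminal"
) -> tuple[list[LoadedSequence], FilterReport]:
    """Read and validate an action log.

    Returns the legal sequences plus a drop report.  ``mode='filter'``
    drops offending records and continues the replay; ``mode='strict'``
    raises on the first violation.
    """
    if mode not in ("filter", "strict"):
        raise ValueError(f"mode must be 'filter' or 'strict', got {mode!r}")
    df = _load_frame(path)
    report = FilterReport()
    sequences: list[LoadedSequence] = []
    for group_id, g in df.groupby("group_id", sort=True):
        g = g.sort_values("step", kind="mergesort")
        state = ProblemState.initial()
        moves: list[Move] = []
        expected_step = 1
        ever_target = is_target(state)
        for idx, record in g.iterrows():
            step = int(record["step"])
            if step != expected_step:
                msg = (
                    f"group {group_id}: step {step} breaks continuity "
                    f"(expected {expected_step})"
                )
                if mode == "strict":
                    raise LogParseError(msg)
                report.add("discontinuous_step")
            expected_step = step + 1
            try:
                move = move_from_record(record.to_dict(), line=idx)
                state = apply_move(state, move)
            except (LogParseError, IllegalMoveError) as exc:
                if mode == "strict":
                    raise
                report.add(
                    "parse_error" if isinstance(exc, LogParseError) else "illegal_move"
                )
                continue
            moves.append(move)
            ever_target = ever_target or is_target(state)
        success = ever_target if success_rule == "ever" else is_target(state)
        sequences.append(LoadedSequence(str(group_id), moves, success))
    return sequences, report


def sequences_to_frame(sequences: Sequence) -> pd.DataFrame:
    """Flatten ``(group_id, moves)``-bearing objects to the long log schema."""
    rows = []
    for seq in sequences:
        for i, m in enumerate(seq.moves, 1):
            rows.append(
                {
                    "group_id": seq.group_id,
                    "step": i,
                    "actor": m.actor,
                    "weight": m.weight,
                    "src_slot": m.src.name,
                    "dst_slot": m.dst.name,
                }
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(sequences: Sequence, path: str | Path) -> None:
    """Write sequences to CSV or JSON-lines (by extension) with a fixed column order."""
    df = sequences_to_frame(sequences)
    path = Path(path)
    if path.suffix.lower() in (".json", ".jsonl", ".ndjson"):
        with open(path, "w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        df.to_csv(path, index=False)


def _config_hash(metadata: dict) -> str:
    payload = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a result table as CSV plus a JSON sidecar with run metadata."""
    path = Path(path)
    out = df.copy()
    out.to_csv(path, index=False)
    from . import __version__ as version  # deferred: avoids a circular import

    meta = dict(metadata or {})
    meta["procfx_version"] = version
    meta["config_hash"] = _config_hash(meta)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
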