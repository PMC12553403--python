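"""Move-table CSV input/output, run configuration and stage logging.

The canonical on-disk format is a flat CSV with one row per move event:

    game_id, ply, elo, opp_clock, clock_before, clock_after,
    tc_start, tc_inc, outcome, move_id_1, shallow_1, deep_1, ...,
    move_id_K, shallow_K, deep_K

Clocks are decimal seconds.  ``outcome`` is the active player's game result
(``win``/``loss``/``draw``).  The trailing triplets carry the consideration
set: paired shallow/deep win-probability utilities per candidate move, K
columns wide (default 5).  Rows with unparseable numeric fields are skipped
and counted, never silently dropped.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import yaml

from .voc import ConsiderationSet, MoveEval

__all__ = [
    "TimeControl",
    "PositionRecord",
    "RunConfig",
    "read_move_table",
    "write_move_table",
    "read_config",
    "log_stage",
    "logger",
]

logger = logging.getLogger("thinktime")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

OUTCOMES = ("win", "loss", "draw")

_BASE_COLUMNS = (
    "game_id",
    "ply",
    "elo",
    "opp_clock",
    "clock_before",
    "clock_after",
    "tc_start",
    "tc_inc",
    "outcome",
)


def log_stage(stage: str, n_records: int, n_skipped: int = 0) -> None:
    """Structured stage log line: stage name, records kept, records skipped."""
    logger.info("stage=%s n_records=%d n_skipped=%d", stage, n_records, n_skipped)


@dataclass(frozen=True, slots=True)
class TimeControl:
    """An S+I clock setting: S starting seconds, I seconds added per move."""

    start_seconds: int
    increment_seconds: int

    def __post_init__(self) -> None:
        if self.start_seconds <= 0:
            raise ValueError("start_seconds must be positive")
        if self.increment_seconds < 0:
            raise ValueError("increment_seconds must be nonnegative")

    @property
    def label(self) -> str:
        return f"{self.start_seconds}+{self.increment_seconds}"

    @classmethod
    def from_label(cls, label: str) -> "TimeControl":
        s, _, i = label.partition("+")
        return cls(int(s), int(i))


@dataclass(slots=True)
class PositionRecord:
    """One move event: clocks, rating, outcome and the consideration set."""

    game_id: str
    ply: int
    active_elo: float
    opponent_clock: float
    clock_before: float
    clock_after: float
    time_control: TimeControl
    outcome: str
    consideration_set: ConsiderationSet
    observed_move_id: str | None = None

    def __post_init__(self) -> None:
        if self.ply < 1:
            raise ValueError("ply must be >= 1")
        if self.clock_before < 0 or self.clock_after < 0:
            raise ValueError("clocks must be nonnegative")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")


@dataclass
class RunConfig:
    """Pipeline configuration with field-of-study defaults.

    ``time_bin_seconds`` (3 s) and ``utility_bin_width`` (0.03) set the value
    grid resolution; ``consideration_size`` (5) the candidate-move count;
    ``ply_min``/``ply_max`` (15/75) the analysis window that strips opening
    book and degenerate endgame play; ``opponent_min_clock`` (60 s, 30 s for
    60+0) isolates the mover's clock from the opponent's time trouble;
    ``offer_scale_s`` (20 000) converts raw engine-time draws to offered
    deliberation seconds.  ``clock_convention`` selects how move time is
    recovered from successive clock readings (see analysis.compute_move_time).
    """

    time_bin_seconds: float = 3.0
    utility_bin_width: float = 0.03
    consideration_size: int = 5
    ply_min: int = 15
    ply_max: int = 75
    opponent_min_clock: float = 60.0
    opponent_min_clock_bullet: float = 30.0
    offer_scale_s: float = 20_000.0
    grid_min_count: int = 50
    motor_time: float = 0.0
    seed: int = 0
    clock_convention: str = "post_increment"

    def __post_init__(self) -> None:
        if self.time_bin_seconds <= 0:
            raise ValueError("time_bin_seconds must be > 0")
        if self.utility_bin_width <= 0:
            raise ValueError("utility_bin_width must be > 0")
        if self.consideration_size < 1:
            raise ValueError("consideration_size must be >= 1")
        if not self.ply_min < self.ply_max:
            raise ValueError("ply_min must be < ply_max")
        if self.clock_convention not in ("post_increment", "literal_paper"):
            raise ValueError(
                "clock_convention must be 'post_increment' or 'literal_paper'"
            )

    def min_opponent_clock(self, time_control: TimeControl) -> float:
        """Opponent-clock floor: lower for the 60+0 bullet setting."""
        if time_control.label == "60+0":
            return self.opponent_min_clock_bullet
        return self.opponent_min_clock


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML key:value config; unspecified keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key:value mapping")
    known = {f.name: f for f in fields(RunConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            logger.warning("config: unknown key %r ignored", key)
            continue
        ftype = known[key].type
        try:
            if ftype in ("int", int):
                if isinstance(value, float) and not value.is_integer():
                    raise ValueError
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        except (TypeError, ValueError):
            raise ValueError(f"config key {key!r}: invalid value {value!r}") from None
    return RunConfig(**kwargs)


def _columns(consideration_size: int) -> list[str]:
    cols = list(_BASE_COLUMNS)
    for k in range(1, consideration_size + 1):
        cols += [f"move_id_{k}", f"shallow_{k}", f"deep_{k}"]
    return cols


def write_move_table(records: Sequence[PositionRecord], path: str | Path) -> int:
    """Write records as CSV (documented column order); returns the row count."""
    k = max((len(r.consideration_set) for r in records), default=1)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_columns(k))
        for rec in records:
            row = [
                rec.game_id,
                rec.ply,
                repr(float(rec.active_elo)),
                repr(float(rec.opponent_clock)),
                repr(float(rec.clock_before)),
                repr(float(rec.clock_after)),
                rec.time_control.start_seconds,
                rec.time_control.increment_seconds,
                rec.outcome,
            ]
            for m in rec.consideration_set.moves:
                row += [m.move_id, repr(float(m.shallow)), repr(float(m.deep))]
            row += [""] * (3 * (k - len(rec.consideration_set)))
            writer.writerow(row)
    log_stage("write_move_table", len(records))
    return len(records)


def read_move_table(path: str | Path) -> list[PositionRecord]:
    """Read a move-table CSV; malformed rows are skipped and counted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[PositionRecord] = []
    n_skipped = 0
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _BASE_COLUMNS:
            if col not in header:
                raise ValueError(f"move table {path} is missing column {col!r}")
        k = 0
        while f"move_id_{k + 1}" in header:
            k += 1
        if k == 0:
            raise ValueError(f"move table {path} has no consideration-set columns")
        for row in reader:
            try:
                moves = []
                for j in range(1, k + 1):
                    mid = row[f"move_id_{j}"]
                    if mid == "" or mid is None:
                        break
                    moves.append(
                        MoveEval(
                            mid,
                            float(row[f"shallow_{j}"]),
                            float(row[f"deep_{j}"]),
                        )
                    )
                rec = PositionRecord(
                    game_id=row["game_id"],
                    ply=int(row["ply"]),
                    active_elo=float(row["elo"]),
                    opponent_clock=float(row["opp_clock"]),
                    clock_before=float(row["clock_before"]),
                    clock_after=float(row["clock_after"]),
                    time_control=TimeControl(int(row["tc_start"]), int(row["tc_inc"])),
                    outcome=row["outcome"],
                    consideration_set=ConsiderationSet(moves),
                )
            except (TypeError, ValueError):
                n_skipped += 1
                continue
            records.append(rec)
    total = len(records) + n_skipped
    if total and n_skipped > 0.5 * total:
        logger.warning(
            "read_move_table: %d of %d rows skipped (>50%%)", n_skipped, total
        )
    log_stage("read_move_table", len(records), n_skipped)
    return records


def records_to_frame(records: Sequence[PositionRecord]) -> "pd.DataFrame":
    """Flat DataFrame view of the record metadata (no consideration sets)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "game_id": [r.game_id for r in records],
            "ply": [r.ply for r in records],
            "elo": [r.active_elo for r in records],
            "opp_clock": [r.opponent_clock for r in records],
            "clock_before": [r.clock_before for r in records],
            "clock_after": [r.clock_after for r in records],
            "tc": [r.time_control.label for r in records],
            "outcome": [r.outcome for r in records],
        }
    )
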