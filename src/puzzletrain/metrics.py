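"""Time-based performance indicators computed from session logs.

Indicators follow the intervention's analysis plan: overall solving time in
minutes, average target search time in seconds (match-3), processing time
per item in seconds, and an improvement slope in seconds per session
(negative slope = getting faster). The match-3 search time is
operationalized as level duration per match made, and items are gems
cleared (match-3, quota of 10 per game object) or path cells (numberlink,
the full board).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ladder import Game
from .simulate import SessionLog

#: gems a player must clear to finish a match-3 level, per game object
MATCH3_QUOTA_PER_OBJECT = 10


@dataclass(frozen=True)
class PerformanceSummary:
    participant_id: str
    game: str
    overall_solving_time_min: float
    avg_target_search_time_s: float
    processing_time_per_item_s: float
    improvement_slope: float


def overall_solving_time(log: SessionLog) -> float:
    """Total time spent on levels across the intervention, in minutes."""
    attempts = log.attempts()
    if not attempts:
        raise ValueError("empty session log")
    return sum(e["duration_s"] for e in attempts) / 60.0


def _items_per_level(event: dict, game: Game) -> int:
    if game == Game.MATCH3:
        return MATCH3_QUOTA_PER_OBJECT * event["num_objects"]
    return event["board_size"] ** 2


def per_item_time(log: SessionLog, game: Game | str) -> float:
    """Total duration of solved levels divided by total items processed."""
    game = Game(game)
    solved = [e for e in log.attempts(game) if e["event"] == "level_complete"]
    items = sum(_items_per_level(e, game) for e in solved)
    if items == 0:
        raise ValueError("no items processed")
    return sum(e["duration_s"] for e in solved) / items


def avg_target_search_time(log: SessionLog) -> float:
    """Match-3 level duration per match made; a match clears three gems, so
    a level of quota q involves q/3 target searches."""
    solved = [e for e in log.attempts(Game.MATCH3) if e["event"] == "level_complete"]
    matches = sum(_items_per_level(e, Game.MATCH3) / 3 for e in solved)
    if matches == 0:
        raise ValueError("no matches made")
    return sum(e["duration_s"] for e in solved) / matches


def improvement_slope(series: Sequence[tuple[float, float]]) -> float:
    """Ordinary least-squares slope of time against session index
    (seconds per session; negative means improvement)."""
    if len(series) < 2:
        raise ValueError("need at least two points")
    x = np.asarray([s for s, _ in series], dtype=float)
    y = np.asarray([t for _, t in series], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constant session index: slope undefined")
    return float(np.polyfit(x, y, 1)[0])


def _session_index(event: dict, log: SessionLog) -> int:
    # sessions are identified by the calendar date of the event
    dates = sorted({e["timestamp"][:10] for e in log.events})
    return dates.index(event["timestamp"][:10]) + 1


def session_time_series(log: SessionLog, game: Game | str) -> list[tuple[int, float]]:
    """Per-session mean attempt duration of one game: the search-time series
    for match-3, the path-completion series for numberlink."""
    game = Game(game)
    per_session: dict[int, list[float]] = {}
    for e in log.attempts(game):
        if e["event"] != "level_complete":
            continue
        s = _session_index(e, log)
        if game == Game.MATCH3:
            value = e["duration_s"] / (_items_per_level(e, game) / 3)
        else:
            value = e["duration_s"]
        per_session.setdefault(s, []).append(value)
    return [(s, float(np.mean(v))) for s, v in sorted(per_session.items())]


def summarize_performance(log: SessionLog, participant_id: str, game: Game | str) -> PerformanceSummary:
    game = Game(game)
    series = session_time_series(log, game)
    return PerformanceSummary(
        participant_id=participant_id,
        game=game.value,
        overall_solving_time_min=overall_solving_time(log),
        avg_target_search_time_s=(
            avg_target_search_time(log) if game == Game.MATCH3 else float("nan")
        ),
        processing_time_per_item_s=per_item_time(log, game),
        improvement_slope=improvement_slope(series) if len(series) >= 2 else float("nan"),
    )


def metrics_table(logs: dict[str, SessionLog]) -> pd.DataFrame:
    """One row per (participant, game) with the four indicator columns."""
    rows = [
        vars(summarize_performance(log, pid, game))
        for pid, log in logs.items()
        for game in Game
    ]
    return pd.DataFrame(rows)
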