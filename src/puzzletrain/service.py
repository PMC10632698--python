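"""Level-adaptation service exposing the four put-level endpoints.

The tablet clients talk to the adaptation logic through four endpoints —
``match_three/putInitialLevel``, ``match_three/putNextLevel``,
``number_link/putInitialLevel`` and ``number_link/putNextLevel`` — with JSON
bodies. This module implements that contract as plain dict-in/dict-out
handlers so simulations and tests run in-process; ``puzzletrain serve``
wraps the same object in a minimal HTTP server. Every request is logged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .adaptive import (
    ATTEMPT_CAP_S,
    AdaptiveConfig,
    AttemptRecord,
    ConstantTimeModel,
    LevelStats,
    PretestScores,
    TimeModel,
    assign_initial_level,
    compute_level_stats,
    decide_next_level,
    next_level,
    predict_time,
)
from .ladder import DifficultyLadder, DifficultyLevel, Game, build_ladder

GAME_ROUTES = {"match_three": Game.MATCH3, "number_link": Game.NUMBERLINK}


class ServiceError(Exception):
    """Maps to a 4xx-style error payload."""

    def __init__(self, message: str, status: int = 400):
        super().__init__(message)
        self.status = status


@dataclass
class _ParticipantGameState:
    level: DifficultyLevel
    total_time: float = 0.0
    n_attempts: int = 0

    @property
    def running_mean(self) -> Optional[float]:
        return self.total_time / self.n_attempts if self.n_attempts else None


@dataclass
class AdaptiveService:
    """Holds one ladder, time model and σ table per game, plus per-player
    state (current level and running mean solving time)."""

    reference: Sequence[PretestScores]
    config: AdaptiveConfig = field(default_factory=AdaptiveConfig)
    ladders: dict[Game, DifficultyLadder] = field(default_factory=dict)
    models: dict[Game, TimeModel | ConstantTimeModel] = field(default_factory=dict)
    stats: dict[Game, dict[int, LevelStats]] = field(default_factory=dict)
    request_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for game in Game:
            self.ladders.setdefault(game, build_ladder(game))
            self.models.setdefault(game, ConstantTimeModel())
            self.stats.setdefault(game, {})
        self._state: dict[tuple[str, Game], _ParticipantGameState] = {}

    # -- wiring ----------------------------------------------------------

    def train(self, attempts: Iterable[AttemptRecord], fit=None, seed: int = 0) -> None:
        """Install a time model and σ table per game from pooled attempts.

        ``fit`` defaults to :func:`puzzletrain.adaptive.fit_time_model`.
        """
        from .adaptive import fit_time_model

        fit = fit or fit_time_model
        pooled = list(attempts)
        for game in Game:
            game_attempts = [a for a in pooled if a.game == game]
            if game_attempts:
                self.models[game] = fit(game_attempts, seed=seed)
                self.stats[game] = compute_level_stats(game_attempts)

    def sigma_for(self, game: Game, level: DifficultyLevel, t_p: float) -> float:
        stats = self.stats[game].get(level.index)
        if stats is not None and stats.n >= self.config.min_attempts_for_sigma:
            return stats.sigma
        return max(self.config.sigma_floor, 0.2 * t_p)

    def _record(self, game: Game, attempt: AttemptRecord) -> None:
        stats = self.stats[game]
        prev = stats.get(attempt.level.index)
        if prev is None:
            stats[attempt.level.index] = LevelStats(attempt.level.index, 1, attempt.t_m, 0.0)
        else:
            # streaming update of mean and sample SD
            n = prev.n + 1
            mean = prev.mean_time + (attempt.t_m - prev.mean_time) / n
            ss = prev.sigma**2 * (prev.n - 1) + (attempt.t_m - prev.mean_time) * (
                attempt.t_m - mean
            )
            sigma = (ss / (n - 1)) ** 0.5 if n >= 2 else 0.0
            stats[attempt.level.index] = LevelStats(attempt.level.index, n, mean, sigma)

    # -- endpoint handlers ------------------------------------------------

    def handle(self, endpoint: str, body: Mapping) -> dict:
        """Dispatch ``<game>/<operation>`` to its handler; errors become a
        4xx-style payload instead of an exception."""
        try:
            route, _, op = endpoint.partition("/")
            game = GAME_ROUTES.get(route)
            if game is None or op not in ("putInitialLevel", "putNextLevel"):
                raise ServiceError(f"unknown endpoint {endpoint!r}", status=404)
            if op == "putInitialLevel":
                response = self.put_initial_level(game, body)
            else:
                response = self.put_next_level(game, body)
        except ServiceError as exc:
            response = {"error": {"status": exc.status, "message": str(exc)}}
        self.request_log.append(
            {"endpoint": endpoint, "body": json.loads(json.dumps(body)), "response": response}
        )
        return response

    def put_initial_level(self, game: Game, body: Mapping) -> dict:
        try:
            participant = str(body["participant_id"])
            raw = body["pretest"]
            pretest = PretestScores(
                moca=float(raw["moca"]),
                tmt_a=float(raw["tmt_a"]),
                tmt_b=float(raw["tmt_b"]),
                smt=float(raw["smt"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ServiceError(f"malformed body: {exc}") from exc
        level = assign_initial_level(pretest, self.ladders[game], self.reference)
        self._state[(participant, game)] = _ParticipantGameState(level=level)
        return {"level_index": level.index}

    def put_next_level(self, game: Game, body: Mapping) -> dict:
        try:
            participant = str(body["participant_id"])
            raw = body["attempt"]
            level_index = int(raw["level_index"])
            t_m = float(raw["solving_time_s"])
            solved = bool(raw["solved"])
            session_index = int(raw.get("session_index", 1))
        except (KeyError, TypeError, ValueError) as exc:
            raise ServiceError(f"malformed body: {exc}") from exc
        ladder = self.ladders[game]
        if not (1 <= level_index <= ladder.max_index):
            raise ServiceError(f"level_index {level_index} outside ladder")
        if t_m <= 0:
            raise ServiceError("solving_time_s must be positive")
        level = ladder[level_index]

        state = self._state.setdefault(
            (participant, game), _ParticipantGameState(level=level)
        )
        history = {"session_index": session_index}
        if state.running_mean is not None:
            history["running_mean_time"] = state.running_mean

        if not solved:
            # unsolved/timeout attempts count at the cap and force a retreat
            t_m = ATTEMPT_CAP_S
            decision = -1
        else:
            with warnings.catch_warnings():
                # ladder edges may sit outside the pooled training range;
                # extrapolating there is expected in the closed loop
                warnings.simplefilter("ignore", UserWarning)
                t_p = predict_time(self.models[game], level, history)
            sigma = self.sigma_for(game, level, t_p)
            decision = decide_next_level(t_m, t_p, sigma, self.config.c)

        attempt = AttemptRecord(
            participant_id=participant,
            game=game,
            level=level,
            t_m=t_m,
            solved=solved,
            session_index=session_index,
        )
        self._record(game, attempt)
        state.total_time += t_m
        state.n_attempts += 1
        state.level = next_level(ladder, level, decision)
        return {"decision": decision, "next_level_index": state.level.index}

    def current_level(self, participant_id: str, game: Game) -> Optional[DifficultyLevel]:
        state = self._state.get((participant_id, game))
        return state.level if state else None


def write_request_log(service: AdaptiveService, path) -> int:
    """Dump the request log as JSONL; returns the number of lines."""
    with open(path, "w") as fh:
        for entry in service.request_log:
            fh.write(json.dumps(entry) + "\n")
    return len(service.request_log)
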