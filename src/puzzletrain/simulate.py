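"""Synthetic players for exercising the adaptation loop end to end.

Human participants are replaced by profiles with three traits: a skill
multiplier (smaller = faster), a per-session fractional speedup (practice
effect) and lognormal attempt-to-attempt noise. A player's solving time for
a level is

    t_m = base(level) · skill · (1 − learning_rate)^(session − 1) · exp(ε),
    ε ~ Normal(0, noise_sd²),   base(level) = 20 s + 15 s · (index − 1)

Times grow with difficulty, shrink with practice, and are right-skewed and
positive — the standard shape of response-time data. The intervention
schedule mirrors the training protocol: 8 weeks, 3 sessions per week, both
games per session, 10 minutes per game and 20 minutes per day at most.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .adaptive import ATTEMPT_CAP_S, AttemptRecord, PretestScores
from .ladder import DifficultyLadder, DifficultyLevel, Game, build_ladder
from .service import AdaptiveService

BASE_INTERCEPT_S = 20.0
BASE_SLOPE_S = 15.0

_START_DATE = _dt.date(2023, 1, 2)  # a Monday


def base_solve_time(level: DifficultyLevel) -> float:
    """Reference solving time of an average unpracticed player (seconds)."""
    return BASE_INTERCEPT_S + BASE_SLOPE_S * (level.index - 1)


@dataclass(frozen=True)
class PlayerProfile:
    participant_id: str
    skill: float = 1.0  # multiplier, > 0, smaller = faster
    learning_rate: float = 0.02  # per-session fractional speedup, in [0, 0.1]
    noise_sd: float = 0.2  # SD of log-time noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.skill <= 0:
            raise ValueError("skill must be positive")
        if not (0 <= self.learning_rate <= 0.1):
            raise ValueError("learning_rate outside [0, 0.1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def pretest(self) -> PretestScores:
        """Pretest scores consistent with the profile's skill: completion
        times scale with the skill multiplier around typical values."""
        return PretestScores(
            moca=28,
            tmt_a=32.0 * self.skill,
            tmt_b=92.0 * self.skill,
            smt=19.0 * self.skill,
        )


@dataclass(frozen=True)
class InterventionSchedule:
    weeks: int = 8
    sessions_per_week: int = 3
    per_game_cap_s: float = 600.0  # 10 min per game
    daily_cap_s: float = 1200.0  # 20 min per day

    def __post_init__(self) -> None:
        if self.sessions_per_week < 3:
            raise ValueError("protocol requires at least 3 sessions per week")
        if self.per_game_cap_s <= 0 or self.daily_cap_s <= 0:
            raise ValueError("caps must be positive")

    @property
    def n_sessions(self) -> int:
        return self.weeks * self.sessions_per_week

    def session_date(self, session_index: int) -> _dt.date:
        week, slot = divmod(session_index - 1, self.sessions_per_week)
        day = min(slot * (7 // self.sessions_per_week), 6)
        return _START_DATE + _dt.timedelta(days=week * 7 + day)


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def simulate_solve_time(
    profile: PlayerProfile,
    level: DifficultyLevel,
    session_index: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """One noisy solving time draw (seconds)."""
    if rng is None:
        rng = _rng(0 if seed is None else seed, profile.seed)
    eps = rng.normal(0.0, profile.noise_sd) if profile.noise_sd > 0 else 0.0
    return (
        base_solve_time(level)
        * profile.skill
        * (1.0 - profile.learning_rate) ** (session_index - 1)
        * float(np.exp(eps))
    )


class SessionLog:
    """Event log of one player's intervention, one JSON object per event.

    Events carry {timestamp, participant_id, game, event, level_index,
    board_size, num_objects, duration_s, decision}; ``event`` is one of
    level_start, level_complete, timeout, session_end.
    """

    def __init__(self, events: Optional[list[dict]] = None):
        self.events: list[dict] = events or []

    def append(self, **event) -> None:
        self.events.append(event)

    def attempts(self, game: Optional[Game | str] = None) -> list[dict]:
        game = None if game is None else Game(game).value
        return [
            e
            for e in self.events
            if e["event"] in ("level_complete", "timeout")
            and (game is None or e["game"] == game)
        ]

    def trajectory(self, game: Game | str) -> list[int]:
        """Level index of every attempt of one game, in play order."""
        return [e["level_index"] for e in self.attempts(game)]

    def to_jsonl(self, path) -> int:
        with open(path, "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event) + "\n")
        return len(self.events)

    @classmethod
    def from_jsonl(cls, path) -> "SessionLog":
        with open(path) as fh:
            return cls([json.loads(line) for line in fh if line.strip()])


def simulate_intervention(
    profile: PlayerProfile,
    schedule: InterventionSchedule,
    service: AdaptiveService,
    engines: Optional[dict] = None,
    seed: int = 0,
) -> SessionLog:
    """Play the full intervention through the adaptation service.

    Each session plays both games. Within a game the player keeps solving
    levels until the 10-minute game budget runs out; every finished attempt
    is routed through putNextLevel. Attempts that would exceed the
    per-attempt cap are logged as timeouts (the service retreats one level);
    an attempt that merely does not fit in the remaining session budget is
    abandoned and never scored. ``engines`` may map games to board
    generators (used to realize a concrete board per attempt); difficulty
    bookkeeping does not depend on them.
    """
    log = SessionLog()
    rng = _rng(seed, profile.seed)
    for route, game in (("match_three", Game.MATCH3), ("number_link", Game.NUMBERLINK)):
        response = service.handle(
            f"{route}/putInitialLevel",
            {"participant_id": profile.participant_id, "pretest": vars(profile.pretest)},
        )
        if "error" in response:
            raise RuntimeError(f"putInitialLevel failed: {response['error']}")

    for session in range(1, schedule.n_sessions + 1):
        date = schedule.session_date(session)
        clock = _dt.datetime.combine(date, _dt.time(9, 0))
        day_budget = schedule.daily_cap_s
        for route, game in (("match_three", Game.MATCH3), ("number_link", Game.NUMBERLINK)):
            budget = min(schedule.per_game_cap_s, day_budget)
            played = 0.0
            while budget > 0:
                level = service.current_level(profile.participant_id, game)
                if engines and game in engines:
                    engines[game](level, int(rng.integers(2**31)))
                t_raw = simulate_solve_time(profile, level, session, rng=rng)
                timeout = t_raw > ATTEMPT_CAP_S
                duration = ATTEMPT_CAP_S if timeout else t_raw
                if duration > budget:
                    if not timeout:
                        break  # player stops; unfinished level is not scored
                    duration = budget
                log.append(
                    timestamp=clock.isoformat(),
                    participant_id=profile.participant_id,
                    game=game.value,
                    event="level_start",
                    level_index=level.index,
                    board_size=level.board_size,
                    num_objects=level.num_objects,
                    duration_s=0.0,
                    decision=None,
                )
                response = service.handle(
                    f"{route}/putNextLevel",
                    {
                        "participant_id": profile.participant_id,
                        "attempt": {
                            "level_index": level.index,
                            "solving_time_s": duration,
                            "solved": not timeout,
                            "session_index": session,
                        },
                    },
                )
                if "error" in response:
                    raise RuntimeError(f"putNextLevel failed: {response['error']}")
                clock += _dt.timedelta(seconds=duration)
                log.append(
                    timestamp=clock.isoformat(),
                    participant_id=profile.participant_id,
                    game=game.value,
                    event="timeout" if timeout else "level_complete",
                    level_index=level.index,
                    board_size=level.board_size,
                    num_objects=level.num_objects,
                    duration_s=duration,
                    decision=response["decision"],
                )
                budget -= duration
                played += duration
            day_budget -= played
            log.append(
                timestamp=clock.isoformat(),
                participant_id=profile.participant_id,
                game=game.value,
                event="session_end",
                level_index=service.current_level(profile.participant_id, game).index,
                board_size=None,
                num_objects=None,
                duration_s=played,
                decision=None,
            )
    return log


def sample_profiles(n_players: int, seed: int = 0) -> list[PlayerProfile]:
    """Draw player profiles from the study priors: skill ~ LogNormal(0, 0.25),
    learning_rate ~ Uniform(0, 0.04), noise_sd ~ Uniform(0.1, 0.3)."""
    if n_players < 1:
        raise ValueError("need at least one player")
    rng = _rng(seed, 101)
    profiles = []
    for i in range(n_players):
        profiles.append(
            PlayerProfile(
                participant_id=f"S{i + 1:02d}",
                skill=float(rng.lognormal(0.0, 0.25)),
                learning_rate=float(rng.uniform(0.0, 0.04)),
                noise_sd=float(rng.uniform(0.1, 0.3)),
                seed=seed + i + 1,
            )
        )
    return profiles


def generate_training_dataset(
    n_players: int,
    schedule: InterventionSchedule = InterventionSchedule(),
    seed: int = 0,
    ladder: Optional[DifficultyLadder] = None,
) -> list[AttemptRecord]:
    """Pooled attempts emulating pilot training data, for fitting the time
    model before any adaptive play.

    Each player follows a bounded, mostly ascending random level walk
    (advance 50%, stay 30%, retreat 20%) with three attempts per game per
    session; times come from :func:`simulate_solve_time`.
    """
    profiles = sample_profiles(n_players, seed=seed)
    ladders = {g: ladder or build_ladder(g) for g in Game}
    rng = _rng(seed, 202)
    attempts: list[AttemptRecord] = []
    for profile in profiles:
        for game in Game:
            lad = ladders[game]
            index = int(rng.integers(1, lad.max_index + 1))
            for session in range(1, schedule.n_sessions + 1):
                for _ in range(3):
                    level = lad[index]
                    t_m = simulate_solve_time(profile, level, session, rng=rng)
                    t_m = min(t_m, ATTEMPT_CAP_S)
                    attempts.append(
                        AttemptRecord(
                            participant_id=profile.participant_id,
                            game=game,
                            level=level,
                            t_m=t_m,
                            solved=t_m < ATTEMPT_CAP_S,
                            session_index=session,
                            timestamp=schedule.session_date(session).isoformat(),
                        )
                    )
                step = int(rng.choice([-1, 0, 1], p=[0.2, 0.3, 0.5]))
                index = min(max(index + step, 1), lad.max_index)
    return attempts
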