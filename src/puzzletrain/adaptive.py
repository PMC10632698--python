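"""AI-based dynamic difficulty adaptation.

The adaptation loop models a player's solving time. A regressor (selected
among candidate families by training adjusted R²) predicts the time ``t_p``
a player should need for a level; after the player solves it in measured
time ``t_m``, the level predictor compares the two against a band of width
``c·σ``, where σ is the standard deviation of all recorded games at that
difficulty level and ``c`` is a constant in (0, 1):

    decision = −1 (retreat)  if t_m > t_p + c·σ
               +1 (advance)  if t_m < t_p − c·σ
                0 (stay)     otherwise

The initial level is assigned from pretest scores (MoCA, Trail Making Test
A, Snellgrove Maze Task) by ranking a composite of the three against a
reference population and mapping its quintile onto the ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import VotingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .ladder import DifficultyLadder, DifficultyLevel, Game

FEATURE_NAMES = (
    "board_size",
    "num_objects",
    "level_index",
    "session_index",
    "running_mean_time",
)

#: neutral running-mean prior for a player with no history (seconds);
#: roughly the base solving time mid-ladder
DEFAULT_RUNNING_MEAN_S = 60.0

#: per-game, per-attempt time cap (seconds); unsolved attempts are recorded
#: at the cap and force a retreat decision
ATTEMPT_CAP_S = 600.0


@dataclass(frozen=True)
class PretestScores:
    """Pretest battery used for the initial level: MoCA (0-30, higher is
    better), TMT-A and SMT completion times in seconds (lower is better)."""

    moca: float
    tmt_a: float
    tmt_b: float
    smt: float

    def __post_init__(self) -> None:
        if not (0 < self.moca <= 30):
            raise ValueError(f"moca {self.moca} outside (0, 30]")
        for name in ("tmt_a", "tmt_b", "smt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AttemptRecord:
    participant_id: str
    game: Game
    level: DifficultyLevel
    t_m: float
    solved: bool
    session_index: int
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.t_m <= 0:
            raise ValueError("solving time must be positive")
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")


@dataclass(frozen=True)
class AdaptiveConfig:
    c: float = 0.5
    sigma_floor: float = 2.0
    min_attempts_for_sigma: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.c < 1):
            raise ValueError(f"c must lie in (0, 1), got {self.c}")
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be >= 0")


@dataclass(frozen=True)
class LevelStats:
    level_index: int
    n: int
    mean_time: float
    sigma: float


# -- level predictor -----------------------------------------------------


def decide_next_level(t_m: float, t_p: float, sigma: float, c: float) -> int:
    """Threshold decision: −1 retreat, 0 stay, +1 advance.

    Inequalities are strict: measured times landing exactly on a band edge
    keep the level unchanged.
    """
    if t_m <= 0 or t_p <= 0:
        raise ValueError("times must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (0 < c < 1):
        raise ValueError("c must lie in (0, 1)")
    if t_m > t_p + c * sigma:
        return -1
    if t_m < t_p - c * sigma:
        return 1
    return 0


def next_level(ladder: DifficultyLadder, current: DifficultyLevel, decision: int) -> DifficultyLevel:
    """Shift the ladder index by the decision, clamped to the ladder ends."""
    if decision not in (-1, 0, 1):
        raise ValueError(f"decision must be -1, 0 or +1, got {decision}")
    target = min(max(current.index + decision, 1), ladder.max_index)
    return ladder[target]


# -- per-level spread ----------------------------------------------------


def compute_level_stats(attempts: Iterable[AttemptRecord]) -> dict[int, LevelStats]:
    """Pooled per-level summary of measured times across all participants."""
    by_level: dict[int, list[float]] = {}
    for a in attempts:
        by_level.setdefault(a.level.index, []).append(a.t_m)
    out = {}
    for idx, times in sorted(by_level.items()):
        arr = np.asarray(times, dtype=float)
        sigma = float(arr.std(ddof=1)) if len(arr) >= 2 else 0.0
        out[idx] = LevelStats(idx, len(arr), float(arr.mean()), sigma)
    return out


def level_sd(
    attempts: Iterable[AttemptRecord],
    level: DifficultyLevel,
    config: AdaptiveConfig = AdaptiveConfig(),
    t_p: Optional[float] = None,
) -> float:
    """Sample SD (n−1 denominator) of measured times at ``level``.

    With fewer than ``config.min_attempts_for_sigma`` attempts the band
    would collapse and thrash, so the fallback max(sigma_floor, 0.2·t_p)
    is returned instead.
    """
    times = [a.t_m for a in attempts if a.level.index == level.index]
    if len(times) >= config.min_attempts_for_sigma:
        return float(np.asarray(times, dtype=float).std(ddof=1))
    fallback = config.sigma_floor
    if t_p is not None:
        fallback = max(fallback, 0.2 * t_p)
    return float(fallback)


# -- time predictor ------------------------------------------------------


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination: 1 − (1−R²)(n−1)/(n−p−1)."""
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def default_candidates(seed: int = 0, n_samples: int = 100) -> list[tuple[str, object]]:
    """Candidate regressor families, in tie-break order.

    A plain linear model, a k-nearest-mean smoother, and an averaging
    committee of heterogeneous estimators (the committee plays the role of
    the voting/neural families often used for this task while staying
    deterministic under the seed).
    """
    k = max(1, min(5, n_samples))
    linear = LinearRegression()
    knn = make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=k))
    committee = VotingRegressor(
        [
            ("linear", LinearRegression()),
            ("knn", make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=k))),
            ("tree", DecisionTreeRegressor(max_depth=6, random_state=seed)),
        ]
    )
    return [("linear", linear), ("k_nearest_mean", knn), ("committee", committee)]


def attempts_to_features(attempts: Sequence[AttemptRecord]) -> pd.DataFrame:
    """Feature matrix for the time model.

    ``running_mean_time`` is the mean of the participant's earlier recorded
    attempts (in record order); a participant's first attempt uses a neutral
    prior so the target never leaks into its own features.
    """
    rows = []
    running: dict[str, tuple[float, int]] = {}
    for a in attempts:
        total, n = running.get(a.participant_id, (0.0, 0))
        mean = total / n if n else DEFAULT_RUNNING_MEAN_S
        rows.append(
            {
                "board_size": a.level.board_size,
                "num_objects": a.level.num_objects,
                "level_index": a.level.index,
                "session_index": a.session_index,
                "running_mean_time": mean,
                "t_m": a.t_m,
            }
        )
        running[a.participant_id] = (total + a.t_m, n + 1)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["t_m"])


@dataclass
class TimeModel:
    """Fitted solving-time predictor with its selection metadata."""

    estimator: object
    selected: str
    scores: dict[str, float]  # training adjusted R² per candidate
    n: int
    p: int = len(FEATURE_NAMES)
    level_index_range: tuple[int, int] = (1, 25)

    def predict(self, features: Mapping[str, float]) -> float:
        x = pd.DataFrame([{k: float(features[k]) for k in FEATURE_NAMES}])
        return float(self.estimator.predict(x)[0])


class ConstantTimeModel:
    """Bootstrap predictor used before any training data exists: predicts a
    fixed base-time curve in the level index."""

    def __init__(self, intercept: float = 20.0, slope: float = 15.0):
        self.selected = "bootstrap"
        self.scores: dict[str, float] = {}
        self.intercept = intercept
        self.slope = slope
        self.level_index_range = (1, 10**9)

    def predict(self, features: Mapping[str, float]) -> float:
        return self.intercept + self.slope * (float(features["level_index"]) - 1)


def fit_time_model(
    attempts: Sequence[AttemptRecord],
    candidates: Optional[list[tuple[str, object]]] = None,
    seed: int = 0,
) -> TimeModel:
    """Fit every candidate family and keep the one with the highest training
    adjusted R² (ties broken by candidate order)."""
    if len(attempts) < 20:
        raise ValueError(f"need at least 20 attempts, got {len(attempts)}")
    levels = {a.level.index for a in attempts}
    if len(levels) < 2:
        raise ValueError("attempts must span at least 2 difficulty levels")
    frame = attempts_to_features(attempts)
    X = frame[list(FEATURE_NAMES)]
    y = frame["t_m"].to_numpy()
    if np.allclose(y.var(), 0):
        raise ValueError("degenerate design: zero variance in solving times")
    if candidates is None:
        candidates = default_candidates(seed=seed, n_samples=len(attempts))
    n, p = len(y), len(FEATURE_NAMES)
    scores: dict[str, float] = {}
    fitted: dict[str, object] = {}
    for name, est in candidates:
        est.fit(X, y)
        r2 = float(est.score(X, y))
        scores[name] = adjusted_r2(r2, n, p)
        fitted[name] = est
    best = max(scores, key=lambda name: (scores[name], -list(scores).index(name)))
    return TimeModel(
        estimator=fitted[best],
        selected=best,
        scores=scores,
        n=n,
        level_index_range=(min(levels), max(levels)),
    )


def predict_time(
    model: TimeModel | ConstantTimeModel,
    level: DifficultyLevel,
    history_features: Optional[Mapping[str, float]] = None,
) -> float:
    """Predicted solving time t_p for a level, clamped below at 1 s.

    ``history_features`` may supply ``session_index`` and
    ``running_mean_time``; missing entries fall back to session 1 and the
    neutral running-mean prior.
    """
    history = dict(history_features or {})
    features = {
        "board_size": level.board_size,
        "num_objects": level.num_objects,
        "level_index": level.index,
        "session_index": history.get("session_index", 1),
        "running_mean_time": history.get("running_mean_time", DEFAULT_RUNNING_MEAN_S),
    }
    lo, hi = model.level_index_range
    if not (lo <= level.index <= hi):
        warnings.warn(
            f"level index {level.index} outside training range [{lo}, {hi}]; "
            "prediction is an extrapolation",
            stacklevel=2,
        )
    return max(1.0, float(model.predict(features)))


# -- initial level assignment -------------------------------------------


def pretest_composite(
    pretest: PretestScores, reference: Sequence[PretestScores]
) -> float:
    """Composite ability score: mean of z-scores of (−TMT-A, −SMT, MoCA)
    standardized against the reference population. Higher means faster."""
    if not reference:
        raise ValueError("reference population must be nonempty")

    def z(value: float, values: np.ndarray) -> float:
        sd = values.std(ddof=1) if len(values) >= 2 else 0.0
        if sd == 0:
            return 0.0
        return (value - values.mean()) / sd

    tmt_a = np.array([p.tmt_a for p in reference], dtype=float)
    smt = np.array([p.smt for p in reference], dtype=float)
    moca = np.array([p.moca for p in reference], dtype=float)
    return float(
        np.mean([-z(pretest.tmt_a, tmt_a), -z(pretest.smt, smt), z(pretest.moca, moca)])
    )


def assign_initial_level(
    pretest: PretestScores,
    ladder: DifficultyLadder,
    reference: Sequence[PretestScores],
) -> DifficultyLevel:
    """Map pretest scores to a starting level.

    The pretest composite's percentile rank within the reference population
    selects one of five bands of the ladder; the starting level is the
    lowest index of that band, so better pretests start weakly higher and
    nobody starts at the very top of a band.
    """
    composite = pretest_composite(pretest, reference)
    ref = np.array([pretest_composite(p, reference) for p in reference])
    n = len(ref)
    percentile = (np.sum(ref < composite) + 0.5 * np.sum(ref == composite)) / n
    band = min(4, int(percentile * 5))
    index = 1 + (band * ladder.max_index) // 5
    return ladder[index]
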