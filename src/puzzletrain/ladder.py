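"""Difficulty ladders for the two puzzle games.

A difficulty level is a (board size, object count) combination. Both games
draw board sizes and object counts from 4..8, giving a 25-level ladder when
the full ranges are used. Levels are ordered lexicographically by
(board_size, num_objects): board growth dominates perceived difficulty, so
all object counts at one size precede the next size.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

SIZE_MIN, SIZE_MAX = 4, 8
OBJECTS_MIN, OBJECTS_MAX = 4, 8


class Game(str, Enum):
    MATCH3 = "match3"
    NUMBERLINK = "numberlink"


@dataclass(frozen=True, order=True)
class DifficultyLevel:
    """One rung of a ladder: ``index`` is 1-based position within its ladder."""

    index: int
    board_size: int
    num_objects: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"level index must be >= 1, got {self.index}")
        if not (SIZE_MIN <= self.board_size <= SIZE_MAX):
            raise ValueError(f"board_size {self.board_size} outside [{SIZE_MIN}, {SIZE_MAX}]")
        if not (OBJECTS_MIN <= self.num_objects <= OBJECTS_MAX):
            raise ValueError(f"num_objects {self.num_objects} outside [{OBJECTS_MIN}, {OBJECTS_MAX}]")


@dataclass(frozen=True)
class DifficultyLadder:
    game: Game
    levels: tuple[DifficultyLevel, ...]

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, index: int) -> DifficultyLevel:
        """Look up a level by its 1-based ladder index."""
        if not (1 <= index <= len(self.levels)):
            raise IndexError(f"level index {index} outside [1, {len(self.levels)}]")
        return self.levels[index - 1]

    @property
    def max_index(self) -> int:
        return len(self.levels)


def build_ladder(
    game: Game | str,
    s_range: Iterable[int] = range(SIZE_MIN, SIZE_MAX + 1),
    g_range: Iterable[int] = range(OBJECTS_MIN, OBJECTS_MAX + 1),
) -> DifficultyLadder:
    """Build a ladder over the cross product of board sizes and object counts.

    Levels are sorted by (board_size, num_objects); with the full 4..8 ranges
    the ladder has 25 levels and index = (s - 4) * 5 + (g - 4) + 1.
    """
    sizes: Sequence[int] = sorted(set(s_range))
    objects: Sequence[int] = sorted(set(g_range))
    if not sizes or not objects:
        raise ValueError("s_range and g_range must be nonempty")
    for s in sizes:
        if not (SIZE_MIN <= s <= SIZE_MAX):
            raise ValueError(f"board size {s} outside [{SIZE_MIN}, {SIZE_MAX}]")
    for g in objects:
        if not (OBJECTS_MIN <= g <= OBJECTS_MAX):
            raise ValueError(f"object count {g} outside [{OBJECTS_MIN}, {OBJECTS_MAX}]")
    levels = tuple(
        DifficultyLevel(index=i + 1, board_size=s, num_objects=g)
        for i, (s, g) in enumerate((s, g) for s in sizes for g in objects)
    )
    return DifficultyLadder(game=Game(game), levels=levels)
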