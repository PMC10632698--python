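"""Match-3 board engine: generation, match detection, swaps, cascades.

Boards are rectangular grids of gem codes ``1..num_types`` (``0`` marks an
empty cell mid-cascade). Coordinates are 0-based ``(row, col)`` with row 0 at
the top; gravity pulls gems toward higher row indices. A move swaps two
orthogonally adjacent gems and is valid only if it creates at least one run
of three or more identical codes in a row or column. Resolving a swap clears
all runs, drops gems within their columns, refills from a seeded stream and
repeats until the board is quiescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .ladder import DifficultyLevel

EMPTY = 0

#: retries allowed when resampling cells during board generation
GENERATION_RETRY_CAP = 1_000


class Match(NamedTuple):
    """A maximal run of >= 3 equal codes: ``orientation`` is 'h' or 'v'."""

    orientation: str
    start: tuple[int, int]
    length: int
    code: int

    @property
    def cells(self) -> tuple[tuple[int, int], ...]:
        r, c = self.start
        if self.orientation == "h":
            return tuple((r, c + i) for i in range(self.length))
        return tuple((r + i, c) for i in range(self.length))


class SwapMove(NamedTuple):
    cell_a: tuple[int, int]
    cell_b: tuple[int, int]


@dataclass
class GemGrid:
    width: int
    height: int
    num_types: int
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (self.height, self.width):
            raise ValueError(
                f"cells shape {self.cells.shape} != (height={self.height}, width={self.width})"
            )
        if self.num_types < 2:
            raise ValueError("need at least 2 gem types")

    @classmethod
    def from_level(cls, level: DifficultyLevel, cells: np.ndarray) -> "GemGrid":
        return cls(
            width=level.board_size,
            height=level.board_size,
            num_types=level.num_objects,
            cells=cells,
        )

    def copy(self) -> "GemGrid":
        return GemGrid(self.width, self.height, self.num_types, self.cells.copy())

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.height and 0 <= c < self.width

    def is_full(self) -> bool:
        return bool(np.all(self.cells != EMPTY))

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        return "\n".join(" ".join(str(v) for v in row) for row in self.cells)

    @classmethod
    def from_text(cls, text: str, num_types: int) -> "GemGrid":
        rows = [[int(v) for v in line.split()] for line in text.strip().splitlines()]
        arr = np.array(rows, dtype=np.int64)
        return cls(width=arr.shape[1], height=arr.shape[0], num_types=num_types, cells=arr)

    def to_json(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "num_types": self.num_types,
            "cells": self.cells.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GemGrid":
        return cls(
            width=obj["width"],
            height=obj["height"],
            num_types=obj["num_types"],
            cells=np.array(obj["cells"], dtype=np.int64),
        )


@dataclass
class CascadeResult:
    final_grid: GemGrid
    cascades: int
    cleared: int
    per_round_matches: list[list[Match]] = field(default_factory=list)


def find_matches(grid: GemGrid) -> list[Match]:
    """All maximal horizontal and vertical runs of length >= 3.

    Runs longer than three cells are reported once; a cell shared by a row
    run and a column run appears in both descriptors. Output order is
    deterministic: horizontal runs in row-major order, then vertical runs in
    column-major order.
    """
    if not grid.is_full():
        raise ValueError("grid has empty cells; resolve cascades before scanning")
    matches: list[Match] = []
    cells = grid.cells
    for r in range(grid.height):
        matches.extend(_scan_line(cells[r, :], lambda c: (r, c), "h"))
    for c in range(grid.width):
        matches.extend(_scan_line(cells[:, c], lambda r: (r, c), "v"))
    return matches


def _scan_line(line: np.ndarray, to_cell, orientation: str) -> list[Match]:
    out: list[Match] = []
    n = len(line)
    start = 0
    for i in range(1, n + 1):
        if i == n or line[i] != line[start]:
            if i - start >= 3:
                out.append(Match(orientation, to_cell(start), i - start, int(line[start])))
            start = i
    return out


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


def is_valid_swap(grid: GemGrid, move: SwapMove) -> bool:
    """True iff the cells hold different codes and swapping them creates a
    match. Cells that are out of bounds or not orthogonally adjacent are a
    malformed move and raise."""
    a, b = move.cell_a, move.cell_b
    if not (grid.in_bounds(a) and grid.in_bounds(b)):
        raise ValueError(f"swap cells {a}, {b} out of bounds")
    if not _adjacent(a, b):
        raise ValueError(f"swap cells {a}, {b} are not orthogonally adjacent")
    if grid.cells[a] == grid.cells[b]:
        return False
    swapped = grid.cells.copy()
    swapped[a], swapped[b] = swapped[b], swapped[a]
    trial = GemGrid(grid.width, grid.height, grid.num_types, swapped)
    return len(find_matches(trial)) > 0


def list_available_moves(grid: GemGrid) -> list[SwapMove]:
    """Every valid swap, in row-major order pairing each cell with its right
    and down neighbour."""
    moves: list[SwapMove] = []
    for r in range(grid.height):
        for c in range(grid.width):
            for dr, dc in ((0, 1), (1, 0)):
                b = (r + dr, c + dc)
                if grid.in_bounds(b):
                    move = SwapMove((r, c), b)
                    if is_valid_swap(grid, move):
                        moves.append(move)
    return moves


def _refill_rng(seed: int) -> np.random.Generator:
    # Philox is counter-based: a fresh generator per resolution makes replays
    # of the same (grid, move, seed) bit-identical.
    return np.random.Generator(np.random.Philox(key=seed))


def apply_swap(grid: GemGrid, move: SwapMove, seed: int) -> CascadeResult:
    """Apply a valid swap and resolve all cascades.

    Each round clears the union of matched cells, drops gems within columns
    (toward higher rows) and refills the vacated top cells from a uniform
    seeded stream over ``1..num_types``; rounds repeat until no match remains.
    """
    if not is_valid_swap(grid, move):
        raise ValueError(f"invalid swap {move}")
    rng = _refill_rng(seed)
    work = grid.copy()
    a, b = move.cell_a, move.cell_b
    work.cells[a], work.cells[b] = work.cells[b], work.cells[a]

    cascades = 0
    cleared = 0
    rounds: list[list[Match]] = []
    while True:
        matches = find_matches(work)
        if not matches:
            break
        cascades += 1
        rounds.append(matches)
        hit = set()
        for m in matches:
            hit.update(m.cells)
        cleared += len(hit)
        for cell in hit:
            work.cells[cell] = EMPTY
        _drop_and_refill(work, rng)
    return CascadeResult(final_grid=work, cascades=cascades, cleared=cleared, per_round_matches=rounds)


def _drop_and_refill(grid: GemGrid, rng: np.random.Generator) -> None:
    for c in range(grid.width):
        col = grid.cells[:, c]
        kept = col[col != EMPTY]
        n_new = grid.height - len(kept)
        if n_new:
            new = rng.integers(1, grid.num_types + 1, size=n_new)
            grid.cells[:, c] = np.concatenate([new, kept])


def generate_board(level: DifficultyLevel, seed: int) -> GemGrid:
    """Generate a quiescent board with at least one available move.

    Rejection sampling: cells that complete a run of three are resampled in
    place; a board with no valid move is discarded and regenerated. Identical
    seeds give identical boards.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    s, g = level.board_size, level.num_objects
    for _attempt in range(GENERATION_RETRY_CAP):
        cells = np.zeros((s, s), dtype=np.int64)
        ok = True
        for r in range(s):
            for c in range(s):
                for _retry in range(GENERATION_RETRY_CAP):
                    code = int(rng.integers(1, g + 1))
                    if _completes_run(cells, r, c, code):
                        continue
                    cells[r, c] = code
                    break
                else:
                    ok = False
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        grid = GemGrid(width=s, height=s, num_types=g, cells=cells)
        if list_available_moves(grid):
            return grid
    raise RuntimeError(f"board generation failed for size={s}, num_types={g}")


def _completes_run(cells: np.ndarray, r: int, c: int, code: int) -> bool:
    # only cells above and to the left are placed so far
    if c >= 2 and cells[r, c - 1] == code and cells[r, c - 2] == code:
        return True
    if r >= 2 and cells[r - 1, c] == code and cells[r - 2, c] == code:
        return True
    return False
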