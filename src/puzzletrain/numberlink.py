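"""Numberlink puzzle engine: generation, solving, validation, counting.

A puzzle places colored endpoint pairs on an s×s grid; a solution joins each
pair by an orthogonal path such that no cell is used twice and every cell of
the grid is covered ("full fill"). Generation works backwards: a random
Hamiltonian path over the grid is cut into the required number of segments,
the segment termini become the endpoint pairs, and the segments themselves
are the witness solution — so every emitted puzzle is solvable by
construction. Solution uniqueness is not enforced.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional

import numpy as np

from .ladder import DifficultyLevel

Cell = tuple[int, int]

#: resamples allowed before generation reports an infeasible configuration
GENERATION_RETRY_CAP = 10_000

_NEIGHBOR_OFFSETS = ((-1, 0), (0, -1), (0, 1), (1, 0))


class LinkPair(NamedTuple):
    color: int
    a: Cell
    b: Cell


@dataclass(frozen=True)
class LinkPuzzle:
    size: int
    pairs: tuple[LinkPair, ...]

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("grid must be at least 2x2")
        seen: set[Cell] = set()
        for color, a, b in self.pairs:
            for cell in (a, b):
                r, c = cell
                if not (0 <= r < self.size and 0 <= c < self.size):
                    raise ValueError(f"endpoint {cell} out of bounds for size {self.size}")
                if cell in seen:
                    raise ValueError(f"endpoint {cell} used by more than one pair")
                seen.add(cell)

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        """Text grid: '.' for empty cells, letters (A=color 1) at endpoints."""
        grid = [["." for _ in range(self.size)] for _ in range(self.size)]
        for color, a, b in self.pairs:
            letter = string.ascii_uppercase[color - 1]
            grid[a[0]][a[1]] = letter
            grid[b[0]][b[1]] = letter
        return "\n".join("".join(row) for row in grid)

    @classmethod
    def from_text(cls, text: str) -> "LinkPuzzle":
        lines = text.strip().splitlines()
        found: dict[str, list[Cell]] = {}
        for r, line in enumerate(lines):
            for c, ch in enumerate(line):
                if ch != ".":
                    found.setdefault(ch, []).append((r, c))
        pairs = []
        for letter in sorted(found):
            cells = found[letter]
            if len(cells) != 2:
                raise ValueError(f"color {letter} has {len(cells)} endpoints, expected 2")
            pairs.append(LinkPair(string.ascii_uppercase.index(letter) + 1, cells[0], cells[1]))
        return cls(size=len(lines), pairs=tuple(pairs))

    def to_json(self) -> dict:
        return {
            "size": self.size,
            "pairs": [{"color": p.color, "a": list(p.a), "b": list(p.b)} for p in self.pairs],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "LinkPuzzle":
        pairs = tuple(
            LinkPair(p["color"], tuple(p["a"]), tuple(p["b"])) for p in obj["pairs"]
        )
        return cls(size=obj["size"], pairs=pairs)


@dataclass(frozen=True)
class LinkSolution:
    paths: tuple[tuple[int, tuple[Cell, ...]], ...]


class ValidationResult(NamedTuple):
    ok: bool
    reason: str

    def __bool__(self) -> bool:
        return self.ok


def validate_solution(puzzle: LinkPuzzle, candidate: LinkSolution) -> ValidationResult:
    """Check the full-fill rules; ``reason`` names the first violated one."""
    by_color = {p.color: p for p in puzzle.pairs}
    used: set[Cell] = set()
    seen_colors: set[int] = set()
    for color, cells in candidate.paths:
        if color not in by_color:
            return ValidationResult(False, f"unknown color {color}")
        if color in seen_colors:
            return ValidationResult(False, f"duplicate path for color {color}")
        seen_colors.add(color)
        if len(cells) < 2:
            return ValidationResult(False, f"path for color {color} shorter than 2 cells")
        pair = by_color[color]
        if {cells[0], cells[-1]} != {pair.a, pair.b}:
            return ValidationResult(False, f"path endpoints mismatch for color {color}")
        for prev, cur in zip(cells, cells[1:]):
            if abs(prev[0] - cur[0]) + abs(prev[1] - cur[1]) != 1:
                return ValidationResult(False, f"non-adjacent step in path for color {color}")
        for cell in cells:
            r, c = cell
            if not (0 <= r < puzzle.size and 0 <= c < puzzle.size):
                return ValidationResult(False, f"cell {cell} out of bounds")
            if cell in used:
                return ValidationResult(False, "cell reuse")
            used.add(cell)
    if seen_colors != set(by_color):
        missing = sorted(set(by_color) - seen_colors)
        return ValidationResult(False, f"missing path for color {missing[0]}")
    if len(used) != puzzle.size**2:
        return ValidationResult(False, "uncovered cell")
    return ValidationResult(True, "")


# -- generation ----------------------------------------------------------


def _serpentine(size: int) -> list[Cell]:
    path = []
    for r in range(size):
        cols = range(size) if r % 2 == 0 else range(size - 1, -1, -1)
        path.extend((r, c) for c in cols)
    return path


def _backbite(path: list[Cell], rng: np.random.Generator, n_moves: int) -> list[Cell]:
    """Randomize a Hamiltonian path with backbite (endpoint reversal) moves."""
    path = list(path)
    index = {cell: i for i, cell in enumerate(path)}
    size = int(np.sqrt(len(path)))
    for _ in range(n_moves):
        if rng.integers(2):
            path.reverse()
            index = {cell: i for i, cell in enumerate(path)}
        head = path[0]
        neighbors = [
            (head[0] + dr, head[1] + dc)
            for dr, dc in _NEIGHBOR_OFFSETS
            if 0 <= head[0] + dr < size and 0 <= head[1] + dc < size
        ]
        cand = [n for n in neighbors if index[n] >= 2]
        if not cand:
            continue
        v = cand[int(rng.integers(len(cand)))]
        j = index[v]
        path[:j] = path[j - 1 :: -1] if j > 0 else path[:j]
        index = {cell: i for i, cell in enumerate(path)}
    return path


def generate_puzzle(
    level: DifficultyLevel, seed: int
) -> tuple[LinkPuzzle, LinkSolution]:
    """Generate a puzzle with ``level.num_objects`` pairs on a
    ``level.board_size`` square grid, plus its witness solution.

    The grid's Hamiltonian path is randomized and cut into exactly the
    required number of segments; segments are at least 3 cells long where the
    cell budget allows it (at least 2 otherwise, e.g. 8 pairs on a 4×4 grid).
    """
    size, n_pairs = level.board_size, level.num_objects
    return _generate(size, n_pairs, seed)


def _generate(size: int, n_pairs: int, seed: int) -> tuple[LinkPuzzle, LinkSolution]:
    n_cells = size * size
    min_len = 3 if 3 * n_pairs <= n_cells else 2
    if min_len * n_pairs > n_cells:
        raise ValueError(f"{n_pairs} pairs cannot fill a {size}x{size} grid")
    rng = np.random.Generator(np.random.Philox(key=seed))
    for _ in range(GENERATION_RETRY_CAP):
        path = _backbite(_serpentine(size), rng, n_moves=10 * n_cells)
        extra = n_cells - min_len * n_pairs
        lengths = min_len + rng.multinomial(extra, [1.0 / n_pairs] * n_pairs)
        segments = []
        pos = 0
        for length in lengths:
            segments.append(tuple(path[pos : pos + int(length)]))
            pos += int(length)
        pairs = tuple(
            LinkPair(i + 1, seg[0], seg[-1]) for i, seg in enumerate(segments)
        )
        puzzle = LinkPuzzle(size=size, pairs=pairs)
        solution = LinkSolution(
            paths=tuple((i + 1, seg) for i, seg in enumerate(segments))
        )
        if validate_solution(puzzle, solution):
            return puzzle, solution
    raise RuntimeError(f"puzzle generation failed for size={size}, pairs={n_pairs}")


# -- solving -------------------------------------------------------------


class SolveStatus(str, Enum):
    SOLVED = "solved"
    UNSOLVABLE = "unsolvable"
    UNKNOWN = "unknown"  # node budget exhausted before the search finished


class SolveResult(NamedTuple):
    status: SolveStatus
    solution: Optional[LinkSolution]


class _Search:
    """Depth-first path router shared by solve() and count_solutions()."""

    def __init__(self, puzzle: LinkPuzzle, node_budget: int, cap: Optional[int]):
        self.puzzle = puzzle
        self.size = puzzle.size
        self.budget = node_budget
        self.cap = cap
        self.nodes = 0
        self.exhausted = False
        self.count = 0
        self.first: Optional[LinkSolution] = None
        self.occupied = np.zeros((self.size, self.size), dtype=bool)
        self.pairs = sorted(puzzle.pairs)
        self.paths: list[list[Cell]] = []

    def run(self) -> None:
        # every endpoint blocks other colors' paths
        for _, a, b in self.pairs:
            self.occupied[a] = True
            self.occupied[b] = True
        self._route(0)

    def _free_neighbors(self, cell: Cell, target: Cell) -> list[Cell]:
        out = []
        for dr, dc in _NEIGHBOR_OFFSETS:
            nxt = (cell[0] + dr, cell[1] + dc)
            if not (0 <= nxt[0] < self.size and 0 <= nxt[1] < self.size):
                continue
            if nxt == target or not self.occupied[nxt]:
                out.append(nxt)
        return out

    def _reachable(self, pair_index: int, head: Cell) -> bool:
        """Prune: the current head must still reach its target through free
        cells, and every unrouted pair's endpoints must be co-connected."""
        free = ~self.occupied
        comp = np.full((self.size, self.size), -1, dtype=np.int32)
        label = 0
        for r in range(self.size):
            for c in range(self.size):
                if free[r, c] and comp[r, c] < 0:
                    stack = [(r, c)]
                    comp[r, c] = label
                    while stack:
                        cr, cc = stack.pop()
                        for dr, dc in _NEIGHBOR_OFFSETS:
                            nr, nc = cr + dr, cc + dc
                            if 0 <= nr < self.size and 0 <= nc < self.size:
                                if free[nr, nc] and comp[nr, nc] < 0:
                                    comp[nr, nc] = label
                                    stack.append((nr, nc))
                    label += 1

        def touches(cell: Cell) -> set[int]:
            out = set()
            if not self.occupied[cell]:
                out.add(int(comp[cell]))
            for dr, dc in _NEIGHBOR_OFFSETS:
                nr, nc = cell[0] + dr, cell[1] + dc
                if 0 <= nr < self.size and 0 <= nc < self.size and free[nr, nc]:
                    out.add(int(comp[nr, nc]))
            return out

        target = self.pairs[pair_index].b
        if head != target and target not in self._free_neighbors(head, target):
            if not (touches(head) & touches(target)):
                return False
        for _, a, b in self.pairs[pair_index + 1 :]:
            if not (touches(a) & touches(b)):
                return False
        return True

    def _route(self, pair_index: int) -> bool:
        """Returns True when the search should stop early."""
        if pair_index == len(self.pairs):
            if self.occupied.all():
                self.count += 1
                if self.first is None:
                    self.first = LinkSolution(
                        paths=tuple(
                            (pair.color, tuple(path))
                            for pair, path in zip(self.pairs, self.paths)
                        )
                    )
                if self.cap is not None and self.count >= self.cap:
                    return True
                if self.cap is None:
                    return True
            return False
        _, a, b = self.pairs[pair_index]
        self.paths.append([a])
        stop = self._extend(pair_index, a, b)
        self.paths.pop()
        return stop

    def _extend(self, pair_index: int, head: Cell, target: Cell) -> bool:
        self.nodes += 1
        if self.nodes > self.budget:
            self.exhausted = True
            return True
        if head == target:
            return self._route(pair_index + 1)
        if not self._reachable(pair_index, head):
            return False
        for nxt in self._free_neighbors(head, target):
            if nxt != target:
                self.occupied[nxt] = True
            self.paths[-1].append(nxt)
            stop = self._extend(pair_index, nxt, target)
            self.paths[-1].pop()
            if nxt != target:
                self.occupied[nxt] = False
            if stop:
                return True
        return False


def solve(puzzle: LinkPuzzle, node_budget: int = 2_000_000) -> SolveResult:
    """Find one full-fill solution by deterministic backtracking.

    Budget exhaustion yields status ``unknown`` rather than ``unsolvable``.
    """
    search = _Search(puzzle, node_budget, cap=None)
    search.run()
    if search.first is not None:
        return SolveResult(SolveStatus.SOLVED, search.first)
    if search.exhausted:
        return SolveResult(SolveStatus.UNKNOWN, None)
    return SolveResult(SolveStatus.UNSOLVABLE, None)


def count_solutions(puzzle: LinkPuzzle, cap: int = 1_000, node_budget: int = 5_000_000) -> int:
    """Number of distinct full-fill solutions, truncated at ``cap``.

    Intended for small instances (size <= 6); paths are undirected, and each
    distinct set of paths is counted once.
    """
    if not puzzle.pairs:
        return 0
    search = _Search(puzzle, node_budget, cap=cap)
    search.run()
    return search.count
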