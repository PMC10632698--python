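"""Generate one board per game at a mid-ladder difficulty and print it.

The match-3 board is quiescent (no ready-made run of three) but always has
at least one useful swap; the numberlink puzzle ships with a hidden witness
solution whose paths cover every cell.
"""

from puzzletrain import build_ladder, match3, numberlink

ladder = build_ladder("match3")
level = ladder[13]  # 6x6 board, 6 object types
print(f"level {level.index}: {level.board_size}x{level.board_size}, "
      f"{level.num_objects} object types\n")

board = match3.generate_board(level, seed=7)
print("match-3 board (gem codes):")
print(board.to_text())
moves = match3.list_available_moves(board)
print(f"ready-made matches: {len(match3.find_matches(board))}, "
      f"available swaps: {len(moves)}\n")

puzzle, witness = numberlink.generate_puzzle(level, seed=7)
print("numberlink puzzle ('.' = empty, letters = endpoint pairs):")
print(puzzle.to_text())
result = numberlink.validate_solution(puzzle, witness)
print(f"witness solution covers all {level.board_size ** 2} cells: {result.ok}")
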