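import numpy as np
import pytest

import puzzletrain as pt
from puzzletrain import trial
from puzzletrain.ladder import Game


@pytest.fixture(scope="session")
def ladder():
    return pt.build_ladder("match3")


@pytest.fixture(scope="session")
def reference_pretests():
    return trial.reference_pretests()


@pytest.fixture(scope="session")
def training_attempts():
    """Pooled pilot-style attempts for fitting time models."""
    return pt.generate_training_dataset(12, seed=11)


@pytest.fixture(scope="session")
def trained_service(reference_pretests, training_attempts):
    service = pt.AdaptiveService(reference=reference_pretests)
    service.train(training_attempts, seed=0)
    return service


# -- independent brute-force oracles (kept free of the engine code paths) --


def oracle_runs(cells):
    """Every maximal run of >= 3 equal codes, by direct scanning."""
    cells = np.asarray(cells)
    h, w = cells.shape
    runs = []
    for r in range(h):
        c = 0
        while c < w:
            c2 = c
            while c2 < w and cells[r, c2] == cells[r, c]:
                c2 += 1
            if c2 - c >= 3:
                runs.append(("h", (r, c), c2 - c, int(cells[r, c])))
            c = c2
    for c in range(w):
        r = 0
        while r < h:
            r2 = r
            while r2 < h and cells[r2, c] == cells[r, c]:
                r2 += 1
            if r2 - r >= 3:
                runs.append(("v", (r, c), r2 - r, int(cells[r, c])))
            r = r2
    return runs


def oracle_moves(cells):
    """All adjacent swaps of unequal codes that create a run, by brute force."""
    cells = np.asarray(cells)
    h, w = cells.shape
    moves = []
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w and cells[r, c] != cells[r2, c2]:
                    trial_cells = cells.copy()
                    trial_cells[r, c], trial_cells[r2, c2] = (
                        trial_cells[r2, c2],
                        trial_cells[r, c],
                    )
                    if oracle_runs(trial_cells):
                        moves.append(((r, c), (r2, c2)))
    return moves


@pytest.fixture(scope="session")
def match3_oracles():
    return oracle_runs, oracle_moves


@pytest.fixture(scope="session")
def games():
    return list(Game)
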