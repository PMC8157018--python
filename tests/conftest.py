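import numpy as np
import pytest

from egress.world import EnvironmentSpec, build_preset, compute_floor_field, load_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def open_7x7():
    """7x7 open room, exits centered on west (L) and east (R) walls."""
    text = "\n".join(
        ["......."] * 3 + ["L.....R"] + ["......."] * 3
    )
    return compute_floor_field(load_map(text))


@pytest.fixture
def e1_small():
    return build_preset(EnvironmentSpec("E1", size=11))


def random_map_text(rng: np.random.Generator, max_side: int = 25,
                    p_obstacle: float = 0.25) -> str:
    """Random rectangular map with scattered obstacles and one exit patch of
    each label placed on floor cells."""
    h = int(rng.integers(5, max_side + 1))
    w = int(rng.integers(5, max_side + 1))
    grid = np.where(rng.random((h, w)) < p_obstacle, "#", ".").astype("<U1")
    free = np.argwhere(grid == ".")
    i, j = rng.choice(len(free), size=2, replace=False)
    (y1, x1), (y2, x2) = free[i], free[j]
    grid[y1, x1] = "L"
    grid[y2, x2] = "R"
    return "\n".join("".join(row) for row in grid)
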