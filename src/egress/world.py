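"""Grid environment: map parsing, preset geometries, and the static floor field.

The simulated space is a bounded rectangular lattice of square cells
("patches").  Each patch is one of three structural types:

* ``normal`` — walkable floor,
* ``obstacle`` — blocks both movement and floor-field spread,
* ``exit`` — walkable; an agent stepping onto it leaves the simulation.

There are exactly two exits, labelled ``left`` and ``right``.  The floor
field assigns every walkable patch, per exit, the minimal number of
cell-to-cell steps to that exit over the 8-connected (Moore) walkability
graph (``hops``) and the compass direction of the best next step (``doms``).
Directions are degrees with 0 = north (up, +y), increasing clockwise, so
the eight Moore directions are 0, 45, ..., 315.

Coordinates are 0-based with ``x`` the column and ``y`` the row, origin at
the bottom-left; map text files list the top row first.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

EXIT_LABELS: tuple[str, str] = ("left", "right")

#: Sentinel stored in hops/doms for obstacle patches, exit patches (the
#: spread sources) and patches unreachable from an exit.
SENTINEL: int = -1

#: Moore-neighbor scan order (N, NE, E, SE, S, SW, W, NW) as compass degrees.
SCAN_ORDER: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)

#: Compass degrees -> (dx, dy) with 0 = north = +y, clockwise.
OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (1, 1),
    90: (1, 0),
    135: (1, -1),
    180: (0, -1),
    225: (-1, -1),
    270: (-1, 0),
    315: (-1, 1),
}

MAP_ALPHABET = {".": "normal", "#": "obstacle", "L": "exit", "R": "exit"}


class Structure(IntEnum):
    NORMAL = 0
    OBSTACLE = 1
    EXIT = 2


class MapFormatError(ValueError):
    """Raised for ragged rows, unknown characters, or a missing exit."""


class ConfigError(ValueError):
    """Raised for invalid run or environment configuration."""


def alternate_exit(label: str) -> str:
    """The other of the two exit labels."""
    return "right" if label == "left" else "left"


@dataclass
class Patch:
    """A read/write view of one grid cell's state.

    ``hops``/``doms``/``pv`` are per-exit mappings keyed by exit label.
    Obstacle and exit patches carry the −1 sentinel in ``hops``/``doms``.
    """

    world: "GridWorld"
    x: int
    y: int

    @property
    def structure_type(self) -> str:
        return ("normal", "obstacle", "exit")[self.world.structure[self.y, self.x]]

    @property
    def exit_label(self) -> str:
        code = self.world.exit_code[self.y, self.x]
        return ("none", "left", "right")[code]

    @property
    def hops(self) -> dict[str, int]:
        return {lab: int(self.world.hops[lab][self.y, self.x]) for lab in EXIT_LABELS}

    @property
    def doms(self) -> dict[str, int]:
        return {lab: int(self.world.doms[lab][self.y, self.x]) for lab in EXIT_LABELS}

    @property
    def pv(self) -> dict[str, float]:
        return {lab: float(self.world.pv[lab][self.y, self.x]) for lab in EXIT_LABELS}

    @property
    def occupant(self) -> int | None:
        occ = int(self.world.occupant[self.y, self.x])
        return None if occ < 0 else occ


class GridWorld:
    """Bounded 2-D lattice of patches with two named exits.

    State is stored as dense numpy arrays indexed ``[y, x]``; :class:`Patch`
    objects are lightweight views for inspection and tests.  No wrap-around:
    every coordinate addresses exactly one patch.
    """

    def __init__(self, structure: np.ndarray, exit_code: np.ndarray):
        if structure.shape != exit_code.shape:
            raise ValueError("structure/exit arrays must share a shape")
        self.structure = structure.astype(np.uint8)
        self.exit_code = exit_code.astype(np.uint8)
        self.height, self.width = structure.shape
        self.hops = {
            lab: np.full(structure.shape, SENTINEL, dtype=np.int32)
            for lab in EXIT_LABELS
        }
        self.doms = {
            lab: np.full(structure.shape, SENTINEL, dtype=np.int16)
            for lab in EXIT_LABELS
        }
        self.pv = {lab: np.zeros(structure.shape, dtype=float) for lab in EXIT_LABELS}
        self.occupant = np.full(structure.shape, -1, dtype=np.int32)
        self.exits: dict[str, list[tuple[int, int]]] = {
            lab: [
                (int(x), int(y))
                for y, x in zip(*np.nonzero(self.exit_code == code))
            ]
            for code, lab in ((1, "left"), (2, "right"))
        }

    # -- basic geometry -------------------------------------------------

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def is_walkable(self, x: int, y: int) -> bool:
        return bool(self.structure[y, x] != Structure.OBSTACLE)

    def patch(self, x: int, y: int) -> Patch:
        if not self.in_bounds(x, y):
            raise IndexError(f"({x}, {y}) outside {self.width}x{self.height} world")
        return Patch(self, x, y)

    def moore_neighbors(self, patch: Patch) -> list[Patch]:
        """The ≤8 in-bounds surrounding patches in N,NE,E,SE,S,SW,W,NW order."""
        out = []
        for d in SCAN_ORDER:
            dx, dy = OFFSETS[d]
            nx, ny = patch.x + dx, patch.y + dy
            if self.in_bounds(nx, ny):
                out.append(Patch(self, nx, ny))
        return out

    def moore_coords(self, x: int, y: int) -> list[tuple[int, int]]:
        return [
            (x + dx, y + dy)
            for dx, dy in (OFFSETS[d] for d in SCAN_ORDER)
            if self.in_bounds(x + dx, y + dy)
        ]

    # -- derived summaries ----------------------------------------------

    def walkable_normal_coords(self) -> list[tuple[int, int]]:
        ys, xs = np.nonzero(self.structure == Structure.NORMAL)
        return [(int(x), int(y)) for y, x in zip(ys, xs)]

    def left_bias(self) -> float:
        """Fraction of normal patches strictly nearer the left exit (by hops).

        Patches unreachable from either exit are excluded from the
        denominator; equidistant patches count as not-nearer.
        """
        hl, hr = self.hops["left"], self.hops["right"]
        normal = self.structure == Structure.NORMAL
        reach = normal & ((hl >= 0) | (hr >= 0))
        hl_eff = np.where(hl < 0, np.iinfo(np.int32).max, hl)
        hr_eff = np.where(hr < 0, np.iinfo(np.int32).max, hr)
        n = int(reach.sum())
        if n == 0:
            return float("nan")
        return float((reach & (hl_eff < hr_eff)).sum() / n)

    def to_map_text(self) -> str:
        chars = np.full((self.height, self.width), ".", dtype="<U1")
        chars[self.structure == Structure.OBSTACLE] = "#"
        chars[self.exit_code == 1] = "L"
        chars[self.exit_code == 2] = "R"
        return "\n".join("".join(row) for row in chars[::-1])


@dataclass
class EnvironmentSpec:
    """Either a named preset (E1–E4) or a custom map text."""

    preset_id: str = "E1"
    map_text: str | None = None
    size: int = 51

    def __post_init__(self) -> None:
        if self.preset_id == "custom":
            if self.map_text is None:
                raise ConfigError("custom environment requires map_text")
        elif self.preset_id not in ("E1", "E2", "E3", "E4"):
            raise ConfigError(f"unknown preset {self.preset_id!r}")
        elif self.map_text is not None:
            raise ConfigError("map_text only allowed with preset_id='custom'")


def load_map(map_text: str) -> GridWorld:
    """Parse a character-grid map into a :class:`GridWorld`.

    Alphabet: ``.`` floor, ``#`` obstacle, ``L`` left exit, ``R`` right
    exit.  The first line of the text is the top row of the world.  The
    floor field is *not* computed; call :func:`compute_floor_field`.
    """
    lines = [ln for ln in map_text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MapFormatError("empty map")
    width = len(lines[0])
    if any(len(ln) != width for ln in lines):
        raise MapFormatError("ragged rows: all map lines must have equal length")
    bad = sorted({c for ln in lines for c in ln} - set(MAP_ALPHABET))
    if bad:
        raise MapFormatError(f"unknown map characters: {bad}")
    height = len(lines)
    structure = np.zeros((height, width), dtype=np.uint8)
    exit_code = np.zeros((height, width), dtype=np.uint8)
    for i, ln in enumerate(lines):
        y = height - 1 - i  # first line is the top row
        for x, c in enumerate(ln):
            if c == "#":
                structure[y, x] = Structure.OBSTACLE
            elif c == "L":
                structure[y, x] = Structure.EXIT
                exit_code[y, x] = 1
            elif c == "R":
                structure[y, x] = Structure.EXIT
                exit_code[y, x] = 2
    if not (exit_code == 1).any() or not (exit_code == 2).any():
        raise MapFormatError("map must contain at least one 'L' and one 'R' exit patch")
    return GridWorld(structure, exit_code)


#: Fraction of the side length covered by the obstacle wall shielding the
#: right exit in presets E2–E4 (E1 has no wall).  Chosen so the fraction of
#: patches nearer the left exit strictly increases across presets.
PRESET_WALL_FRACTION = {"E1": 0.0, "E2": 0.30, "E3": 0.55, "E4": 0.80}

EXIT_HALF_WIDTH = 1  # exits span 2*EXIT_HALF_WIDTH + 1 = 3 wall patches


def preset_map_text(preset_id: str, size: int = 51) -> str:
    """Character grid for presets E1–E4.

    E1 is an open room with a 3-patch exit centered on the west wall (left)
    and on the east wall (right).  E2–E4 add a vertical obstacle wall two
    cells in front of the right exit, centered on it, spanning an increasing
    fraction of the side length with gaps at both ends, so ever more of the
    floor is nearer the left exit.
    """
    if preset_id not in PRESET_WALL_FRACTION:
        raise ConfigError(f"unknown preset {preset_id!r}")
    if size < 11 or size % 2 == 0:
        raise ConfigError("preset size must be odd and >= 11")
    c = size // 2
    grid = np.full((size, size), ".", dtype="<U1")
    for dy in range(-EXIT_HALF_WIDTH, EXIT_HALF_WIDTH + 1):
        grid[c + dy, 0] = "L"
        grid[c + dy, size - 1] = "R"
    frac = PRESET_WALL_FRACTION[preset_id]
    if frac > 0:
        half = max(1, int(round(frac * size / 2)))
        half = min(half, c - 2)  # keep gaps at top and bottom
        wall_x = size - 3  # two cells in front of the right exit
        grid[c - half : c + half + 1, wall_x] = "#"
    return "\n".join("".join(row) for row in grid[::-1])


def build_preset(spec: EnvironmentSpec) -> GridWorld:
    """Build the world for an :class:`EnvironmentSpec`, floor field included."""
    if spec.preset_id == "custom":
        world = load_map(spec.map_text)
    else:
        world = load_map(preset_map_text(spec.preset_id, spec.size))
    return compute_floor_field(world)


def compute_floor_field(world: GridWorld) -> GridWorld:
    """Fill hops/doms for both exits by outward spread from the exit patches.

    For each exit independently, a multi-source breadth-first search over the
    8-connected walkability graph assigns every reachable walkable patch the
    minimal hop count to that exit; ``doms`` is the compass direction toward
    the neighbor through which the minimum is achieved (ties broken by the
    fixed N,NE,E,SE,S,SW,W,NW scan order).  Obstacles are opaque, and each
    exit's field spreads over floor patches and its own exit patches only
    (the other exit's patches hold sentinels and do not relay).  Exit
    patches are the spread sources (internally distance 0) but store the −1
    sentinel, as do unreachable patches.  Pure function of the map: repeated
    calls give identical fields.  Modifies ``world`` in place and returns it.
    """
    h, w = world.height, world.width
    for code, lab in ((1, "left"), (2, "right")):
        # spread travels over floor and this exit's own patches only: the
        # other exit's patches hold sentinels and do not relay the field
        walkable = (world.structure == Structure.NORMAL) | (world.exit_code == code)
        dist = np.full((h, w), -1, dtype=np.int32)
        q: deque[tuple[int, int]] = deque()
        for y, x in zip(*np.nonzero(world.exit_code == code)):
            dist[y, x] = 0
            q.append((int(x), int(y)))
        while q:
            x, y = q.popleft()
            d0 = dist[y, x]
            for d in SCAN_ORDER:
                dx, dy = OFFSETS[d]
                nx, ny = x + dx, y + dy
                if 0 <= nx < w and 0 <= ny < h and walkable[ny, nx] and dist[ny, nx] < 0:
                    dist[ny, nx] = d0 + 1
                    q.append((nx, ny))
        hops = np.full((h, w), SENTINEL, dtype=np.int32)
        doms = np.full((h, w), SENTINEL, dtype=np.int16)
        normal = world.structure == Structure.NORMAL
        reached = normal & (dist > 0)
        hops[reached] = dist[reached]
        for y, x in zip(*np.nonzero(reached)):
            target = dist[y, x] - 1
            for d in SCAN_ORDER:
                dx, dy = OFFSETS[d]
                nx, ny = x + dx, y + dy
                if 0 <= nx < w and 0 <= ny < h and walkable[ny, nx] and dist[ny, nx] == target:
                    doms[y, x] = d
                    break
        world.hops[lab] = hops
        world.doms[lab] = doms
    return world
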