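"""Evacuee agents: placement, heading, microscopic movement, and the
WALK/WAIT/PANIC state machine with its three mutually-exclusive indices.

Each agent occupies one cell and moves at most one cell per tick.  After a
move attempt exactly one of the three indices (moving, waiting, panic) is
incremented according to the new state and the other two are reset to 0:

* moved            -> WALK, moving index += 1
* blocked, waiting index <  threshold -> WAIT,  waiting index += 1
* blocked, waiting index >= threshold -> PANIC, panic index += 1

The Mobility Index (MI) is a running score of movement quality used by the
small-world strategy: +1 on WALK, −1 on WAIT, and MI ← MI − MI·sensitivity
on PANIC (sensitivity 0.5 by default, so panic halves it).  MI is not
clamped and may go negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import OFFSETS, ConfigError, GridWorld, Structure

WALK, WAIT, PANIC = "WALK", "WAIT", "PANIC"
EMOTIONAL, RATIONAL = "emotional", "rational"

#: Angular offsets from the heading, in preference order, for next-cell
#: selection: straight ahead first, then alternating nearest angles to
#: either side, finally directly behind.  Positive offsets are clockwise.
DIAL_OFFSETS: tuple[int, ...] = (0, 45, -45, 90, -90, 135, -135, 180)

DEFAULT_SENSITIVITY = 0.5
DEFAULT_PANIC_THRESHOLD = 4


class Agent:
    """One evacuee.

    ``type`` is ``emotional`` (mimics its surroundings, otherwise heads to
    the nearest exit) or ``rational`` (plays the game-theoretic exit-choice
    rules).  ``distant_contact`` is the static small-world tie used by the
    distant-influence strategy, or None.
    """

    __slots__ = (
        "id", "x", "y", "type", "state", "current_exit",
        "moving_index", "waiting_index", "panic_index",
        "mobility_index", "heading", "distant_contact", "ever_panicked",
    )

    def __init__(self, agent_id: int, x: int, y: int, agent_type: str,
                 current_exit: str, heading: int = 0):
        self.id = agent_id
        self.x = x
        self.y = y
        self.type = agent_type
        self.state = WALK
        self.current_exit = current_exit
        self.moving_index = 0
        self.waiting_index = 0
        self.panic_index = 0
        self.mobility_index = 0.0
        self.heading = heading
        self.distant_contact: int | None = None
        self.ever_panicked = False

    @property
    def pos(self) -> tuple[int, int]:
        return (self.x, self.y)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Agent(id={self.id}, pos=({self.x},{self.y}), {self.type}, "
                f"{self.state}, exit={self.current_exit})")


@dataclass(frozen=True)
class MoveOutcome:
    """Result of next-cell selection: where (if anywhere) the agent can go
    and the rank (1..8) of the chosen dial position."""

    moved: bool
    new_pos: tuple[int, int] | None = None
    chosen_offset_rank: int | None = None


def initialize_agents(world: GridWorld, n: int, rational_pct: float,
                      rng: np.random.Generator) -> list[Agent]:
    """Place ``n`` agents on distinct normal patches, uniformly at random.

    ``round(n * rational_pct / 100)`` agents (chosen at random) are typed
    rational, the rest emotional.  Every agent starts in WALK with all
    indices and MI at 0, heading toward its nearest exit (hops argmin of
    its patch; ties broken uniformly at random).  Occupancy is registered
    on ``world.occupant``.
    """
    if not 0 <= rational_pct <= 100:
        raise ConfigError("rational_pct must be in [0, 100]")
    cells = world.walkable_normal_coords()
    if n > len(cells):
        raise ConfigError(f"cannot place {n} agents on {len(cells)} walkable patches")
    idx = rng.choice(len(cells), size=n, replace=False)
    n_rational = int(round(n * rational_pct / 100.0))
    types = np.array([RATIONAL] * n_rational + [EMOTIONAL] * (n - n_rational))
    rng.shuffle(types)
    agents = []
    big = np.iinfo(np.int32).max
    for aid, (ci, typ) in enumerate(zip(idx, types)):
        x, y = cells[int(ci)]
        hl = int(world.hops["left"][y, x])
        hr = int(world.hops["right"][y, x])
        hl = big if hl < 0 else hl
        hr = big if hr < 0 else hr
        if hl < hr:
            exit_lab = "left"
        elif hr < hl:
            exit_lab = "right"
        else:
            exit_lab = "left" if rng.random() < 0.5 else "right"
        ag = Agent(aid, x, y, str(typ), exit_lab)
        dom = int(world.doms[exit_lab][y, x])
        ag.heading = dom if dom >= 0 else 0
        agents.append(ag)
        world.occupant[y, x] = aid
    return agents


def adjust_heading(agent: Agent, world: GridWorld) -> Agent:
    """Point the agent along the floor field toward its current exit.

    If the patch is unreachable for that exit (doms sentinel −1) the
    previous heading is kept.
    """
    dom = int(world.doms[agent.current_exit][agent.y, agent.x])
    if dom >= 0:
        agent.heading = dom
    return agent


def select_next_cell(agent: Agent, world: GridWorld) -> MoveOutcome:
    """Scan the Moore neighborhood in dial order and pick the first free cell.

    The dial tries the heading direction first, then alternates to either
    side in 45° steps (see :data:`DIAL_OFFSETS`).  A cell qualifies if it is
    in bounds, walkable (normal or exit), and unoccupied.
    """
    for rank, off in enumerate(DIAL_OFFSETS, start=1):
        d = (agent.heading + off) % 360
        dx, dy = OFFSETS[d]
        nx, ny = agent.x + dx, agent.y + dy
        if not world.in_bounds(nx, ny):
            continue
        if world.structure[ny, nx] == Structure.OBSTACLE:
            continue
        if world.occupant[ny, nx] >= 0:
            continue
        return MoveOutcome(True, (nx, ny), rank)
    return MoveOutcome(False)


def apply_move_and_update_state(agent: Agent, world: GridWorld,
                                outcome: MoveOutcome,
                                panic_threshold: int = DEFAULT_PANIC_THRESHOLD) -> Agent:
    """Commit a move outcome, transition the state, and update the indices.

    Occupancy is claimed atomically in activation order: if the target cell
    has been taken since selection the move is treated as failed.  Exit
    patches are never claimed here — the engine removes exiting agents
    before this step.
    """
    moved = outcome.moved
    if moved:
        nx, ny = outcome.new_pos
        if world.occupant[ny, nx] >= 0:
            moved = False
    if moved:
        world.occupant[agent.y, agent.x] = -1
        agent.x, agent.y = nx, ny
        world.occupant[ny, nx] = agent.id
        agent.state = WALK
        agent.moving_index += 1
        agent.waiting_index = 0
        agent.panic_index = 0
    else:
        if agent.waiting_index < panic_threshold:
            agent.state = WAIT
            agent.waiting_index += 1
            agent.moving_index = 0
            agent.panic_index = 0
        else:
            agent.state = PANIC
            agent.panic_index += 1
            agent.moving_index = 0
            agent.waiting_index = 0
            agent.ever_panicked = True
    return agent


def update_mobility_index(agent: Agent,
                          sensitivity: float = DEFAULT_SENSITIVITY) -> Agent:
    """Update MI from the state set this tick: +1 WALK, −1 WAIT,
    MI − MI·sensitivity on PANIC."""
    if agent.state == WALK:
        agent.mobility_index += 1.0
    elif agent.state == WAIT:
        agent.mobility_index -= 1.0
    else:
        agent.mobility_index -= agent.mobility_index * sensitivity
    return agent
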