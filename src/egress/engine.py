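"""The per-tick simulation loop.

Each tick, live agents are activated in a fresh uniform-random order; each
activated agent, in sequence, (1) decides its exit per the configured
strategy, (2) adjusts its heading along the floor field, (3) selects and
(4) commits a next cell, updating its state/indices, then (5) updates its
Mobility Index.  An agent stepping onto an exit patch is removed and
counted the moment it does so — it never blocks later agents in the same
tick.  Under S3, exits seed the potential field when used, and the field
spreads (agent-borne) and decays once per tick after all activations.
The run terminates when the space is empty, or at a safety cap.

A single seeded numpy Generator drives every random choice, consumed in
activation order, so (config, seed) fully determines the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import agents as ag
from . import potential as pot
from . import strategies as strat
from .world import ConfigError, EnvironmentSpec, GridWorld, Structure, build_preset


@dataclass
class SimulationConfig:
    """All parameters of one run."""

    env: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    n_agents: int = 1000
    rational_pct: float = 5.0
    strategy: str = "S1"
    panic_threshold: int = ag.DEFAULT_PANIC_THRESHOLD
    sensitivity: float = ag.DEFAULT_SENSITIVITY
    decay_factor: float = pot.DEFAULT_DECAY
    spread_attenuation: float = pot.DEFAULT_ATTENUATION
    seed: int = 0
    max_ticks: int | None = None  # None -> 50 * (width + height)
    record_ticks: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in strat.STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.n_agents < 0:
            raise ConfigError("n_agents must be >= 0")
        if not 0 <= self.rational_pct <= 100:
            raise ConfigError("rational_pct must be in [0, 100]")
        if self.panic_threshold < 1:
            raise ConfigError("panic_threshold must be >= 1")
        if not 0 < self.decay_factor <= 1:
            raise ConfigError("decay_factor must be in (0, 1]")


@dataclass
class RunResult:
    """End-of-run metrics (plus an optional per-tick log).

    ``exit_time`` is the number of ticks until the space emptied.  Two
    panic summaries are reported because both are meaningful: the maximum
    number of agents simultaneously in PANIC at any tick boundary (overall
    and rational-only), and the number of agents of each type that entered
    PANIC at least once during the run.
    """

    n_agents: int
    exit_time: int
    exited: dict[str, int]
    max_concurrent_panic: int
    max_concurrent_panic_rational: int
    ever_panicked: dict[str, int]
    terminated: bool
    tick_log: list[dict] | None = None

    @property
    def max_panic_rational_pct(self) -> float:
        n_rat = self.ever_panicked_denominator("rational")
        return 100.0 * self.max_concurrent_panic_rational / n_rat if n_rat else 0.0

    def ever_panicked_denominator(self, agent_type: str) -> int:
        # set by Simulation.run; stored on exited-agnostic counts
        return self._type_counts.get(agent_type, 0)

    _type_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "exit_time": self.exit_time,
            "exited_left": self.exited["left"],
            "exited_right": self.exited["right"],
            "max_concurrent_panic": self.max_concurrent_panic,
            "max_concurrent_panic_rational": self.max_concurrent_panic_rational,
            "ever_panicked_rational": self.ever_panicked["rational"],
            "ever_panicked_emotional": self.ever_panicked["emotional"],
            "terminated": self.terminated,
        }


class Simulation:
    """A stepping simulation: world + agents + tick counter + RNG."""

    def __init__(self, config: SimulationConfig, world: GridWorld | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.world = world if world is not None else build_preset(config.env)
        self.agents: dict[int, ag.Agent] = {
            a.id: a
            for a in ag.initialize_agents(
                self.world, config.n_agents, config.rational_pct, self.rng
            )
        }
        self.type_counts = {
            t: sum(1 for a in self.agents.values() if a.type == t)
            for t in (ag.RATIONAL, ag.EMOTIONAL)
        }
        if config.strategy == "S4":
            strat.establish_distant_links(list(self.agents.values()), self.rng)
        self.tick = 0
        self.exited = {"left": 0, "right": 0}
        self.max_concurrent_panic = 0
        self.max_concurrent_panic_rational = 0
        self.ever_panicked_ids: set[int] = set()
        self.ever_panicked_type = {ag.RATIONAL: 0, ag.EMOTIONAL: 0}
        self.tick_log: list[dict] | None = [] if config.record_ticks else None
        if config.max_ticks is not None:
            self.max_ticks = config.max_ticks
        else:
            self.max_ticks = 50 * (self.world.width + self.world.height)

    @property
    def population(self) -> int:
        return len(self.agents)

    def step(self) -> None:
        """Advance one tick (see module docstring for the schedule)."""
        cfg, world, rng = self.config, self.world, self.rng
        order = rng.permutation(np.fromiter(self.agents.keys(), dtype=np.int64,
                                            count=len(self.agents)))
        s3 = cfg.strategy == "S3"
        for aid in order:
            a = self.agents[int(aid)]
            self._decide(a)
            ag.adjust_heading(a, world)
            outcome = ag.select_next_cell(a, world)
            if outcome.moved:
                nx, ny = outcome.new_pos
                if world.structure[ny, nx] == Structure.EXIT:
                    world.occupant[a.y, a.x] = -1
                    label = ("none", "left", "right")[world.exit_code[ny, nx]]
                    self.exited[label] += 1
                    del self.agents[a.id]
                    if s3:
                        pot.seed_exit_potential(world, (nx, ny), label)
                    continue
            ag.apply_move_and_update_state(a, world, outcome, cfg.panic_threshold)
            ag.update_mobility_index(a, cfg.sensitivity)
            if a.state == ag.PANIC and a.id not in self.ever_panicked_ids:
                self.ever_panicked_ids.add(a.id)
                self.ever_panicked_type[a.type] += 1
        if s3:
            pot.spread_potential(world, cfg.spread_attenuation)
            pot.decay_potential(world, cfg.decay_factor)
        self.tick += 1
        n_panic = sum(1 for a in self.agents.values() if a.state == ag.PANIC)
        n_panic_rat = sum(
            1 for a in self.agents.values()
            if a.state == ag.PANIC and a.type == ag.RATIONAL
        )
        self.max_concurrent_panic = max(self.max_concurrent_panic, n_panic)
        self.max_concurrent_panic_rational = max(
            self.max_concurrent_panic_rational, n_panic_rat
        )
        if self.tick_log is not None:
            self.tick_log.append({
                "tick": self.tick,
                "population": self.population,
                "exited_left": self.exited["left"],
                "exited_right": self.exited["right"],
                "n_panic": n_panic,
            })

    def _decide(self, a: ag.Agent) -> None:
        cfg, world, rng = self.config, self.world, self.rng
        if cfg.strategy == "S1":
            return
        if cfg.strategy == "S3" and a.type == ag.EMOTIONAL:
            return  # emotional agents keep following the nearest exit
        neighbor = strat.pick_random_neighbor(a, world, self.agents, rng)
        ctx = strat.DecisionContext(acting_agent=a, local_neighbor=neighbor)
        if cfg.strategy == "S3":
            ctx.dominant_exit = pot.dominant_exit_values(
                float(world.pv["left"][a.y, a.x]),
                float(world.pv["right"][a.y, a.x]),
            )
        elif cfg.strategy == "S4" and a.type == ag.RATIONAL and a.panic_index > 0:
            ctx.max_mobility_contact = strat.pick_max_mobility_contact(
                a, world, self.agents, rng
            )
        a.current_exit = strat.decide_exit(cfg.strategy, ctx, rng)

    def run(self) -> RunResult:
        while self.agents and self.tick < self.max_ticks:
            self.step()
        result = RunResult(
            n_agents=self.config.n_agents,
            exit_time=self.tick,
            exited=dict(self.exited),
            max_concurrent_panic=self.max_concurrent_panic,
            max_concurrent_panic_rational=self.max_concurrent_panic_rational,
            ever_panicked={
                "rational": self.ever_panicked_type[ag.RATIONAL],
                "emotional": self.ever_panicked_type[ag.EMOTIONAL],
            },
            terminated=not self.agents,
            tick_log=self.tick_log,
        )
        result._type_counts = dict(self.type_counts)
        return result


def run(config: SimulationConfig, world: GridWorld | None = None) -> RunResult:
    """Build the world (unless given), place agents, and run to completion."""
    return Simulation(config, world).run()
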