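"""The four exit-choice strategies.

* **S1** (individual): every agent keeps the nearest exit fixed at setup.
* **S2** (local social): a game against one random Moore neighbor.  A calm
  rational agent switches exits with probability 0.1 when the neighbor
  agrees with it and 0.9 when it disagrees; a panicking rational agent
  whose neighbor shares its exit switches with certainty (anti-herding),
  and keeps its exit when the neighbor disagrees.  Emotional agents only
  adopt a disagreeing neighbor's exit with probability 0.1, and only while
  panicking.
* **S3** (technological): rational agents weigh panic (0.5), the social
  signal (0.25) and the exit-potential signal (0.25); the resulting branch
  probabilities are tabulated in :data:`S3_TABLE`.  Emotional agents stick
  to the nearest exit.
* **S4** (small-world social): identical to S2 except that a panicking
  rational agent adopts the exit of its most mobile contact — the maximum
  Mobility Index over its Moore neighbors plus one static long-distance tie.

With two exits, "the alternate exit" is simply the other one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import Agent, EMOTIONAL, RATIONAL
from .world import GridWorld, alternate_exit

STRATEGIES: tuple[str, ...] = ("S1", "S2", "S3", "S4")

#: S2/S4 branch probabilities (switch to the alternate exit, or for the
#: emotional branch, adopt the neighbor's exit).
S2_PROBS: dict[str, float] = {
    "emotional_panic_adopt": 0.1,   # emotional, panicking, neighbor disagrees
    "calm_agree_switch": 0.1,       # rational, calm, neighbor agrees
    "calm_disagree_switch": 0.9,    # rational, calm, neighbor disagrees
}

#: S3 switch probabilities keyed by
#: (in_panic, neighbor_agrees, potential_agrees).  Six of the eight entries
#: equal the weight sum 0.5·panic + 0.25·(neighbor disagrees) +
#: 0.25·(potential disagrees); the two panic∧disagreeing-neighbor branches
#: are stated explicitly: a panicking agent whose neighbor *and* potential
#: both point away from its exit switches with 0.75, while agreement of the
#: potential with its own exit amid a disagreeing neighbor makes the switch
#: certain.
S3_TABLE: dict[tuple[bool, bool, bool], float] = {
    (False, True, True): 0.0,
    (False, True, False): 0.25,
    (False, False, True): 0.25,
    (False, False, False): 0.50,
    (True, True, True): 0.50,
    (True, True, False): 0.75,
    (True, False, False): 0.75,
    (True, False, True): 1.0,
}


@dataclass
class DecisionContext:
    """Everything one decision call can see: the acting agent, one random
    local neighbor (None if the Moore neighborhood is empty), the max-MI
    contact (S4 only), and the patch's dominant exit potential (S3 only)."""

    acting_agent: Agent
    local_neighbor: Agent | None = None
    max_mobility_contact: Agent | None = None
    dominant_exit: str | None = None


def pick_random_neighbor(agent: Agent, world: GridWorld,
                         agents: dict[int, Agent],
                         rng: np.random.Generator) -> Agent | None:
    """Uniform draw among agents on the ≤8 Moore cells; None if empty."""
    ids = [
        int(world.occupant[ny, nx])
        for nx, ny in world.moore_coords(agent.x, agent.y)
        if world.occupant[ny, nx] >= 0
    ]
    if not ids:
        return None
    return agents[ids[int(rng.integers(len(ids)))]]


def establish_distant_links(agents: list[Agent],
                            rng: np.random.Generator) -> list[Agent]:
    """Give every rational agent one static long-distance tie to a
    uniformly chosen *other* agent (of any type).  Links are fixed for the
    run; a link whose endpoint has exited simply goes inert."""
    ids = [a.id for a in agents]
    for a in agents:
        if a.type != RATIONAL:
            continue
        others = [i for i in ids if i != a.id]
        a.distant_contact = (
            others[int(rng.integers(len(others)))] if others else None
        )
    return agents


def pick_max_mobility_contact(agent: Agent, world: GridWorld,
                              agents: dict[int, Agent],
                              rng: np.random.Generator) -> Agent | None:
    """Argmax of MI over Moore neighbors plus the distant tie (if still in
    the simulation); MI ties broken uniformly at random; None if no
    candidates."""
    cand_ids = {
        int(world.occupant[ny, nx])
        for nx, ny in world.moore_coords(agent.x, agent.y)
        if world.occupant[ny, nx] >= 0
    }
    if agent.distant_contact is not None and agent.distant_contact in agents:
        cand_ids.add(agent.distant_contact)
    cand_ids.discard(agent.id)
    if not cand_ids:
        return None
    cands = [agents[i] for i in sorted(cand_ids)]
    best = max(c.mobility_index for c in cands)
    top = [c for c in cands if c.mobility_index == best]
    if len(top) == 1:
        return top[0]
    return top[int(rng.integers(len(top)))]


def decide_exit(strategy: str, ctx: DecisionContext,
                rng: np.random.Generator) -> str:
    """Return the (possibly unchanged) exit label for the acting agent.

    Branches that need a neighbor treat a missing neighbor as "no
    influence" and keep the current exit; branches conditioned on the
    dominant exit potential are skipped when no exit dominates (both
    potentials zero, or tied)."""
    a = ctx.acting_agent
    ae = a.current_exit
    if strategy == "S1":
        return ae
    in_panic = a.panic_index > 0

    if strategy in ("S2", "S4"):
        n = ctx.local_neighbor
        if a.type == EMOTIONAL:
            if n is not None and ae != n.current_exit and in_panic:
                if rng.random() < S2_PROBS["emotional_panic_adopt"]:
                    return n.current_exit
            return ae
        # rational
        if not in_panic:
            if n is None:
                return ae
            p = (S2_PROBS["calm_agree_switch"] if ae == n.current_exit
                 else S2_PROBS["calm_disagree_switch"])
            return alternate_exit(ae) if rng.random() < p else ae
        if strategy == "S4":
            m = ctx.max_mobility_contact
            return m.current_exit if m is not None else ae
        # S2, panicking: switch with certainty only on herding agreement
        if n is not None and ae == n.current_exit:
            return alternate_exit(ae)
        return ae

    if strategy == "S3":
        if a.type == EMOTIONAL:
            return ae  # emotional agents keep following the nearest exit
        n, ep = ctx.local_neighbor, ctx.dominant_exit
        if n is None or ep is None:
            return ae
        p = S3_TABLE[(in_panic, ae == n.current_exit, ae == ep)]
        if p > 0 and rng.random() < p:
            return alternate_exit(ae)
        return ae

    raise ValueError(f"unknown strategy {strategy!r}")
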