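"""Exit-choice strategies: neighbor sampling, distant ties, branch
probabilities, and the S3 weight structure."""

import numpy as np
import pytest

from egress.agents import EMOTIONAL, RATIONAL, Agent
from egress.strategies import (
    S3_TABLE,
    DecisionContext,
    decide_exit,
    establish_distant_links,
    pick_max_mobility_contact,
    pick_random_neighbor,
)


def make_agent(aid=0, typ=RATIONAL, exit_lab="left", panic=0, x=3, y=3, mi=0.0):
    a = Agent(aid, x, y, typ, exit_lab)
    a.panic_index = panic
    a.mobility_index = mi
    return a


def place(world, *agents):
    reg = {}
    for a in agents:
        world.occupant[a.y, a.x] = a.id
        reg[a.id] = a
    return reg


# --------------------------------------------------------- neighbor sampling

def test_no_adjacent_agents_gives_none(open_7x7, rng):
    a = make_agent()
    reg = place(open_7x7, a)
    assert pick_random_neighbor(a, open_7x7, reg, rng) is None
    open_7x7.occupant[:] = -1


def test_single_neighbor_is_certain(open_7x7, rng):
    a, b = make_agent(0), make_agent(1, x=4, y=3)
    reg = place(open_7x7, a, b)
    for _ in range(5):
        assert pick_random_neighbor(a, open_7x7, reg, rng) is b
    open_7x7.occupant[:] = -1


def test_neighbor_draw_is_uniform(open_7x7):
    rng = np.random.default_rng(42)
    a = make_agent(0)
    nbrs = [make_agent(1, x=2, y=2), make_agent(2, x=3, y=4),
            make_agent(3, x=4, y=3)]
    reg = place(open_7x7, a, *nbrs)
    n = 30_000
    counts = {1: 0, 2: 0, 3: 0}
    for _ in range(n):
        counts[pick_random_neighbor(a, open_7x7, reg, rng).id] += 1
    for c in counts.values():
        assert abs(c / n - 1 / 3) < 0.01
    open_7x7.occupant[:] = -1


# ------------------------------------------------------------- distant links

def test_every_rational_agent_gets_one_link(rng):
    agents = [make_agent(i, typ=RATIONAL if i < 2 else EMOTIONAL)
              for i in range(10)]
    establish_distant_links(agents, rng)
    links = [a.distant_contact for a in agents if a.type == RATIONAL]
    assert len(links) == 2 and all(l is not None and l != a.id
                                   for l, a in zip(links, agents))
    assert all(a.distant_contact is None for a in agents if a.type == EMOTIONAL)


def test_links_are_seed_deterministic():
    mk = lambda: [make_agent(i, typ=RATIONAL) for i in range(20)]
    a1, a2 = mk(), mk()
    establish_distant_links(a1, np.random.default_rng(5))
    establish_distant_links(a2, np.random.default_rng(5))
    assert [a.distant_contact for a in a1] == [a.distant_contact for a in a2]


def test_single_agent_population_gets_no_link(rng):
    agents = [make_agent(0, typ=RATIONAL)]
    establish_distant_links(agents, rng)
    assert agents[0].distant_contact is None


def test_link_endpoint_is_uniform_over_others():
    rng = np.random.default_rng(7)
    n, trials = 100, 30_000
    counts = np.zeros(n)
    agents = [make_agent(i, typ=EMOTIONAL) for i in range(n)]
    agents[0].type = RATIONAL
    for _ in range(trials):  # re-draw the one link many times
        establish_distant_links(agents, rng)
        counts[agents[0].distant_contact] += 1
    freqs = counts[1:] / counts.sum()
    se = np.sqrt((1 / 99) * (1 - 1 / 99) / counts.sum())
    assert np.all(np.abs(freqs - 1 / 99) < 5 * se + 1e-3)


# ------------------------------------------------------- max-mobility contact

def test_max_mi_contact_is_argmax(open_7x7, rng):
    a = make_agent(0)
    n1 = make_agent(1, x=2, y=3, mi=2)
    n2 = make_agent(2, x=4, y=3, mi=5)
    distant = make_agent(3, x=6, y=6, mi=3)
    a.distant_contact = 3
    reg = place(open_7x7, a, n1, n2, distant)
    assert pick_max_mobility_contact(a, open_7x7, reg, rng) is n2
    open_7x7.occupant[:] = -1


def test_lone_distant_contact_wins_even_with_negative_mi(open_7x7, rng):
    a = make_agent(0)
    distant = make_agent(3, x=6, y=6, mi=-1)
    a.distant_contact = 3
    reg = place(open_7x7, a, distant)
    assert pick_max_mobility_contact(a, open_7x7, reg, rng) is distant
    open_7x7.occupant[:] = -1


def test_exited_distant_contact_is_inert(open_7x7, rng):
    a = make_agent(0)
    a.distant_contact = 3  # id no longer registered
    reg = place(open_7x7, a)
    assert pick_max_mobility_contact(a, open_7x7, reg, rng) is None
    open_7x7.occupant[:] = -1


def test_mi_ties_break_uniformly(open_7x7):
    rng = np.random.default_rng(11)
    a = make_agent(0)
    n1 = make_agent(1, x=2, y=3, mi=4)
    n2 = make_agent(2, x=4, y=3, mi=4)
    reg = place(open_7x7, a, n1, n2)
    picks = sum(pick_max_mobility_contact(a, open_7x7, reg, rng) is n1
                for _ in range(10_000))
    assert abs(picks / 10_000 - 0.5) < 0.02
    open_7x7.occupant[:] = -1


# ----------------------------------------------------------- decide_exit S1

def test_s1_never_switches(rng):
    a = make_agent(typ=EMOTIONAL, exit_lab="left", panic=3)
    for _ in range(100):
        assert decide_exit("S1", DecisionContext(a), rng) == "left"


# ------------------------------------------- branch probability calibration

def switch_rate(strategy, typ, panic, neighbor_exit, dominant, trials=20_000,
                seed=0, contact_exit=None):
    rng = np.random.default_rng(seed)
    switched = 0
    for _ in range(trials):
        a = make_agent(typ=typ, exit_lab="left", panic=panic)
        ctx = DecisionContext(a)
        if neighbor_exit is not None:
            ctx.local_neighbor = make_agent(1, exit_lab=neighbor_exit, x=4)
        if dominant is not None:
            ctx.dominant_exit = dominant
        if contact_exit is not None:
            ctx.max_mobility_contact = make_agent(2, exit_lab=contact_exit, x=2)
        switched += decide_exit(strategy, ctx, rng) != "left"
    return switched / trials


def tol(p, trials=20_000):
    return 3 * np.sqrt(max(p * (1 - p), 0.25 / trials) / trials)


@pytest.mark.parametrize(
    "strategy,typ,panic,neighbor,expected",
    [
        # rational, calm: random deviation 0.1 on agreement, 0.9 follow on
        # disagreement
        ("S2", RATIONAL, 0, "left", 0.1),
        ("S2", RATIONAL, 0, "right", 0.9),
        # rational, panicking: strict anti-herding on agreement, keep on
        # disagreement
        ("S2", RATIONAL, 1, "left", 1.0),
        ("S2", RATIONAL, 1, "right", 0.0),
        # emotional: only panicking + disagreeing adopts, with 0.1
        ("S2", EMOTIONAL, 1, "right", 0.1),
        ("S2", EMOTIONAL, 0, "right", 0.0),
        ("S2", EMOTIONAL, 1, "left", 0.0),
        # S4 shares every S2 branch except the rational panic ones
        ("S4", RATIONAL, 0, "left", 0.1),
        ("S4", RATIONAL, 0, "right", 0.9),
        ("S4", EMOTIONAL, 1, "right", 0.1),
    ],
)
def test_s2_s4_branch_probabilities(strategy, typ, panic, neighbor, expected):
    rate = switch_rate(strategy, typ, panic, neighbor, None, seed=17)
    assert abs(rate - expected) <= tol(expected)


@pytest.mark.parametrize("panic", [0, 1])
@pytest.mark.parametrize("neighbor", ["left", "right"])
@pytest.mark.parametrize("dominant", ["left", "right"])
def test_s3_full_branch_table(panic, neighbor, dominant):
    expected = S3_TABLE[(panic > 0, neighbor == "left", dominant == "left")]
    rate = switch_rate("S3", RATIONAL, panic, neighbor, dominant, seed=23)
    assert abs(rate - expected) <= tol(expected)


def test_s3_weight_decomposition_where_stated():
    """Branch probabilities equal 0.5·panic + 0.25·(neighbor disagrees) +
    0.25·(potential disagrees) on the branches the weighting motivates; the
    two panic∧disagreeing-neighbor branches carry explicitly stated
    probabilities (0.75 / certain) instead."""
    for (panic, agree_n, agree_p), p in S3_TABLE.items():
        weight = 0.5 * panic + 0.25 * (not agree_n) + 0.25 * (not agree_p)
        if not (panic and not agree_n):
            assert p == min(weight, 1.0)
    assert S3_TABLE[(True, False, True)] == 1.0
    assert S3_TABLE[(True, False, False)] == 0.75


def test_s3_emotional_agents_never_switch(rng):
    a = make_agent(typ=EMOTIONAL, exit_lab="left", panic=5)
    ctx = DecisionContext(a, local_neighbor=make_agent(1, exit_lab="right", x=4),
                          dominant_exit="right")
    assert all(decide_exit("S3", ctx, rng) == "left" for _ in range(200))


def test_s3_keeps_exit_without_dominant_potential(rng):
    a = make_agent(typ=RATIONAL, exit_lab="left", panic=1)
    ctx = DecisionContext(a, local_neighbor=make_agent(1, exit_lab="left", x=4),
                          dominant_exit=None)
    assert all(decide_exit("S3", ctx, rng) == "left" for _ in range(200))


def test_s4_panicking_rational_adopts_max_mi_contact_exit(rng):
    rate = switch_rate("S4", RATIONAL, 1, "left", None, trials=500,
                       contact_exit="right")
    assert rate == 1.0
    rate = switch_rate("S4", RATIONAL, 1, "left", None, trials=500,
                       contact_exit="left")
    assert rate == 0.0


def test_s4_panicking_rational_without_contact_keeps_exit(rng):
    rate = switch_rate("S4", RATIONAL, 1, "left", None, trials=500)
    assert rate == 0.0


def test_missing_neighbor_means_keep(rng):
    for strategy in ("S2", "S3", "S4"):
        a = make_agent(typ=RATIONAL, exit_lab="right", panic=0)
        ctx = DecisionContext(a, dominant_exit="left")
        assert all(decide_exit(strategy, ctx, rng) == "right"
                   for _ in range(100))


def test_decide_exit_output_is_closed(rng):
    for strategy in ("S1", "S2", "S3", "S4"):
        for _ in range(200):
            a = make_agent(typ=rng.choice([RATIONAL, EMOTIONAL]),
                           exit_lab=rng.choice(["left", "right"]),
                           panic=int(rng.integers(0, 2)))
            ctx = DecisionContext(
                a,
                local_neighbor=make_agent(1, exit_lab=rng.choice(["left", "right"]), x=4),
                dominant_exit=rng.choice(["left", "right", None]),
            )
            assert decide_exit(strategy, ctx, rng) in ("left", "right")
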