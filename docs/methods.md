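# Methods

## Space, time, and the floor field

The world is a bounded lattice with no wrap-around; coordinates are
0-based, `x` the column, `y` the row, origin at the bottom-left, and map
text files list the top row first. Directions are compass degrees with
0° = north (+y), increasing clockwise, so the eight Moore directions are
0, 45, …, 315; with this encoding a cell informed by its "right and
behind" neighbor (relative to a north-facing reference) points at 135°.

The floor field is a multi-source breadth-first search per exit over the
8-connected walkability graph. All steps cost one hop, diagonal or not.
Each exit's field spreads over floor cells and its own exit cells only;
the other exit's cells do not relay it (their `Hops`/`Doms` stay at the −1
sentinel, as do obstacles and unreachable pockets). `Doms` points toward
the neighbor achieving the minimal hop count; when several neighbors tie,
the fixed scan order N, NE, E, SE, S, SW, W, NW decides. The field is a
pure function of the map.

Movement is microscopic: one cell per tick, scanning the dial of angular
offsets [0, +45, −45, +90, −90, +135, −135, 180] from the heading and
taking the first in-bounds, walkable, unoccupied cell. Movement conflicts
are resolved by activation order within the tick: the first agent to
select a cell claims it. Exit cells are walkable and absorb any number of
agents per tick — an agent is removed the moment it steps on one, and
never blocks a later agent in the same tick.

## The state machine and its parameters

A blocked agent WAITs; once its waiting index reaches the **panic
threshold** (default 4 ticks, configurable) a further failure makes it
PANIC. Exactly one of the three indices is incremented per tick (by the
new state) and the other two reset; a PANIC tick therefore resets the
waiting index, so a permanently blocked agent cycles WAIT×threshold →
PANIC → WAIT×… — panic spells last one tick at a time under this literal
reading, and the panic index seen by the decision rules is nonzero only on
the tick after a panic transition.

The Mobility Index is unclamped and may go negative; panic shrinks it
multiplicatively by the sensitivity (default 0.5, so one panic tick halves
it), leaving MI = 0 a fixed point. Clamping would silently distort the
max-MI comparisons of the small-world strategy, so it is deliberately
absent.

The exit potential field used by S3 is seeded to 1 on the Moore neighbors
of an exit cell whenever an agent leaves through it (only that exit's
field — a left-exit event announces the left exit). It then spreads only
via agents: once per tick, every occupied cell with a positive value
relays `0.9 × value` to any Moore neighbor holding strictly less, taken as
a maximum with the neighbor's current value (the attenuated-copy reading;
a subtractive reading could drive values negative and would not decay the
signal with distance). Spreading works from a per-tick snapshot, so the
result is independent of agent order. A multiplicative decay (default
0.99 per tick, configurable) runs last in the tick, fresh values included,
and values below 10⁻⁶ snap to zero. A cell's *dominant* exit is the
strictly greater of its two potentials; ties (including 0–0) mean no
technological influence, and decision branches conditioned on it then keep
the current exit.

## Decision rules

Decisions run once per agent per tick, before heading adjustment and the
move. One Bernoulli draw per decision call realizes each stated branch
probability. A missing neighbor (empty Moore neighborhood) means "no
social influence": every branch that compares against the neighbor keeps
the current exit. With two exits, "the alternate exit" is the other one.

The S3 branch table follows the weight decomposition — 0.5 for panic, 0.25
for a disagreeing neighbor, 0.25 for a disagreeing potential, summed and
capped at 1 — on the six branches that motivation covers. The two branches
where a panicking agent faces a disagreeing neighbor carry explicitly
stated probabilities instead: 0.75 when the potential also disagrees, and
a certain switch when the potential still favors the current exit.

Distant ties (S4) are drawn once at setup: every rational agent links to
one uniformly chosen other agent of any type. Links are static; if the
endpoint has exited, the link is simply inert (the max-MI candidate set
falls back to the local neighborhood).

At initialization agents are placed uniformly on distinct floor cells,
typed rational with probability matching the requested percentage
(`round(n·pct/100)` exactly), all WALKing with zero indices, and assigned
the nearest exit by hop count (equidistant cells choose uniformly at
random, so symmetric rooms stay unbiased).

## Scheduling and reproducibility

Each tick draws a fresh uniform-random activation order; every activated
agent runs decide → adjust heading → select cell → commit move and state →
update MI; exits are processed immediately; under S3, spread and decay run
after all activations. One shared `numpy` Generator, consumed in
activation order, drives all randomness, so (configuration, seed) fully
determines the trajectory, bit for bit. The safety cap defaults to
50 × (width + height) ticks; runs that hit it are flagged non-terminated
and excluded from sweep means.

## Environments and fixtures

E1 is an open room with two 3-cell exits centered on the west and east
walls. E2–E4 add a vertical obstacle wall two cells in front of the right
exit, centered on it, spanning 0.30 / 0.55 / 0.80 of the side length with
gaps at both ends. The only property the presets are built to guarantee —
and the tests assert — is that the fraction of floor nearer the left exit
strictly increases from E1 to E4 (≈ 0.49, 0.55, 0.62, 0.70 at size 51);
the exact wall shapes are otherwise a free design choice.

The test fixtures (`generate_fixture_world`) are deliberately small worlds
with **single-cell** doorway exits: because exit cells absorb arrivals
without ever being blocked, wide exits at fixture scale drain faster than
agents arrive and no queueing, waiting, or panic would be exercised at
all. A narrow doorway restores the bottleneck that the state machine is
about. The `asymmetric` fixture uses the most uneven (E4-like, 0.8) wall.

## The scaled-down comparison study

`qualitative_comparison` reruns the four-strategy comparison at reduced
scale (default 21×21 asymmetric fixture, 200 agents, 15% rational, 10
replicates). Replicate seeds are `base_seed + index` and shared across
strategies, so comparisons are paired on identical initial placements, and
orderings are judged by one-sided paired Wilcoxon signed-rank tests. The
waiting threshold in this study scales with the world's time scale —
`round(4 · size/51)`, i.e. 2 ticks at size 21 — since egress times shrink
roughly with the side length and a fixed 4-tick patience at a 2.5×-shorter
time scale would correspond to proportionally far more patient agents
(and, numerically, to an almost unpopulated PANIC state).

At this scale the exit-time ordering (S1 no slower than S2) and the
exit-usage ordering (S2 loads the left exit less than S1) reproduce
decisively. The panic orderings (S2 < S1, S4 < S3 in ever-panicked counts)
are *not* statistically resolvable at 10 pairs: panic spells last one tick
under the literal index-reset state machine, so the panic-conditioned
anti-herding branch fires only about once per run at this scale, and the
resulting mean differences sit well inside replicate noise. The
corresponding acceptance test states the orderings as designed and is
expected to flag this.

What the fixtures do not emulate: real rooms are not convex empty squares,
real crowds have heterogeneous speeds, bodies larger than one cell, and
doorway capacities below one agent per feeder cell per tick. Passing the
scaled-down tests shows the implemented mechanisms interact as designed,
not that the magnitudes transfer to real evacuations.

## Known limitations

* Two exits only; the decision algorithms are written for a binary choice.
* No social-force physics, velocities, or multi-cell agents.
* The panic threshold and the potential decay rate are free parameters
  with no empirical anchoring; defaults are stated above and exposed in
  the configuration.
* A run's wall-clock cost grows with agents × ticks; the full factorial
  sweep at paper scale (4×4×4×50 runs of 1,000 agents) takes hours, which
  is why the bundled studies default to reduced problem sizes.
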