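# egress

An agent-based simulator of crowd evacuation from a bounded two-exit room,
for researchers studying how individual, social, and technological
information channels shape egress dynamics — exit times, exit-usage balance,
and panic.

## The model

The space is a square lattice of cells (default 51 × 51 = 2,601), each
either floor, obstacle, or one of two exits (*left*, *right*). A static
**floor field** is spread outward from each exit over the 8-connected
(Moore) walkability graph before the run: each walkable cell stores, per
exit, the minimal hop count `Hops` and the compass direction `Doms`
(0° = north, clockwise) of the best next step. Obstacles and exit cells
hold −1 sentinels.

Evacuees occupy one cell each and move at most one cell per tick. An agent
headed in direction θ scans its eight neighbors in a dial order of angular
offsets [0°, +45°, −45°, +90°, −90°, +135°, −135°, 180°] and takes the
first free walkable cell; stepping onto an exit cell removes it from the
simulation. After each move attempt the agent transitions between three
cognitive states — **WALK** when it moved, **WAIT** when blocked, and
**PANIC** when it has been blocked longer than a waiting threshold — and
exactly one of its three indices (moving / waiting / panic) is incremented
while the other two reset. A **Mobility Index** (MI) tracks movement
quality: +1 per WALK, −1 per WAIT, and `MI ← MI − MI·s` (sensitivity
`s = 0.5`) per PANIC tick.

Agents are *emotional* (follow their surroundings, default to the nearest
exit) or *rational* (play game-theoretic exit-choice rules). Four
strategies govern the per-tick exit decision:

* **S1 — individual**: everyone keeps the nearest exit (hop-count argmin).
* **S2 — local social**: a game against one random Moore neighbor; calm
  rational agents switch with probability 0.1 (neighbor agrees) or 0.9
  (neighbor disagrees); a panicking rational agent whose neighbor shares
  its exit switches with certainty (anti-herding); emotional agents adopt
  a disagreeing neighbor's exit with probability 0.1, only while panicking.
* **S3 — technological**: rational agents weigh panic (0.5), the social
  signal (0.25), and a decaying, agent-relayed **exit potential field**
  (PVL/PVR, 0.25) announcing recent exit usage; the weights sum to the
  switch probability of each branch. Emotional agents stick to the nearest
  exit.
* **S4 — small-world social**: S2 plus one static long-distance tie per
  rational agent; while panicking, the agent adopts the exit of its most
  mobile (max-MI) contact.

Preset environments E1–E4 add an obstacle wall of increasing extent in
front of the right exit, so an increasing majority of the floor is nearer
the left exit.

## Worked example

One full-scale run of the local-social strategy in the most uneven
environment:

```sh
egress run --env E4 --strategy S2 --agents 1000 --rational-pct 15 --seed 7
```

```json
{
  "n_agents": 1000,
  "exit_time": 321,
  "exited_left": 680,
  "exited_right": 320,
  "max_concurrent_panic": 13,
  "max_concurrent_panic_rational": 3,
  "ever_panicked_rational": 33,
  "ever_panicked_emotional": 227,
  "terminated": true
}
```

The room emptied in 321 ticks; 680 of 1,000 agents used the geometrically
favored left exit; at the worst moment 13 agents were simultaneously in
panic, and 260 agents panicked at least once. The same seed under `--strategy
S1` empties faster (248 ticks) but loads the left exit harder (696) — the
individual strategy is quicker while the social one balances exit usage.

Batch sweeps over environments × strategies × rational percentages:

```sh
egress sweep --spec sweep.yaml --out results/   # rows.csv + summary
```

From Python, `egress.experiments.qualitative_comparison()` runs the
scaled-down four-strategy comparison with paired seeds and reports
one-sided Wilcoxon p-values for the headline orderings.

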