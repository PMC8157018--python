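"""Exit potential fields: the "technological" information channel of S3.

Each patch carries one potential value per exit (PVL, PVR), in [0, 1].
Whenever an agent leaves through an exit, the Moore neighbors of that exit
patch are charged to 1 for that exit's field.  The field then travels only
on the backs of agents: once per tick, every *occupied* patch relays its
value to poorer neighbors at nine-tenths strength.  A multiplicative decay
erodes all values over time, so the signal reflects *recent* exit usage.
"""

from __future__ import annotations

import numpy as np

from .world import EXIT_LABELS, ConfigError, GridWorld, Patch, Structure

DEFAULT_DECAY = 0.99
DEFAULT_ATTENUATION = 0.9
SNAP_EPS = 1e-6

# Moore shifts as (dy, dx) for array rolling
_SHIFTS = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def seed_exit_potential(world: GridWorld, exit_pos: tuple[int, int],
                        label: str) -> GridWorld:
    """Set pv[label] = 1 on all in-bounds Moore neighbors of the exit patch
    just used (obstacles included make no difference downstream: they are
    never read or spread from, but we skip them for cleanliness)."""
    x, y = exit_pos
    pv = world.pv[label]
    for nx, ny in world.moore_coords(x, y):
        if world.structure[ny, nx] != Structure.OBSTACLE:
            pv[ny, nx] = 1.0
    return world


def spread_potential(world: GridWorld, attenuation: float = DEFAULT_ATTENUATION) -> GridWorld:
    """Agent-borne synchronous spread, once per tick after movement.

    From a snapshot of the field: for every occupied patch P with pv > 0
    and every Moore neighbor N with a strictly smaller snapshot value,
    N receives max(its value, attenuation × pv(P)).  Obstacles never
    receive potential.  Values stay in [0, 1].
    """
    occupied = world.occupant >= 0
    not_obstacle = world.structure != Structure.OBSTACLE
    for lab in EXIT_LABELS:
        snap = world.pv[lab].copy()
        src = np.where(occupied & (snap > 0), snap, 0.0)
        if not src.any():
            continue
        best = np.zeros_like(snap)
        h, w = snap.shape
        for dy, dx in _SHIFTS:
            # contribution to cell (y, x) from source at (y+dy, x+dx)
            contrib = np.zeros_like(snap)
            ys_dst = slice(max(0, -dy), min(h, h - dy))
            xs_dst = slice(max(0, -dx), min(w, w - dx))
            ys_src = slice(max(0, dy), min(h, h + dy))
            xs_src = slice(max(0, dx), min(w, w + dx))
            contrib[ys_dst, xs_dst] = src[ys_src, xs_src]
            gain = np.where(snap < contrib, attenuation * contrib, 0.0)
            best = np.maximum(best, gain)
        world.pv[lab] = np.clip(np.maximum(snap, np.where(not_obstacle, best, 0.0)), 0.0, 1.0)
    return world


def decay_potential(world: GridWorld, decay_factor: float = DEFAULT_DECAY) -> GridWorld:
    """Multiply both fields by ``decay_factor``; snap values below 1e-6 to 0."""
    if not 0 < decay_factor <= 1:
        raise ConfigError("decay_factor must be in (0, 1]")
    for lab in EXIT_LABELS:
        pv = world.pv[lab] * decay_factor
        pv[pv < SNAP_EPS] = 0.0
        world.pv[lab] = pv
    return world


def dominant_exit_values(pvl: float, pvr: float) -> str | None:
    """Label of the strictly greater potential; None when both are zero or
    tied (no dominant influence)."""
    if pvl > pvr:
        return "left"
    if pvr > pvl:
        return "right"
    return None


def dominant_exit(patch: Patch) -> str | None:
    """Patch-level convenience wrapper around :func:`dominant_exit_values`."""
    pv = patch.pv
    return dominant_exit_values(pv["left"], pv["right"])
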