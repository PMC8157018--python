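"""Batch experiment sweeps, aggregation, CSV output, and fixture maps.

The headline study design is a full factorial sweep over environment
presets, strategies, and rational-agent fractions, each case repeated with
several replicate seeds and summarized by per-case means.  Replicate seeds
are derived deterministically as ``base_seed + replicate_index`` — the same
replicate index therefore reuses identical initial agent placements across
strategies, giving paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RunResult, Simulation, SimulationConfig
from .world import ConfigError, EnvironmentSpec

SWEEP_COLUMNS = [
    "env", "strategy", "rational_pct", "replicate", "seed",
    "exit_time", "exited_left", "exited_right",
    "max_concurrent_panic", "max_concurrent_panic_rational",
    "ever_panicked_rational", "ever_panicked_emotional", "terminated",
]


@dataclass
class SweepSpec:
    """A full factorial sweep: envs × strategies × rational fractions ×
    replicates.  Defaults mirror the headline study design (4 envs ×
    4 strategies × {5,10,15,20}% rational × 50 replicates, 1000 agents on
    a 51×51 world)."""

    envs: list[EnvironmentSpec] = field(
        default_factory=lambda: [EnvironmentSpec(p) for p in ("E1", "E2", "E3", "E4")]
    )
    strategies: list[str] = field(default_factory=lambda: ["S1", "S2", "S3", "S4"])
    rational_pcts: list[float] = field(default_factory=lambda: [5, 10, 15, 20])
    replicates: int = 50
    base_seed: int = 0
    n_agents: int = 1000
    panic_threshold: int = 4
    max_ticks: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Execute every case × replicate; returns one row per run.

    Non-terminated runs (safety cap hit) are kept in the table but flagged
    ``terminated=False``; :func:`summarize` excludes them from means.
    """
    rows = []
    for env in spec.envs:
        for pct in spec.rational_pcts:
            for strategy in spec.strategies:
                for rep in range(spec.replicates):
                    cfg = SimulationConfig(
                        env=env,
                        n_agents=spec.n_agents,
                        rational_pct=pct,
                        strategy=strategy,
                        panic_threshold=spec.panic_threshold,
                        seed=spec.base_seed + rep,
                        max_ticks=spec.max_ticks,
                    )
                    res = Simulation(cfg).run()
                    rows.append({
                        "env": env.preset_id,
                        "strategy": strategy,
                        "rational_pct": pct,
                        "replicate": rep,
                        "seed": cfg.seed,
                        **res.to_dict(),
                    })
                    if progress:
                        print(f"\r{len(rows)} runs done", end="", flush=True)
    if progress:
        print()
    df = pd.DataFrame(rows)
    return df[[c for c in SWEEP_COLUMNS if c in df.columns]]


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-case mean and standard deviation over terminated replicates."""
    metrics = [
        "exit_time", "exited_left", "exited_right",
        "max_concurrent_panic", "max_concurrent_panic_rational",
        "ever_panicked_rational", "ever_panicked_emotional",
    ]
    done = rows[rows["terminated"]]
    g = done.groupby(["env", "strategy", "rational_pct"])[metrics]
    out = g.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    out["n_replicates"] = g.size()
    return out.reset_index()


def write_metrics_csv(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write the row table as RFC-4180 CSV (full float precision); a
    per-case summary lands alongside as ``<stem>_summary.csv``."""
    if rows.empty:
        raise ValueError("refusing to write an empty metrics table")
    path = Path(path)
    rows.to_csv(path, index=False)
    summarize(rows).to_csv(path.with_name(path.stem + "_summary.csv"), index=False)
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def generate_fixture_world(kind: str, size: int,
                           rng: np.random.Generator | None = None) -> str:
    """Emit map text for small test geometries.

    All fixture kinds use single-cell doorway exits centered on the west
    and east walls: at fixture scale a narrow doorway is what produces the
    congestion, queueing and panic dynamics the simulator is about.

    * ``open``: bare room, no obstacles.
    * ``corridor``: a one-cell-wide passage connecting the two exits;
      everything else is obstacle.
    * ``pocket``: an open room plus a sealed obstacle box whose interior is
      unreachable from both exits.
    * ``asymmetric``: a partial vertical wall shielding the right exit
      (spanning 0.8 of the side length, like the most uneven preset), so
      most of the floor is nearer the left exit.
    """
    if size < 7:
        raise ConfigError("fixture size must be >= 7")
    c = size // 2
    grid = np.full((size, size), ".", dtype="<U1")
    if kind == "open":
        grid[c, 0], grid[c, size - 1] = "L", "R"
    elif kind == "corridor":
        grid[:, :] = "#"
        grid[c, :] = "."
        grid[c, 0], grid[c, size - 1] = "L", "R"
    elif kind == "pocket":
        grid[c, 0], grid[c, size - 1] = "L", "R"
        # sealed 3x3 box with an unreachable interior cell, away from exits
        by, bx = size - 2, c  # top edge, centered
        grid[by - 1 : by + 2, bx - 1 : bx + 2] = "#"
        grid[by, bx] = "."
    elif kind == "asymmetric":
        grid[c, 0], grid[c, size - 1] = "L", "R"
        half = max(1, int(round(0.8 * size / 2)))
        half = min(half, c - 2)
        grid[c - half : c + half + 1, size - 3] = "#"
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    return "\n".join("".join(row) for row in grid[::-1])


def scaled_panic_threshold(size: int, full_size: int = 51,
                           full_threshold: int = 4) -> int:
    """Waiting-tolerance for a scaled-down world.

    The WAIT→PANIC threshold is a patience measured in ticks; egress time
    scales roughly with the side length, so a fixture-scale study keeps
    patience proportional to the world's time scale rather than fixed:
    ``round(full_threshold * size / full_size)``, at least 1.
    """
    return max(1, int(round(full_threshold * size / full_size)))


def qualitative_comparison(size: int = 21, n_agents: int = 200,
                           rational_pct: float = 15.0, replicates: int = 10,
                           base_seed: int = 0) -> dict:
    """Scaled-down reproduction of the headline strategy orderings.

    Runs all four strategies on an asymmetric fixture world with paired
    replicate seeds and evaluates, by one-sided paired Wilcoxon signed-rank
    tests, the groupings reported at full scale: the social strategies
    {S2, S4} panic less and use the left exit less than their non-social
    counterparts {S1, S3}, while the individual strategy S1 evacuates no
    slower than S2.

    Returns a dict with the raw row table, per-strategy means, and the
    p-value of each ordering test.
    """
    from scipy import stats

    env = EnvironmentSpec("custom", generate_fixture_world("asymmetric", size))
    threshold = scaled_panic_threshold(size)
    rows = []
    for strategy in ("S1", "S2", "S3", "S4"):
        for rep in range(replicates):
            cfg = SimulationConfig(
                env=env, n_agents=n_agents, rational_pct=rational_pct,
                strategy=strategy, panic_threshold=threshold,
                seed=base_seed + rep,
            )
            d = Simulation(cfg).run().to_dict()
            d["strategy"], d["replicate"] = strategy, rep
            d["ever_panicked"] = (
                d["ever_panicked_rational"] + d["ever_panicked_emotional"]
            )
            rows.append(d)
    df = pd.DataFrame(rows)
    piv = df.pivot(index="replicate", columns="strategy")

    def one_sided_less(metric: str, a: str, b: str) -> float:
        diff = piv[(metric, a)] - piv[(metric, b)]
        if (diff == 0).all():
            return 1.0  # no evidence either way
        return float(stats.wilcoxon(piv[(metric, a)], piv[(metric, b)],
                                    alternative="less").pvalue)

    tests = {
        "panic_S2_lt_S1": one_sided_less("ever_panicked", "S2", "S1"),
        "panic_S4_lt_S3": one_sided_less("ever_panicked", "S4", "S3"),
        "exit_time_S1_le_S2": one_sided_less("exit_time", "S1", "S2"),
        "left_usage_S2_lt_S1": one_sided_less("exited_left", "S2", "S1"),
    }
    means = df.groupby("strategy")[
        ["exit_time", "exited_left", "ever_panicked", "max_concurrent_panic"]
    ].mean()
    return {"rows": df, "means": means, "tests": tests,
            "panic_threshold": threshold}


def plot_metric(summary: pd.DataFrame, metric: str, path: str | Path,
                rational_pct: float | None = None) -> Path:
    """Grouped bar chart of a per-case mean: environments on the x-axis,
    one bar per strategy."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = summary
    if rational_pct is not None:
        data = data[data["rational_pct"] == rational_pct]
    pivot = data.pivot_table(index="env", columns="strategy",
                             values=f"{metric}_mean")
    ax = pivot.plot.bar(rot=0)
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_xlabel("environment")
    fig = ax.get_figure()
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
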