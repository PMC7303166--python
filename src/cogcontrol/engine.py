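"""Seeded simulation runs, trajectory recording, and replicates.

A run iterates, once per generation: environment relaxation (from the
previous generation's strategies), fitness evaluation, and a single Moran
death-birth event.  The population-mean strategy and environment are recorded
every generation; full strategy snapshots are kept at a configurable stride
so that memory stays bounded for long runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Params, PopulationState, Scenario, moran_step, update_environment
from .topology import Topology, make_complete, make_ring, make_small_world, write_edgelist, read_edgelist

__all__ = ["TopologySpec", "RunConfig", "Trajectory", "run", "run_replicates",
           "save_trajectory", "load_trajectory"]


@dataclass(frozen=True)
class TopologySpec:
    """Recipe for the interaction graph of a run."""

    kind: str = "ring"
    n: int = 100
    k: int = 2
    beta: float = 0.0  # small_world rewiring rate

    def build(self, seed: int = 0) -> Topology:
        if self.kind == "ring":
            return make_ring(self.n, self.k)
        if self.kind == "complete":
            return make_complete(self.n)
        if self.kind == "small_world":
            return make_small_world(self.n, self.k, self.beta, seed)
        raise ValueError(f"unknown topology kind {self.kind!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run.

    ``burn_in`` generations are excluded from equilibrium summaries; the
    default (half the run) matches the convention of averaging the last half
    of an 8e4-generation run for the stable strategy.
    """

    params: Params = field(default_factory=Params)
    scenario: Scenario = field(default_factory=Scenario)
    topology: TopologySpec = field(default_factory=TopologySpec)
    generations: int = 80_000
    seed: int = 0
    x0: float = 0.01
    p0: float | None = None  # default: 1 - x0
    record_every: int = 100
    burn_in: int | None = None  # default: generations // 2

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (1 <= self.record_every <= self.generations):
            raise ValueError("record_every must lie in [1, generations]")
        bi = self.burn_in
        if bi is not None and not (0 <= bi < self.generations):
            raise ValueError("burn_in must lie in [0, generations)")
        if not (0.0 <= self.x0 <= 1.0):
            raise ValueError("x0 must lie in [0, 1]")

    @property
    def effective_burn_in(self) -> int:
        return self.generations // 2 if self.burn_in is None else self.burn_in

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["params"] = Params(**d["params"])
        d["scenario"] = Scenario(**d["scenario"])
        d["topology"] = TopologySpec(**d["topology"])
        return cls(**d)


@dataclass
class Trajectory:
    """Recorded output of one run.

    mean_x, mean_p : per-generation series of length generations + 1
        (index 0 is the initial state; under a local environment mean_p is
        the population mean of the per-agent p).
    snapshots : (n_snapshots, n_agents) strategy matrix at the recorded
        generations ``snapshot_gens`` (initial state included).
    p_snapshots : per-agent environment at the same generations under a
        local environment, else None.
    """

    config: RunConfig
    topology: Topology
    mean_x: np.ndarray
    mean_p: np.ndarray
    snapshots: np.ndarray
    snapshot_gens: np.ndarray
    p_snapshots: np.ndarray | None = None

    @property
    def analysis_window(self) -> tuple[int, int]:
        """Post-burn-in generation range [start, end] for summaries."""
        return (self.config.effective_burn_in, self.config.generations)

    def window_snapshot_mask(self, window: tuple[int, int] | None = None) -> np.ndarray:
        lo, hi = window if window is not None else self.analysis_window
        return (self.snapshot_gens >= lo) & (self.snapshot_gens <= hi)

    def equilibrium_mean_x(self, window: tuple[int, int] | None = None) -> float:
        """Time-averaged population-mean strategy over the analysis window."""
        lo, hi = window if window is not None else self.analysis_window
        return float(self.mean_x[lo : hi + 1].mean())


def run(config: RunConfig) -> Trajectory:
    """Run one seeded simulation.

    Per generation: (1) the environment relaxes using the previous
    generation's strategies, (2) fitnesses are evaluated with the updated
    environment and current strategies, (3) one Moran death-birth event
    fires.  Identical configs (same seed) give bit-identical trajectories.
    """
    top = config.topology.build(seed=config.seed)
    scenario = config.scenario
    params = config.params
    rng = np.random.default_rng(config.seed)
    state = PopulationState.initial(top.n_agents, scenario, x0=config.x0, p0=config.p0)

    gens = config.generations
    stride = config.record_every
    n_snap = gens // stride + 1
    mean_x = np.empty(gens + 1)
    mean_p = np.empty(gens + 1)
    snapshots = np.empty((n_snap, top.n_agents))
    snapshot_gens = np.empty(n_snap, dtype=np.intp)
    local_env = scenario.environment == "local"
    p_snapshots = np.empty((n_snap, top.n_agents)) if local_env else None

    mean_x[0] = state.x.mean()
    mean_p[0] = state.p.mean() if local_env else state.p
    snapshots[0] = state.x
    snapshot_gens[0] = 0
    if local_env:
        p_snapshots[0] = state.p
    si = 1

    need_means = local_env or scenario.contact == "local"
    for t in range(1, gens + 1):
        m = top.neighborhood_mean(state.x, include_self=True) if need_means else None
        update_environment(state, top, scenario, params, neighbor_means=m)
        cm = m if scenario.contact == "local" else state.x.mean()
        moran_step(state, top, scenario, params, rng, contact_means=cm)
        mean_x[t] = state.x.mean()
        mean_p[t] = state.p.mean() if local_env else state.p
        if t % stride == 0:
            snapshots[si] = state.x
            snapshot_gens[si] = t
            if local_env:
                p_snapshots[si] = state.p
            si += 1

    return Trajectory(config=config, topology=top, mean_x=mean_x, mean_p=mean_p,
                      snapshots=snapshots, snapshot_gens=snapshot_gens,
                      p_snapshots=p_snapshots)


def replicate_seeds(base_seed: int, n_replicates: int) -> list[int]:
    """Deterministic per-replicate seeds: base_seed + i."""
    return [base_seed + i for i in range(n_replicates)]


def run_replicates(config: RunConfig, n_replicates: int) -> list[Trajectory]:
    """Independent replicate runs with seeds ``config.seed + i``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [run(replace(config, seed=s))
            for s in replicate_seeds(config.seed, n_replicates)]


# ---------------------------------------------------------------------------
# persistence (CSV series + CSV snapshot matrix + JSON sidecar config)


def save_trajectory(traj: Trajectory, out_dir: str | Path) -> Path:
    """Write series.csv, snapshots.csv, topology.txt, and config.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "generation": np.arange(traj.mean_x.size),
        "mean_x": traj.mean_x,
        "mean_p": traj.mean_p,
    }).to_csv(out / "series.csv", index=False)
    snap = pd.DataFrame(traj.snapshots)
    snap.insert(0, "generation", traj.snapshot_gens)
    snap.to_csv(out / "snapshots.csv", index=False)
    if traj.p_snapshots is not None:
        psnap = pd.DataFrame(traj.p_snapshots)
        psnap.insert(0, "generation", traj.snapshot_gens)
        psnap.to_csv(out / "p_snapshots.csv", index=False)
    write_edgelist(traj.topology, out / "topology.txt")
    (out / "config.json").write_text(json.dumps(traj.config.to_dict(), indent=2))
    return out


def load_trajectory(out_dir: str | Path) -> Trajectory:
    """Load a trajectory saved by :func:`save_trajectory`."""
    out = Path(out_dir)
    config = RunConfig.from_dict(json.loads((out / "config.json").read_text()))
    series = pd.read_csv(out / "series.csv")
    snap = pd.read_csv(out / "snapshots.csv")
    snapshot_gens = snap["generation"].to_numpy(dtype=np.intp)
    snapshots = snap.drop(columns="generation").to_numpy(dtype=float)
    p_path = out / "p_snapshots.csv"
    p_snapshots = None
    if p_path.exists():
        psnap = pd.read_csv(p_path)
        p_snapshots = psnap.drop(columns="generation").to_numpy(dtype=float)
    top = read_edgelist(out / "topology.txt", n_agents=config.topology.n,
                        kind=config.topology.kind)
    return Trajectory(config=config, topology=top,
                      mean_x=series["mean_x"].to_numpy(),
                      mean_p=series["mean_p"].to_numpy(),
                      snapshots=snapshots, snapshot_gens=snapshot_gens,
                      p_snapshots=p_snapshots)
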