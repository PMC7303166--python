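"""Parameter sweeps over scenarios and model constants, and raster export.

A sweep runs every (scenario, c, w, tau_p) cell for a number of replicates,
summarizes each cell with the statistics module, and returns tidy tables —
one row per replicate and one aggregated row per cell (replicate means with
95% CIs).  Deterministic given the base seed: cell c gets base seed
``seed + 1000 * cell_index`` and replicate r within it ``+ r``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import Scenario
from .engine import RunConfig, Trajectory, run_replicates
from .stats import SameStrategyRule, summarize_replicates

__all__ = ["SweepSpec", "sweep", "raster_export", "config_hash"]

log = logging.getLogger("cogcontrol")

_STAT_COLS = ("mean_control", "assortment", "strategy_variance", "mean_peak")


@dataclass(frozen=True)
class SweepSpec:
    """Grid of simulation cells.

    The default c/w grids span the regimes where contact with automatic
    agents harms (w < 0), leaves unaffected (w = 0), or helps (w > 0)
    controlled agents, around the anchor cell (c = 0.5, w = -0.15).
    """

    c_values: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    w_values: tuple = (-0.3, -0.15, 0.0, 0.15, 0.3)
    tau_p_values: tuple = (1.0,)
    scenarios: tuple = field(default_factory=Scenario.all_scenarios)
    replicates: int = 10
    base: RunConfig = field(default_factory=RunConfig)
    rule: SameStrategyRule = field(default_factory=SameStrategyRule)

    def __post_init__(self):
        if not (self.c_values and self.w_values and self.tau_p_values and self.scenarios):
            raise ValueError("all sweep lists must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self):
        i = 0
        for scen in self.scenarios:
            for tau in self.tau_p_values:
                for c in self.c_values:
                    for w in self.w_values:
                        yield i, scen, float(c), float(w), float(tau)
                        i += 1


def sweep(spec: SweepSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the grid; return (per_replicate, aggregated) tables."""
    rep_rows, agg_rows = [], []
    for idx, scen, c, w, tau in spec.cells():
        log.info("cell %d: scenario=%s c=%g w=%g tau_p=%g (%d replicates, %d generations)",
                 idx, scen.tag, c, w, tau, spec.replicates, spec.base.generations)
        try:
            params = replace(spec.base.params, c=c, w=w, tau_p=tau)
            cfg = replace(spec.base, params=params, scenario=scen,
                          seed=spec.base.seed + 1000 * idx)
            trajs = run_replicates(cfg, spec.replicates)
            summary = summarize_replicates(trajs, rule=spec.rule)
        except Exception as exc:
            raise RuntimeError(
                f"sweep cell failed: scenario={scen.tag} c={c} w={w} tau_p={tau}"
            ) from exc
        key = dict(scenario=scen.tag, learning=scen.learning, contact=scen.contact,
                   environment=scen.environment, c=c, w=w, tau_p=tau)
        for r, traj in enumerate(trajs):
            one = summarize_replicates([traj], rule=spec.rule)
            rep_rows.append({**key, "replicate": r, "seed": traj.config.seed,
                             **{col: getattr(one, col) for col in _STAT_COLS}})
        row = {**key, "replicates": spec.replicates,
               **{col: getattr(summary, col) for col in _STAT_COLS}}
        for col, ci in summary.ci95.items():
            row[f"{col}_ci_lo"], row[f"{col}_ci_hi"] = ci.lo, ci.hi
        agg_rows.append(row)
    return pd.DataFrame(rep_rows), pd.DataFrame(agg_rows)


def config_hash(obj) -> str:
    """Short provenance hash of a config-like object (dataclass or dict)."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def raster_export(traj: Trajectory, path: str | Path, image: bool = False) -> Path:
    """Write the agents × recorded-generations strategy matrix.

    The CSV has one row per agent (ring position) and one column per
    recorded generation; under local learning, contiguous bands of rows with
    similar values are the mesoscale communities.  With ``image=True`` a PNG
    heatmap (agents on the vertical axis, generations horizontal) is also
    rendered next to the CSV.
    """
    if traj.snapshots.shape[0] < 1:
        raise ValueError("trajectory has no snapshots")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat = traj.snapshots.T  # (n_agents, n_snapshots)
    df = pd.DataFrame(mat, columns=[f"gen_{g}" for g in traj.snapshot_gens])
    df.insert(0, "agent", np.arange(mat.shape[0]))
    with open(path, "w") as fh:
        fh.write(f"# config_hash = {config_hash(traj.config)}\n")
        df.to_csv(fh, index=False)
    if image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        im = ax.imshow(mat, aspect="auto", origin="lower", cmap="Reds",
                       vmin=0.0, vmax=1.0,
                       extent=(0, traj.snapshot_gens[-1], 0, mat.shape[0]))
        ax.set_xlabel("generation")
        ax.set_ylabel("agent (ring position)")
        ax.set_title(f"controlled processing x — {traj.config.scenario.tag}")
        fig.colorbar(im, ax=ax, label="x")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=150)
        plt.close(fig)
    return path
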