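"""Flat key-value config files for runs and sweeps.

Format: one ``key = value`` pair per line; ``#`` starts a comment.  Keys::

    c, w, s, u, tau_p            model parameters
    learning, contact, environment   scenario scopes (local | global)
    topology.kind, topology.n, topology.k, topology.beta
    generations, seed, x0, record_every, burn_in

Sweep configs additionally accept comma-separated lists::

    c_values, w_values, tau_p_values, scenarios (tags like LLL,GGG or "all"),
    replicates
"""

from __future__ import annotations

from pathlib import Path

from .dynamics import Params, Scenario
from .engine import RunConfig, TopologySpec

__all__ = ["load_keyvalues", "save_keyvalues", "run_config_from_file",
           "run_config_to_file", "scenario_from_tag"]


def load_keyvalues(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def save_keyvalues(pairs: dict, path: str | Path) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in pairs.items()))


def scenario_from_tag(tag: str) -> Scenario:
    """Expand a 3-letter tag like ``LGL`` (learning, contact, environment)."""
    tag = tag.strip().upper()
    if len(tag) != 3 or any(ch not in "LG" for ch in tag):
        raise ValueError(f"scenario tag must be 3 letters from {{L, G}}, got {tag!r}")
    scope = {"L": "local", "G": "global"}
    return Scenario(scope[tag[0]], scope[tag[1]], scope[tag[2]])


def run_config_from_file(path: str | Path) -> RunConfig:
    kv = load_keyvalues(path)

    def get(key, cast, default):
        return cast(kv[key]) if key in kv else default

    params = Params(
        c=get("c", float, 0.5), w=get("w", float, -0.15), s=get("s", float, 10.0),
        u=get("u", float, 0.01), tau_p=get("tau_p", float, 1.0),
    )
    scenario = Scenario(
        learning=get("learning", str, "local"),
        contact=get("contact", str, "local"),
        environment=get("environment", str, "local"),
    )
    topology = TopologySpec(
        kind=get("topology.kind", str, "ring"), n=get("topology.n", int, 100),
        k=get("topology.k", int, 2), beta=get("topology.beta", float, 0.0),
    )
    burn_in = get("burn_in", int, None)
    return RunConfig(
        params=params, scenario=scenario, topology=topology,
        generations=get("generations", int, 80_000), seed=get("seed", int, 0),
        x0=get("x0", float, 0.01), record_every=get("record_every", int, 100),
        burn_in=burn_in,
    )


def run_config_to_file(config: RunConfig, path: str | Path) -> None:
    p, sc, tp = config.params, config.scenario, config.topology
    pairs = {
        "c": p.c, "w": p.w, "s": p.s, "u": p.u, "tau_p": p.tau_p,
        "learning": sc.learning, "contact": sc.contact, "environment": sc.environment,
        "topology.kind": tp.kind, "topology.n": tp.n, "topology.k": tp.k,
        "topology.beta": tp.beta,
        "generations": config.generations, "seed": config.seed, "x0": config.x0,
        "record_every": config.record_every,
    }
    if config.burn_in is not None:
        pairs["burn_in"] = config.burn_in
    save_keyvalues(pairs, path)
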