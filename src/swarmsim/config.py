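"""Flat key-value (YAML) serialization of simulation configurations.

The file is a single flat mapping.  The 11 model parameters use their bare
names (``gamma``, ``scale``, ``gain``, ``chi_rep``, ``r_rep``, ``chi_ali``,
``r_ali``, ``chi_att``, ``r_att``, ``chi_res``, ``r_res``); other sections
use dotted keys (``noise.kind``, ``avoidance.agent_radius``,
``sim.n_insects``, ...).  ``radius_convention`` may be ``absolute``
(default) or ``differences``, in which case ``r_ali`` / ``r_att`` hold the
shell widths rali* = r_ali - r_rep and ratt* = r_att - r_ali.
"""

from __future__ import annotations

import numpy as np
import yaml

from .avoidance import AvoidanceConfig
from .core import Stimulus, SwarmParams
from .noise import NoiseSpec
from .simulator import SimConfig

__all__ = ["config_to_dict", "config_from_dict", "save_config", "load_config"]

_SIM_KEYS = ("n_insects", "dt", "n_frames", "boundary_mode", "seed",
             "drag_form", "critical_density", "scenario")
_AVOID_KEYS = ("agent_radius", "time_horizon", "max_speed", "dt",
               "infeasible_policy", "max_neighbors")


def config_to_dict(cfg: SimConfig) -> dict:
    """Flatten a SimConfig into a plain mapping of scalars."""
    d: dict = {}
    d.update(cfg.params.to_dict())
    d["radius_convention"] = "absolute"
    d["noise.kind"] = cfg.noise.kind
    d["noise.scale"] = float(cfg.noise.scale)
    d["noise.gain"] = float(cfg.noise.gain)
    if cfg.noise.lam is not None:
        d["noise.lambda"] = float(cfg.noise.lam)
    d["noise.seed"] = int(cfg.noise.seed)
    for k in _SIM_KEYS:
        d[f"sim.{k}"] = getattr(cfg, k)
    for ax, name in enumerate("xyz"):
        d[f"box.{name}_min"] = float(cfg.box[ax, 0])
        d[f"box.{name}_max"] = float(cfg.box[ax, 1])
    for k in _AVOID_KEYS:
        d[f"avoidance.{k}"] = getattr(cfg.avoidance, k)
    for si, s in enumerate(cfg.stimuli):
        if callable(s.position):
            continue  # programmatic stimuli are not serializable
        d[f"stimulus.{si}.x"], d[f"stimulus.{si}.y"], d[f"stimulus.{si}.z"] = (
            float(v) for v in s.position
        )
        d[f"stimulus.{si}.kind"] = int(s.kind)
        d[f"stimulus.{si}.start_frame"] = int(s.start_frame)
        if s.end_frame is not None:
            d[f"stimulus.{si}.end_frame"] = int(s.end_frame)
    return d


def config_from_dict(d: dict) -> SimConfig:
    conv = d.get("radius_convention", "absolute")
    params = SwarmParams.from_dict(d, radius_convention=conv)

    sim_kw = {k: d[f"sim.{k}"] for k in _SIM_KEYS if f"sim.{k}" in d}
    box = np.array(
        [
            [d.get("box.x_min", 0.0), d.get("box.x_max", 20.0)],
            [d.get("box.y_min", 0.0), d.get("box.y_max", 20.0)],
            [d.get("box.z_min", 0.0), d.get("box.z_max", 20.0)],
        ]
    )
    avoid_kw = {k: d[f"avoidance.{k}"] for k in _AVOID_KEYS if f"avoidance.{k}" in d}
    avoidance = AvoidanceConfig(**avoid_kw) if avoid_kw else AvoidanceConfig()

    stimuli = []
    si = 0
    while f"stimulus.{si}.x" in d:
        stimuli.append(
            Stimulus(
                position=np.array(
                    [d[f"stimulus.{si}.x"], d[f"stimulus.{si}.y"], d[f"stimulus.{si}.z"]]
                ),
                kind=int(d.get(f"stimulus.{si}.kind", 0)),
                start_frame=int(d.get(f"stimulus.{si}.start_frame", 0)),
                end_frame=d.get(f"stimulus.{si}.end_frame"),
            )
        )
        si += 1

    noise = NoiseSpec(
        kind=d.get("noise.kind", "curl"),
        scale=float(d.get("noise.scale", params.scale)),
        gain=float(d.get("noise.gain", params.gain)),
        lam=d.get("noise.lambda"),
        seed=int(d.get("noise.seed", sim_kw.get("seed", 0))),
    )
    return SimConfig(
        params=params, noise=noise, avoidance=avoidance,
        stimuli=stimuli, box=box, **sim_kw,
    )


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} does not hold a flat mapping")
    return config_from_dict(d)
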