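"""YAML configuration for generation and analysis."""

from __future__ import annotations

import numpy as np
import yaml

from .synthetic_data import GenParams


def genparams_from_yaml(path, seed: int | None = None) -> tuple[GenParams, float]:
    """Load GenParams (plus session duration) from a YAML file.

    Any GenParams field may appear at top level; ``duration_s`` (default
    3600) sets the session length. A ``seed`` argument overrides the file.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    duration_s = float(cfg.pop("duration_s", 3600.0))
    if "state_transition_matrix" in cfg:
        cfg["state_transition_matrix"] = np.asarray(cfg["state_transition_matrix"], dtype=float)
    if "stim_times" in cfg:
        cfg["stim_times"] = np.asarray(cfg["stim_times"], dtype=float)
    if seed is not None:
        cfg["seed"] = seed
    for key in ("band_power_by_state",):
        if key in cfg:
            cfg[key] = {k: tuple(v) for k, v in cfg[key].items()}
    return GenParams(**cfg), duration_s


def default_stim_times(first_hour_s: float = 3600.0, rng=None) -> np.ndarray:
    """Stimulus onsets every 30-45 s through the initial stimulation period."""
    rng = np.random.default_rng(0) if rng is None else rng
    times, t = [], 10.0
    while t < first_hour_s - 15.0:
        times.append(t)
        t += rng.uniform(30.0, 45.0)
    return np.asarray(times)
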