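"""Default numeric constants for every pipeline stage, overridable via YAML."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "peth": {
        "bin_width_s": 0.02,
        "window_s": [-1.0, 1.0],
        "baseline_window_s": [-1.0, -0.2],
        "stat_window_s": [-0.5, 0.5],
        "n_boot": 1000,
        "alpha": 0.001,
    },
    "inclusion": {
        "min_rate_hz": 0.5,
    },
    "ethogram": {
        "min_run_frames": 10,
        "speed_threshold_mm_s": None,      # null disables the motion criterion
        "synchrony_window_s": 0.2,
        "onset_fraction": 0.05,
        "fit_margin_s": 0.5,
    },
    "preference": {
        "peak_window_s": [-0.2, 0.5],
        "mw_alpha": 0.05,
        "n_perm": 10000,
        "peak_per_condition": True,        # vs one pooled peak per unit
    },
    "geometry": {
        "soft_norm_hz": 5.0,
        "alignment_dim": 10,
        "angle_subspace_dim": 1,
        "n_boot": 1000,
        "n_perm": 10000,
        "center": True,
    },
    "correlation": {
        "bin_s": 0.005,
    },
    "decoding": {
        "lag_before_s": 0.200,
        "lag_after_s": 0.050,
        "lambda_grid": {"log10_min": -2, "log10_max": 4, "n": 13},
        "n_folds": 5,
        "n_boot": 1000,
        "n_chunks": 20,
        "dims": ["x", "y", "z"],
    },
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """DEFAULTS, deep-merged with an optional YAML override file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        _merge(cfg, overrides)
    return cfg


def _merge(base: dict, overrides: dict) -> None:
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v
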