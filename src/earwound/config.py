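"""Run configuration: defaults, YAML loading, dotted overrides.

Every tunable parameter of the pipeline lives here with an explicit unit
suffix (``_um``, ``_s``, ``_per_day``).  Defaults encode the study design
being emulated: a mouse-ear arterial transsection imaged twice daily from
3.5 to 6.5 days post-transection (dpt), with tracer-perfusion sessions at
4, 6 and 8 dpt.
"""

from __future__ import annotations

import copy
import json
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

#: structural (anatomy + calcium) imaging grid, days post-transection
STRUCTURAL_SESSIONS_DPT = (3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5)
#: tracer-perfusion imaging grid
PERFUSION_SESSIONS_DPT = (4.0, 6.0, 8.0)

#: treatment group labels and cohort sizes
DEFAULT_GROUPS = {"control": 10, "sunitinib": 7, "AZD4547": 7, "combo": 7}

GROUP_COLORS = {
    "control": "tab:blue",
    "AZD4547": "tab:red",
    "sunitinib": "gold",
    "combo": "tab:orange",
}

DEFAULTS: dict[str, Any] = {
    "master_seed": 42,
    "groups": dict(DEFAULT_GROUPS),
    "sessions": {
        "structural_dpt": list(STRUCTURAL_SESSIONS_DPT),
        "perfusion_dpt": list(PERFUSION_SESSIONS_DPT),
    },
    "scene": {
        "fov_um": 1000.0,
        "wound_width_um": 300.0,
        "n_arteries": 1,
        "artery_radius_um": 15.0,
        "vein_radius_um": 20.0,
        "vein_offset_um": 60.0,
    },
    "sprouting": {
        # population (session-mean) dynamics; per-sprout elongation is
        # derived internally (see sim.sprouting)
        "birth_rate_per_day": 1.5,
        "onset_dpt": 3.5,
        "elongation_um_per_day": 10.4,
        "elongation_cv": 0.3,
        "p_perfused": 2.0 / 3.0,
        "sprout_radius_um": 8.0,
        "min_length_um": 10.0,
    },
    "perfusion": {
        # probability of an artery-to-vein anastomosis per side and dpt
        "p_prox_anastomosis": {4.0: 0.9, 6.0: 1.0, 8.0: 1.0},
        "p_dist_anastomosis": {4.0: 0.8, 6.0: 1.0, 8.0: 1.0},
        # wound-crossing arrival difference t(C)-t(B), seconds
        "dt_cb_mean_s": {4.0: 4.74, 6.0: 1.0, 8.0: 0.0},
        "dt_cb_sd_s": {4.0: 6.62, 6.0: 1.0, 8.0: 0.0},
        # |dt| along a stump fed by its own anastomosis (half-normal)
        "ana_dt_scale_s": 0.3,
        "ana_dt_loc_s": 0.5,
        "ana_dt_max_s": 1.1,
        # bolus circulation time to ROI A after injection (lognormal)
        "bolus_mu_log_s": float(np.log(10.0)),
        "bolus_sigma_log": 0.3,
        # tracer reaching the distal stump through a vein route only
        "vein_transit_mean_s": {4.0: 5.0, 6.0: 1.5, 8.0: 0.5},
        # sprout length treated as functionally spanning the wound
        "span_threshold_um": 20.0,
        "baseline_s": 20.0,  # 30 frames at 2/3 s before injection
    },
    "calcium": {
        "session_s": 1320.0,  # 22 min
        "frame_period_s": 0.66,  # 2000 frames per session
        "peak_dpt": 5.0,
        "peak_rate_per_session": 5.0,
        "rise_start_dpt": 3.0,
        "fall_end_dpt": 8.0,
        "proximal_factor": 0.1,
        "amplitude_dff_mean": 1.0,
        "amplitude_dff_cv": 0.25,
        "decay_tau_s": 5.0,
        "noise_dff_sd": 0.05,
    },
    "imaging": {
        "frame_period_s": 2.0 / 3.0,
        "n_baseline_frames": 30,
        "resolution_px": 256,
        "n_z": 8,
        "z_step_um": 2.0,
        "tracer_fill_tau_s": 0.25,
        "trace_baseline": 100.0,
        "trace_amplitude": 500.0,
        "trace_snr": 10.0,
    },
    "detection": {
        "k_sd": 3.0,
        "min_consecutive": 2,
        "anastomosis_threshold_s": 1.3,
        "perfusion_window_s": 66.66,
        "ca_k_sd": 3.0,
        "ca_min_duration_s": 2.0,
        "ca_merge_gap_s": 1.0,
        "ca_baseline_percentile": 20.0,
        "ca_baseline_window_s": 60.0,
        "snr_threshold": 3.0,
        "coverage_fraction": 0.5,
    },
    "treatment": {
        # multiplicative suppression relative to control
        "mono_birth_factor": 0.5,
        "mono_elongation_factor": 0.5,
        "combo_birth_factor": 0.25,
        "combo_elongation_factor": 0.25,
        # anastomosis-probability factors, linear in dpt between anchors
        "mono_prox_ana_factor": {4.0: 0.3, 8.0: 0.7},
        "combo_prox_ana_factor": {4.0: 0.4, 8.0: 0.45},
        "mono_dist_ana_factor": {4.0: 0.8, 8.0: 1.0},
        "combo_dist_ana_factor": {4.0: 0.6, 8.0: 0.6},
        "onset_dpt": 1.0,
    },
}


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration values."""


def default_config() -> dict[str, Any]:
    """Return a deep copy of the default run configuration."""
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: Mapping) -> dict:
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown configuration key: {key!r}")
        if isinstance(base[key], dict) and isinstance(val, Mapping):
            _merge(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Build a config: defaults, optionally updated from a YAML/JSON file
    and then from dotted-key overrides (``{"sprouting.birth_rate_per_day": 2}``).
    """
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} does not contain a mapping")
        _merge(cfg, data)
    if overrides:
        for dotted, value in overrides.items():
            set_dotted(cfg, dotted, value)
    validate_config(cfg)
    return cfg


def set_dotted(cfg: dict, dotted: str, value: Any) -> None:
    """Set ``cfg["a"]["b"] = value`` from ``"a.b"``, parsing YAML scalars."""
    keys = dotted.split(".")
    node = cfg
    for key in keys[:-1]:
        if key not in node or not isinstance(node[key], dict):
            raise ConfigError(f"unknown configuration key: {dotted!r}")
        node = node[key]
    leaf = keys[-1]
    if leaf not in node:
        raise ConfigError(f"unknown configuration key: {dotted!r}")
    if isinstance(value, str):
        value = yaml.safe_load(value)
    node[leaf] = value


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Check basic invariants; raise :class:`ConfigError` naming the key."""
    if cfg["scene"]["wound_width_um"] >= cfg["scene"]["fov_um"]:
        raise ConfigError("scene.wound_width_um must be smaller than scene.fov_um")
    if cfg["sprouting"]["birth_rate_per_day"] < 0:
        raise ConfigError("sprouting.birth_rate_per_day must be non-negative")
    if cfg["sprouting"]["elongation_um_per_day"] < 0:
        raise ConfigError("sprouting.elongation_um_per_day must be non-negative")
    p = cfg["sprouting"]["p_perfused"]
    if not 0.0 <= p <= 1.0:
        raise ConfigError("sprouting.p_perfused must lie in [0, 1]")
    for key in ("p_prox_anastomosis", "p_dist_anastomosis"):
        for dpt, prob in cfg["perfusion"][key].items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"perfusion.{key}[{dpt}] must lie in [0, 1]")
    for group in cfg["groups"]:
        if group not in DEFAULT_GROUPS:
            raise ConfigError(f"groups: unknown group name {group!r}")


def dump_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")


def animal_seed(master_seed: int, animal_id: str) -> np.random.SeedSequence:
    """Per-animal seed stream, stable under cohort growth.

    Derived by hashing (master_seed, animal_id) so that adding animals to a
    cohort never perturbs the streams of existing animals.
    """
    return np.random.SeedSequence([int(master_seed) % (2**31),
                                   zlib.crc32(animal_id.encode()) % (2**31)])


def subseed(master_seed: int, *tags: str | int) -> np.random.SeedSequence:
    """Named sub-stream of the master seed for non-animal randomness."""
    entropy = [int(master_seed) % (2**31)]
    for tag in tags:
        if isinstance(tag, str):
            entropy.append(zlib.crc32(tag.encode()) % (2**31))
        else:
            entropy.append(int(tag) % (2**31))
    return np.random.SeedSequence(entropy)
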