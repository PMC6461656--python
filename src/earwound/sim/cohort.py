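"""Full synthetic study: cohort of animals, all sessions, written to disk.

The cohort table is tidy long format (animal_id, group, dpt, metric,
value, censored), one row per measurement, which is the single input
format of the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..config import (ConfigError, DEFAULT_GROUPS, animal_seed, default_config,
                      dump_config)
from .calcium_truth import CalciumEventTrain, simulate_calcium_events
from .perfusion_truth import PerfusionGroundTruth, is_censored, simulate_perfusion_truth
from .scene import VascularScene, make_scene
from .sprouting import SproutRecord, TreatmentSpec, assign_perfusion, simulate_sprouting
from .traces import render_region_trace, render_roi_traces

COHORT_COLUMNS = ["animal_id", "group", "dpt", "metric", "value", "censored"]


@dataclass
class AnimalTruth:
    """Everything the generator knows about one animal."""

    animal_id: str
    group: str
    scene: VascularScene
    sprouts: list[SproutRecord]
    perfusion: dict[float, PerfusionGroundTruth] = field(default_factory=dict)
    calcium: dict[tuple[float, str], CalciumEventTrain] = field(default_factory=dict)


def simulate_animal(animal_id: str, group: str, cfg: dict,
                    structural_dpt: list[float], perfusion_dpt: list[float],
                    with_calcium: bool = True) -> AnimalTruth:
    """Deterministic ground truth for one animal.

    The animal's random stream is derived by hashing (master_seed,
    animal_id), so cohort membership changes never perturb it.
    """
    ss = animal_seed(cfg["master_seed"], animal_id)
    streams = ss.spawn(5)
    rng_scene, rng_sprout, rng_perf, rng_ca, rng_misc = (
        np.random.default_rng(s) for s in streams)

    treatment = TreatmentSpec.for_group(group, cfg["treatment"])
    scene = make_scene(seed=rng_scene.integers(2**31), params=cfg["scene"],
                       n_arteries=cfg["scene"]["n_arteries"],
                       scene_id=animal_id)

    horizon = sorted(set(list(structural_dpt) + list(perfusion_dpt)))
    sp = cfg["sprouting"]
    sprouts = simulate_sprouting(
        scene, horizon,
        birth_rate=sp["birth_rate_per_day"],
        elongation=sp["elongation_um_per_day"],
        treatment=treatment, seed=rng_sprout,
        onset_dpt=sp["onset_dpt"], elongation_cv=sp["elongation_cv"])
    sprouts = assign_perfusion(sprouts, sp["p_perfused"], seed=rng_sprout)

    truth = AnimalTruth(animal_id=animal_id, group=group, scene=scene, sprouts=sprouts)
    for dpt in perfusion_dpt:
        truth.perfusion[float(dpt)] = simulate_perfusion_truth(
            scene, sprouts, dpt, params=cfg["perfusion"], seed=rng_perf,
            treatment=treatment)
    if with_calcium:
        for dpt in structural_dpt:
            for region in ("proximal", "distal"):
                truth.calcium[(float(dpt), region)] = simulate_calcium_events(
                    dpt, region, params=cfg["calcium"], seed=rng_ca)
    return truth


def truth_rows(truth: AnimalTruth, structural_dpt: list[float]) -> list[dict]:
    """Tidy ground-truth rows for one animal."""
    rows = []

    def add(dpt, metric, value, censored=0):
        rows.append(dict(animal_id=truth.animal_id, group=truth.group,
                         dpt=float(dpt), metric=metric, value=value,
                         censored=int(censored)))

    count_dpt = sorted(set(list(structural_dpt) + sorted(truth.perfusion)))
    for dpt in count_dpt:
        live = [s for s in truth.sprouts if s.birth_dpt <= dpt]
        lengths = [s.length_at(dpt) for s in live]
        add(dpt, "sprout_count_distal", float(len(live)))
        add(dpt, "sprout_count_proximal", 0.0)
        add(dpt, "mean_length_um",
            float(np.mean(lengths)) if lengths else np.nan,
            censored=0 if lengths else 1)
        add(dpt, "n_sprouts_perfused",
            float(sum(1 for s in live if s.is_perfused)))

    for dpt, perf in sorted(truth.perfusion.items()):
        add(dpt, "ana_prox", float(perf.anastomosis_proximal))
        add(dpt, "ana_dist", float(perf.anastomosis_distal))
        add(dpt, "wound_connected", float(perf.wound_connected))
        for roi in "ABCD":
            t = perf.arrival(roi)
            add(dpt, f"t_{roi}_s", t, censored=int(is_censored(t)))

    for (dpt, region), train in sorted(truth.calcium.items()):
        add(dpt, f"ca_count_{region}", float(train.count))
    return rows


def simulate_cohort(
    groups: dict[str, int] | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    cfg: dict | None = None,
    write_traces: bool = True,
    with_calcium: bool = True,
) -> tuple[pd.DataFrame, dict[str, AnimalTruth]]:
    """Simulate a complete study and (optionally) write it to disk.

    Returns the tidy ground-truth cohort table and the per-animal truth.
    Re-running with the same seed reproduces the files byte-identically.
    """
    cfg = cfg or default_config()
    if seed is not None:
        cfg = {**cfg, "master_seed": int(seed)}
    groups = groups if groups is not None else cfg["groups"]
    for g in groups:
        if g not in DEFAULT_GROUPS:
            raise ConfigError(f"unknown group name {g!r}")
    structural = [float(x) for x in cfg["sessions"]["structural_dpt"]]
    perfusion = [float(x) for x in cfg["sessions"]["perfusion_dpt"]]

    truths: dict[str, AnimalTruth] = {}
    rows: list[dict] = []
    for group, n in groups.items():
        for i in range(int(n)):
            aid = f"{group}{i:02d}"
            truth = simulate_animal(aid, group, cfg, structural, perfusion,
                                    with_calcium=with_calcium)
            truths[aid] = truth
            rows.extend(truth_rows(truth, structural))
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "traces" / "perfusion").mkdir(parents=True, exist_ok=True)
        (out / "traces" / "calcium").mkdir(parents=True, exist_ok=True)
        (out / "scenes").mkdir(parents=True, exist_ok=True)
        dump_config(cfg, out / "config.json")
        table.to_csv(out / "ground_truth.csv", index=False, float_format="%.8g")
        for aid, truth in truths.items():
            truth.scene.to_json(out / "scenes" / f"{aid}.json")
            if not write_traces:
                continue
            ss = animal_seed(cfg["master_seed"], aid + "/traces")
            rng = np.random.default_rng(ss)
            for dpt, perf in sorted(truth.perfusion.items()):
                df = render_roi_traces(perf, params=cfg["imaging"], seed=rng)
                df.to_csv(out / "traces" / "perfusion" / f"{aid}_{dpt:g}.csv",
                          index=False, float_format="%.8g")
            for (dpt, region), train in sorted(truth.calcium.items()):
                df = render_region_trace(train, params=cfg["calcium"], seed=rng)
                df.to_csv(out / "traces" / "calcium" / f"{aid}_{dpt:g}_{region}.csv",
                          index=False, float_format="%.8g")
    return table, truths
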