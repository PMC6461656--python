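"""End-to-end quantification of a (synthetic or conforming) study layout.

A study directory, as written by :func:`earwound.sim.simulate_cohort`,
contains ``ground_truth.csv``, per-session tracer ROI traces under
``traces/perfusion`` and GCaMP region traces under ``traces/calcium``.
Quantification re-measures everything measurable from the traces
(arrival times, dt metrics, anastomosis calls, transient counts) and
carries the morphometric sprout metrics through, producing a tidy
measured cohort table with the same schema as the ground truth.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import compute_dff, detect_transients
from .config import DEFAULTS
from .perfusion import ArrivalResult, compute_metrics, detect_arrival, is_censored
from .sim.cohort import COHORT_COLUMNS


class StudyLayoutError(FileNotFoundError):
    pass


def quantify_trace_frame(df: pd.DataFrame, imaging: dict | None = None,
                         detection: dict | None = None) -> ArrivalResult:
    """Arrival detection + metric computation for one ROI trace table."""
    im = dict(DEFAULTS["imaging"])
    if imaging:
        im.update(imaging)
    det = dict(DEFAULTS["detection"])
    if detection:
        det.update(detection)
    arrivals = {}
    for roi in "ABCD":
        arrivals[roi] = detect_arrival(
            df[f"roi_{roi}"].to_numpy(),
            frame_period_s=im["frame_period_s"],
            n_baseline=im["n_baseline_frames"],
            k_sd=det["k_sd"],
            min_consecutive=det["min_consecutive"])
    return compute_metrics(arrivals,
                           recording_window_s=det["perfusion_window_s"],
                           anastomosis_threshold_s=det["anastomosis_threshold_s"])


def arrival_rows(aid: str, group: str, dpt: float, res: ArrivalResult) -> list[dict]:
    rows = []

    def add(metric, value, censored=None):
        if censored is None:
            censored = int(is_censored(value)) if isinstance(value, float) else 0
        rows.append(dict(animal_id=aid, group=group, dpt=float(dpt),
                         metric=metric, value=value, censored=censored))

    for roi in "ABCD":
        add(f"t_{roi}_s", res.t[roi])
    add("dt_ba_s", res.dt_ba)
    add("dt_cb_s", res.dt_cb)
    add("dt_dc_s", res.dt_dc)
    add("integral_s", res.integral_dt)
    for name, key in (("perf_prox", "proximal"), ("perf_wound", "wound"),
                      ("perf_dist", "distal")):
        add(name, float(res.perfused[key]), censored=0)
    add("ana_prox", float(res.anastomosis["proximal"]), censored=0)
    add("ana_dist", float(res.anastomosis["distal"]), censored=0)
    return rows


def quantify_study(study_dir: str | Path, cfg: dict | None = None) -> pd.DataFrame:
    """Measure a full study directory; returns a tidy cohort table."""
    study = Path(study_dir)
    gt_path = study / "ground_truth.csv"
    missing = [str(p) for p in (gt_path, study / "traces")if not p.exists()]
    if missing:
        raise StudyLayoutError("incomplete study layout; missing: " + ", ".join(missing))
    cfg = cfg or DEFAULTS
    truth = pd.read_csv(gt_path)
    meta = truth[["animal_id", "group"]].drop_duplicates().set_index("animal_id")["group"]

    rows: list[dict] = []
    pattern = re.compile(r"(?P<aid>.+)_(?P<dpt>[\d.]+)\.csv")
    for path in sorted((study / "traces" / "perfusion").glob("*.csv")):
        m = pattern.match(path.name)
        if not m:
            continue
        aid, dpt = m["aid"], float(m["dpt"])
        df = pd.read_csv(path)
        res = quantify_trace_frame(df, cfg.get("imaging"), cfg.get("detection"))
        rows.extend(arrival_rows(aid, meta.get(aid, "control"), dpt, res))

    ca_pattern = re.compile(r"(?P<aid>.+)_(?P<dpt>[\d.]+)_(?P<region>proximal|distal)\.csv")
    det = cfg.get("detection", DEFAULTS["detection"])
    cal = cfg.get("calcium", DEFAULTS["calcium"])
    for path in sorted((study / "traces" / "calcium").glob("*.csv")):
        m = ca_pattern.match(path.name)
        if not m:
            continue
        aid, dpt, region = m["aid"], float(m["dpt"]), m["region"]
        trace = pd.read_csv(path)["f"].to_numpy()
        dff = compute_dff(trace, frame_period_s=cal["frame_period_s"],
                          baseline_percentile=det["ca_baseline_percentile"],
                          window_s=det["ca_baseline_window_s"])
        events = detect_transients(dff, frame_period_s=cal["frame_period_s"],
                                   k_sd=det["ca_k_sd"],
                                   min_duration_s=det["ca_min_duration_s"],
                                   merge_gap_s=det["ca_merge_gap_s"],
                                   region=region)
        rows.append(dict(animal_id=aid, group=meta.get(aid, "control"),
                         dpt=dpt, metric=f"ca_count_{region}",
                         value=float(len(events)), censored=0))

    # sprout morphometrics are carried through from the structural truth
    keep = truth[truth["metric"].str.startswith(("sprout_count", "mean_length",
                                                 "n_sprouts"))]
    rows.extend(keep.to_dict(orient="records"))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def metric_wide(table: pd.DataFrame, metrics: list[str],
                drop_censored: bool = True) -> pd.DataFrame:
    """Pivot a tidy cohort table to one row per (animal, dpt)."""
    df = table[table["metric"].isin(metrics)].copy()
    if drop_censored:
        df = df[df["censored"] == 0]
    wide = df.pivot_table(index=["animal_id", "group", "dpt"], columns="metric",
                          values="value", aggfunc="first").reset_index()
    wide.columns.name = None
    return wide
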