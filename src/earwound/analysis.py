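"""High-level statistical analysis of a tidy cohort table.

Glue between the measured cohort table and the model layer: selects the
right rows per readout, fits every model the available metrics support,
and returns a name -> fit mapping that serializes to the fits JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import stats as st
from .pipeline import metric_wide

STRUCTURAL_MAX_DPT = 6.5


def control_counts(table: pd.DataFrame) -> pd.DataFrame:
    df = table[(table["metric"] == "sprout_count_distal")
               & (table["group"] == "control")
               & (table["dpt"] <= STRUCTURAL_MAX_DPT)]
    return df.rename(columns={"value": "count"})[["animal_id", "dpt", "count"]]


def control_lengths(table: pd.DataFrame) -> pd.DataFrame:
    df = table[(table["metric"] == "mean_length_um")
               & (table["group"] == "control")
               & (table["censored"] == 0)
               & (table["dpt"] <= STRUCTURAL_MAX_DPT)].dropna(subset=["value"])
    return df[["animal_id", "dpt", "value"]]


def perfused_totals(table: pd.DataFrame, dpt: float = 8.0,
                    groups: list[str] | None = None) -> pd.DataFrame:
    df = table[table["metric"].isin(["sprout_count_distal", "n_sprouts_perfused"])]
    if groups is not None:
        df = df[df["group"].isin(groups)]
    df = df[df["dpt"] == dpt]
    wide = df.pivot_table(index=["animal_id", "group"], columns="metric",
                          values="value").reset_index()
    wide = wide.rename(columns={"sprout_count_distal": "total",
                                "n_sprouts_perfused": "perfused"})
    return wide.dropna(subset=["total", "perfused"])


def calcium_pairs(table: pd.DataFrame, group: str = "control") -> pd.DataFrame:
    df = table[table["metric"].isin(["ca_count_proximal", "ca_count_distal"])
               & (table["group"] == group)]
    wide = df.pivot_table(index=["animal_id", "dpt"], columns="metric",
                          values="value").reset_index()
    return wide.dropna(subset=["ca_count_proximal", "ca_count_distal"])


def run_stats(table: pd.DataFrame) -> dict:
    """Fit every supported model on the cohort table."""
    fits: dict[str, object] = {}
    counts = control_counts(table)
    if len(counts):
        fits["sprout_count_glmm"] = st.fit_poisson_glmm(counts)
    lengths = control_lengths(table)
    if lengths["animal_id"].nunique() >= 3:
        fits["sprout_length_lmm"] = st.fit_lmm(lengths)

    ratio = perfused_totals(table, dpt=8.0, groups=["control"])
    if len(ratio) and (ratio["total"] > 0).any():
        fits["perfused_ratio"] = st.fit_perfused_ratio(ratio)
    pooled = perfused_totals(table, dpt=8.0)
    if pooled["group"].nunique() > 1 and (pooled["total"] > 0).any():
        fits["perfused_ratio_pooled"] = st.fit_perfused_ratio(pooled)

    n_groups = table["group"].nunique()
    for metric in ("dt_ba_s", "dt_cb_s", "dt_dc_s", "integral_s",
                   "sprout_count_distal", "mean_length_um"):
        df = table[(table["metric"] == metric) & (table["censored"] == 0)]
        df = df.dropna(subset=["value"])
        if df.empty:
            continue
        if metric in ("sprout_count_distal", "mean_length_um"):
            df = df[df["dpt"] <= STRUCTURAL_MAX_DPT]
        if n_groups > 1 and df["group"].nunique() > 1:
            fits[f"mlmr_{metric}"] = st.fit_mlmr_interaction(df)
        else:
            try:
                fits[f"lmm_{metric}"] = st.fit_lmm(df)
            except st.DegenerateFitError:
                pass

    pairs = calcium_pairs(table)
    if len(pairs):
        res = st.wilcoxon_signed_rank(pairs["ca_count_distal"],
                                      pairs["ca_count_proximal"],
                                      alternative="greater")
        fits["calcium_wilcoxon"] = res
    return fits


def fits_to_json(fits: dict, path: str | Path | None = None) -> dict:
    out = {}
    for name, fit in fits.items():
        if isinstance(fit, st.ModelFit):
            out[name] = fit.to_jsonable()
        elif isinstance(fit, st.TestResult):
            out[name] = {"test": fit.test, "statistic": fit.statistic,
                         "p": fit.pvalue, "flag": fit.flag}
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")
    return out
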