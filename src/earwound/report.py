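"""Figure panels and summary tables for a quantified cohort.

Each panel is written as both vector graphics (SVG) and a CSV of the
exact plotted values, so every number in a figure is reproducible from
its sidecar table.  Error bars are 90% confidence intervals for the
longitudinal structural panels and 95% for the treatment transit-time
panels; the group colour code (control blue, AZD4547 red, sunitinib
gold, combination orange) is fixed across all panels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import GROUP_COLORS

log = logging.getLogger(__name__)


def _ci_halfwidth(x: np.ndarray, level: float) -> float:
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return 0.0
    return float(sps.t.ppf(0.5 + level / 2, len(x) - 1) * sps.sem(x))


def _panel_timecourse(table: pd.DataFrame, metric: str, ylabel: str,
                      out: Path, name: str, ci: float = 0.90) -> None:
    df = table[(table["metric"] == metric) & (table["censored"] == 0)].dropna(subset=["value"])
    if df.empty:
        log.info("panel %s skipped: no data for %s", name, metric)
        return
    rows = []
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    for group, gdf in df.groupby("group"):
        agg = gdf.groupby("dpt")["value"]
        mean = agg.mean()
        hw = agg.apply(lambda v: _ci_halfwidth(v.to_numpy(), ci))
        ax.errorbar(mean.index, mean.values, yerr=hw.values, marker="o",
                    capsize=2, label=group,
                    color=GROUP_COLORS.get(group, "gray"))
        for dpt, m_, h_ in zip(mean.index, mean.values, hw.values):
            rows.append(dict(group=group, dpt=dpt, mean=m_, ci_halfwidth=h_,
                             ci_level=ci))
    ax.set_xlabel("days post-transection")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"{name}.svg")
    plt.close(fig)
    pd.DataFrame(rows).to_csv(out / f"{name}.csv", index=False)


def _panel_perfused_ratio(table: pd.DataFrame, out: Path, slope: float | None) -> None:
    wide = table[table["metric"].isin(["sprout_count_distal", "n_sprouts_perfused"])]
    wide = wide.pivot_table(index=["animal_id", "group", "dpt"], columns="metric",
                            values="value").reset_index()
    if wide.empty or "n_sprouts_perfused" not in wide:
        log.info("panel perfused_ratio skipped")
        return
    fig, ax = plt.subplots(figsize=(3.6, 3.2))
    for group, gdf in wide.groupby("group"):
        ax.scatter(gdf["sprout_count_distal"], gdf["n_sprouts_perfused"],
                   s=14, label=group, color=GROUP_COLORS.get(group, "gray"),
                   alpha=0.7)
    if slope is not None:
        xs = np.linspace(0, wide["sprout_count_distal"].max() + 1, 10)
        ax.plot(xs, slope * xs, "k--", lw=1, label=f"slope {slope:.3f}")
    ax.set_xlabel("total sprouts")
    ax.set_ylabel("perfused sprouts")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "perfused_ratio.svg")
    plt.close(fig)
    wide.to_csv(out / "perfused_ratio.csv", index=False)


def _panel_fraction(table: pd.DataFrame, metric: str, ylabel: str, out: Path,
                    name: str) -> None:
    df = table[table["metric"] == metric]
    if df.empty:
        log.info("panel %s skipped", name)
        return
    agg = df.groupby(["group", "dpt"])["value"].mean().reset_index()
    fig, ax = plt.subplots(figsize=(4.0, 3.0))
    dpts = sorted(agg["dpt"].unique())
    groups = sorted(agg["group"].unique())
    width = 0.8 / max(len(groups), 1)
    for gi, group in enumerate(groups):
        sub = agg[agg["group"] == group].set_index("dpt")["value"]
        xs = [d + (gi - (len(groups) - 1) / 2) * width for d in dpts]
        ax.bar(xs, [100 * sub.get(d, np.nan) for d in dpts], width=width,
               label=group, color=GROUP_COLORS.get(group, "gray"))
    ax.set_xticks(dpts)
    ax.set_xlabel("days post-transection")
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 105)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"{name}.svg")
    plt.close(fig)
    agg.to_csv(out / f"{name}.csv", index=False)


def build_report(table: pd.DataFrame, out_dir: str | Path,
                 fits: dict | None = None) -> list[str]:
    """Write all panels supported by the available metrics.

    Returns the list of panel names written; missing metrics skip their
    panel with a log entry rather than failing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fits = fits or {}

    _panel_timecourse(table, "sprout_count_distal", "sprouts (distal)",
                      out, "sprout_count", ci=0.90)
    _panel_timecourse(table, "mean_length_um", "mean sprout length (um)",
                      out, "sprout_length", ci=0.90)
    for metric, name in (("dt_ba_s", "dt_ba"), ("dt_cb_s", "dt_cb"),
                         ("dt_dc_s", "dt_dc"), ("integral_s", "integral")):
        _panel_timecourse(table, metric, f"{name} (s)", out, name, ci=0.95)
    for region in ("proximal", "distal"):
        _panel_timecourse(table, f"ca_count_{region}",
                          f"Ca2+ transients / 22 min ({region})",
                          out, f"ca_count_{region}", ci=0.90)
    _panel_fraction(table, "ana_prox", "% proximal anastomoses", out, "ana_prox")
    _panel_fraction(table, "ana_dist", "% distal anastomoses", out, "ana_dist")
    for side in ("prox", "wound", "dist"):
        _panel_fraction(table, f"perf_{side}", f"% perfused ({side})",
                        out, f"perf_{side}")
    ratio_fit = fits.get("perfused_ratio")
    slope = None
    if ratio_fit is not None:
        slope = next(iter(ratio_fit.slopes.values()))[0]
    _panel_perfused_ratio(table, out, slope)
    return sorted(p.stem for p in out.glob("*.svg"))
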