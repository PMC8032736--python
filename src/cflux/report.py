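"""Diagnostic products: fire-regime summaries, severity-class
chronosequences, and emission-partition ratios.

All operations here are pure functions of simulation outputs — producing a
report never re-runs a simulation.  Severity classes are seven bins of
width 100 dNBR: <100, 100-200, ..., >=600.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .region import Cohort
from .severity import SeverityRecord

SEVERITY_EDGES = np.array([0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, np.inf])
SEVERITY_LABELS = ["<100", "100-200", "200-300", "300-400",
                   "400-500", "500-600", ">=600"]

#: Chronosequence variables reported as no-fire minus fire.
DIFF_NOFIRE_MINUS_FIRE = ["cveg", "csoil", "npp", "rh", "nep", "net_nmin"]
#: Physical diagnostics reported as fire minus no-fire.
DIFF_FIRE_MINUS_NOFIRE = ["tsoil", "moisture"]


def severity_class(dnbr: float) -> str:
    """Label of the 100-wide severity bin containing ``dnbr``."""
    idx = int(np.digitize([max(dnbr, 0.0)], SEVERITY_EDGES[1:-1])[0])
    return SEVERITY_LABELS[idx]


@dataclass(frozen=True)
class FireRegimeSummary:
    """Annual fire-regime aggregates and the severity trend."""

    table: pd.DataFrame          # year, n_fires, area_km2, aw_mean_dnbr
    dnbr_trend_slope: float      # dNBR units per year (OLS)
    dnbr_trend_stderr: float
    dnbr_trend_pvalue: float
    area_weighted_mean_dnbr: float  # whole-period


def fire_regime_summary(records: list[SeverityRecord]) -> FireRegimeSummary:
    """Per-year fire counts, burned area and area-weighted mean dNBR,
    with an ordinary-least-squares trend of the annual means."""
    if not records:
        raise ValueError("no fires to summarize")
    df = pd.DataFrame(
        {
            "year": [r.year for r in records],
            "area_km2": [r.area_km2 for r in records],
            "dnbr": [r.dnbr for r in records],
        }
    )
    def aw_mean(g: pd.DataFrame) -> float:
        return float(np.average(g["dnbr"], weights=g["area_km2"]))

    grouped = df.groupby("year")
    table = pd.DataFrame(
        {
            "year": sorted(df["year"].unique()),
            "n_fires": grouped.size().values,
            "area_km2": grouped["area_km2"].sum().values,
            "aw_mean_dnbr": [aw_mean(g) for _, g in grouped],
        }
    )
    if len(table) > 1:
        fit = stats.linregress(table["year"], table["aw_mean_dnbr"])
        slope, stderr, pvalue = float(fit.slope), float(fit.stderr), float(fit.pvalue)
    else:
        slope, stderr, pvalue = 0.0, float("nan"), float("nan")
    overall = float(np.average(df["dnbr"], weights=df["area_km2"]))
    return FireRegimeSummary(table, slope, stderr, pvalue, overall)


def _once_burned(cohorts: list[Cohort]) -> list[int]:
    return [i for i, c in enumerate(cohorts) if len(c.fires) == 1]


def _paired(fire_runs, nofire_runs, cohorts):
    if len(fire_runs) != len(cohorts) or len(nofire_runs) != len(cohorts):
        raise ValueError("each cohort needs a fire run and its no-fire twin")


def chronosequence(
    fire_runs: list[pd.DataFrame],
    nofire_runs: list[pd.DataFrame],
    cohorts: list[Cohort],
    max_years: int = 25,
    area_weighted: bool = False,
) -> pd.DataFrame:
    """Severity-class mean post-fire differences by years since fire.

    Only once-burned cohorts enter.  Each cohort is re-indexed by years
    since its fire (0..``max_years``); within each severity class the
    cohort differences are averaged — unweighted across cohorts by
    default, or weighted by cohort area with ``area_weighted=True``.
    Returns a tidy frame keyed by (severity_class, years_since_fire,
    variable) with columns ``value`` and ``n_cohorts``.
    """
    _paired(fire_runs, nofire_runs, cohorts)
    rows = []
    for i in _once_burned(cohorts):
        cohort = cohorts[i]
        fire_year, sev = cohort.fires[0]
        label = severity_class(sev.dnbr)
        f, n = fire_runs[i], nofire_runs[i]
        years = f["year"].to_numpy()
        sel = (years >= fire_year) & (years <= fire_year + max_years)
        ysf = years[sel] - fire_year
        for var in DIFF_NOFIRE_MINUS_FIRE:
            d = n[var].to_numpy()[sel] - f[var].to_numpy()[sel]
            rows.extend(
                dict(severity_class=label, years_since_fire=int(t), variable=var,
                     value=v, weight=cohort.area_frac)
                for t, v in zip(ysf, d)
            )
        for var in DIFF_FIRE_MINUS_NOFIRE:
            d = f[var].to_numpy()[sel] - n[var].to_numpy()[sel]
            rows.extend(
                dict(severity_class=label, years_since_fire=int(t), variable=var,
                     value=v, weight=cohort.area_frac)
                for t, v in zip(ysf, d)
            )
    if not rows:
        raise ValueError("no once-burned cohorts inside the period")
    tidy = pd.DataFrame(rows)

    def agg(g: pd.DataFrame) -> pd.Series:
        w = g["weight"] if area_weighted else np.ones(len(g))
        return pd.Series(
            {"value": float(np.average(g["value"], weights=w)),
             "n_cohorts": len(g)}
        )

    out = (
        tidy.groupby(["severity_class", "years_since_fire", "variable"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_cohorts"] = out["n_cohorts"].astype(int)
    return out


def emission_partition(
    fire_runs: list[pd.DataFrame],
    cohorts: list[Cohort],
    max_years: int = 25,
) -> pd.DataFrame:
    """Per-severity-class emission partitions for once-burned cohorts.

    Three series per class and years-since-fire:

    * ``soil_share_direct`` — soil share of the direct combustion
      emission (constant across years; the fire-year split);
    * ``direct_soil_over_soil_total`` — direct soil emission over direct
      soil emission plus cumulative R_H since the fire;
    * ``direct_over_total`` — direct emission over direct emission plus
      cumulative R_H since the fire.

    Classes with zero emission are reported as NaN (undefined), not 0.
    """
    if len(fire_runs) != len(cohorts):
        raise ValueError("one run per cohort is required")
    rows = []
    for i in _once_burned(cohorts):
        cohort = cohorts[i]
        fire_year, sev = cohort.fires[0]
        label = severity_class(sev.dnbr)
        f = fire_runs[i]
        years = f["year"].to_numpy()
        sel = (years >= fire_year) & (years <= fire_year + max_years)
        ysf = years[sel] - fire_year
        direct_soil = float(f["emis_soil"].to_numpy()[sel][0])
        direct_total = float(f["emis_total"].to_numpy()[sel][0])
        cum_rh = np.cumsum(f["rh"].to_numpy()[sel])
        soil_share = direct_soil / direct_total if direct_total > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            r_soil = np.where(direct_soil + cum_rh > 0,
                              direct_soil / (direct_soil + cum_rh), np.nan)
            r_total = np.where(direct_total + cum_rh > 0,
                               direct_total / (direct_total + cum_rh), np.nan)
        for t, rs, rt in zip(ysf, r_soil, r_total):
            rows.append(
                dict(severity_class=label, years_since_fire=int(t),
                     soil_share_direct=soil_share,
                     direct_soil_over_soil_total=float(rs),
                     direct_over_total=float(rt))
            )
    tidy = pd.DataFrame(rows)
    return (
        tidy.groupby(["severity_class", "years_since_fire"])
        .mean()
        .reset_index()
    )


def indirect_ratio(
    fire_runs: list[pd.DataFrame],
    nofire_runs: list[pd.DataFrame],
    cohorts: list[Cohort],
    max_years: int = 25,
) -> pd.DataFrame:
    """Cumulative (total-emission difference) / (direct emission) ratio.

    ratio(t) = (direct + cumulative R_H with fire - cumulative R_H
    without fire) / direct, per severity class and years since fire.  A
    ratio above 1 means the fire also raised indirect (respiration)
    emissions; equal R_H in both runs gives exactly 1.  Cohorts with zero
    direct emission are undefined (NaN).
    """
    _paired(fire_runs, nofire_runs, cohorts)
    rows = []
    for i in _once_burned(cohorts):
        cohort = cohorts[i]
        fire_year, sev = cohort.fires[0]
        label = severity_class(sev.dnbr)
        f, n = fire_runs[i], nofire_runs[i]
        years = f["year"].to_numpy()
        sel = (years >= fire_year) & (years <= fire_year + max_years)
        ysf = years[sel] - fire_year
        direct = float(f["emis_total"].to_numpy()[sel][0])
        cum_gap = np.cumsum(f["rh"].to_numpy()[sel]) - np.cumsum(n["rh"].to_numpy()[sel])
        ratio = (direct + cum_gap) / direct if direct > 0 else np.full(len(ysf), np.nan)
        for t, r in zip(ysf, np.atleast_1d(ratio)):
            rows.append(dict(severity_class=label, years_since_fire=int(t),
                             ratio=float(r)))
    tidy = pd.DataFrame(rows)
    return (
        tidy.groupby(["severity_class", "years_since_fire"])
        .mean()
        .reset_index()
    )


def plot_fire_regime(summary: FireRegimeSummary, path=None):
    """Annual fire counts / burned area and the dNBR trend (two panels)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    t = summary.table
    ax1.bar(t["year"], t["area_km2"], color="0.7", label="burned area (km2)")
    ax1b = ax1.twinx()
    ax1b.plot(t["year"], t["n_fires"], "k.-", label="fire count")
    ax1.set_ylabel("burned area (km$^2$)")
    ax1b.set_ylabel("fire count")
    ax2.plot(t["year"], t["aw_mean_dnbr"], "o", color="0.4")
    xs = np.array([t["year"].min(), t["year"].max()], dtype=float)
    intercept = t["aw_mean_dnbr"].mean() - summary.dnbr_trend_slope * t["year"].mean()
    ax2.plot(xs, intercept + summary.dnbr_trend_slope * xs, "k-",
             label=f"trend {summary.dnbr_trend_slope:+.1f}/yr")
    ax2.set_xlabel("year")
    ax2.set_ylabel("area-weighted mean dNBR")
    ax2.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_chronosequence(table: pd.DataFrame, path=None):
    """Panel grid of class-mean post-fire differences by years since fire."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    variables = list(table["variable"].unique())
    ncol = 2
    nrow = (len(variables) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.6 * nrow), squeeze=False)
    for ax, var in zip(axes.ravel(), variables):
        sub = table[table["variable"] == var]
        for label in SEVERITY_LABELS:
            cls = sub[sub["severity_class"] == label]
            if len(cls):
                ax.plot(cls["years_since_fire"], cls["value"], label=label)
        ax.set_title(var)
        ax.set_xlabel("years since fire")
    axes.ravel()[0].legend(fontsize=7)
    for ax in axes.ravel()[len(variables):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
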