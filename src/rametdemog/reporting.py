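"""Summary tables: stage densities per plot-year and site comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from rametdemog.census import STAGES


class ReportingError(ValueError):
    pass


def summarize_densities(records: pd.DataFrame, site: str) -> pd.DataFrame:
    """Mean +/- SE ramets per plot-year, by stage, for one site.

    Rows: all_ramets, seedlings, sprout_recruits (tags first seen that
    year in a non-seedling stage, excluding the initial tagging year),
    then the six stages.  SE = SD/sqrt(n plot-years); a single
    plot-year leaves SE undefined (NaN).
    """
    sub = records[(records["site"] == site)
                  & records["stage"].isin(STAGES)].copy()
    if sub.empty:
        raise ReportingError(f"no records for site {site!r}")
    plots = sorted(sub["plot"].unique())
    years = sorted(sub["year"].unique())
    first_year = years[0]
    idx = pd.MultiIndex.from_product([years, plots], names=["year", "plot"])

    per_stage = {}
    for stage in STAGES:
        c = (sub[sub["stage"] == stage].groupby(["year", "plot"]).size()
             .reindex(idx, fill_value=0))
        per_stage[stage] = c
    all_ramets = sum(per_stage.values())

    first_seen = sub.sort_values("year").groupby(["plot", "tag_id"]).first()
    sprouts = first_seen[(first_seen["stage"] != "Sd")
                         & (first_seen["year"] > first_year)]
    sprout_counts = (sprouts.groupby(["year", "plot"]).size()
                     .reindex(idx, fill_value=0))

    rows = [("all_ramets", all_ramets), ("seedlings", per_stage["Sd"]),
            ("sprout_recruits", sprout_counts)]
    rows += [(s, per_stage[s]) for s in ("SR", "SF", "MR", "MF", "IA")]
    out = []
    for name, counts in rows:
        v = counts.to_numpy(dtype=float)
        se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        out.append((site, name, float(np.mean(v)), se, v.size))
    return pd.DataFrame(out, columns=["site", "density", "mean", "se",
                                      "n_plot_years"])


def compare_sites(a, b) -> tuple[float, float]:
    """Welch two-sample t-test between two per-plot-year (or per-year)
    metric series.  Returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ReportingError("need at least 2 observations per side")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ReportingError("zero variance on both sides with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
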