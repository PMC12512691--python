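"""Time-course figures: group mean ± SE ribbons with phase-boundary lines.

Every figure is paired with the exact tidy CSV behind it — no number exists
only in a plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .workflow import LeafResult

AXIS_LABELS = {
    "gsw": "g$_{SW}$ (mol m$^{-2}$ s$^{-1}$)",
    "A": "A (µmol m$^{-2}$ s$^{-1}$)",
    "iwue": "iWUE (µmol mol$^{-1}$)",
    "Ci": "C$_i$ (µmol mol$^{-1}$)",
    "Ca": "C$_a$ (µmol mol$^{-1}$)",
    "E": "E (mol m$^{-2}$ s$^{-1}$)",
}


def plotted_data(results: list[LeafResult], variable: str) -> pd.DataFrame:
    """Group mean ± SE per logged minute for one variable (tidy)."""
    if not results:
        raise ValueError("no results to plot")
    cols = results[0].ts.data.columns
    if variable not in cols:
        raise ValueError(
            f"unknown variable '{variable}'; available: {sorted(c for c in cols if c != 'iwue_defined')}"
        )
    frames = []
    for r in results:
        t0 = float(r.ts.data["t"].iloc[0])
        frames.append(
            pd.DataFrame(
                {
                    "group": r.entry.group,
                    "individual": r.entry.individual,
                    "minute": np.round((r.ts.data["t"].to_numpy(float) - t0) / 60.0, 6),
                    "value": r.ts.data[variable].to_numpy(float),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    rows = []
    for (group, minute), sub in long.groupby(["group", "minute"], sort=True):
        vals = sub["value"].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        rows.append(
            {
                "group": group,
                "minute": minute,
                "mean": float(np.mean(vals)) if n else float("nan"),
                "se": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def phase_boundaries_min(results: list[LeafResult]) -> list[float]:
    r = results[0]
    t0 = float(r.ts.data["t"].iloc[0])
    return [(p.t_start - t0) / 60.0 for p in r.phases[1:]]


def plot_variable(
    results: list[LeafResult],
    variable: str,
    out_png: str | Path,
    out_csv: str | Path | None = None,
    title: str | None = None,
) -> pd.DataFrame:
    """Write the figure and its data CSV; returns the plotted table."""
    table = plotted_data(results, variable)
    out_png = Path(out_png)
    out_csv = Path(out_csv) if out_csv else out_png.with_suffix(".csv")

    fig, ax = plt.subplots(figsize=(7, 4))
    for group, sub in table.groupby("group", sort=False):
        sub = sub.sort_values("minute")
        ax.plot(sub["minute"], sub["mean"], label=str(group))
        ax.fill_between(
            sub["minute"], sub["mean"] - sub["se"], sub["mean"] + sub["se"], alpha=0.25
        )
    for b in phase_boundaries_min(results):
        ax.axvline(b, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(AXIS_LABELS.get(variable, variable))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)

    table.to_csv(out_csv, index=False)
    return table
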