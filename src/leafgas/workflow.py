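"""Config-driven analysis pipeline shared by the CLI commands.

One :class:`LeafResult` per input file (read → area-correct → iWUE → segment
→ steady states → transition fits), then cross-individual aggregation into
the three standard tables: per-leaf-area steady states, per-stoma steady
states, and the kinetics summary (λ, k, 1/k, Sl_max per transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, kinetics, timecourse
from .config import FileEntry, RunConfig


@dataclass
class LeafResult:
    entry: FileEntry
    ts: io.GasExchangeTimeseries
    phases: list[timecourse.LightPhase]
    steady: timecourse.SteadyStateSummary
    fits: list[kinetics.KineticsFit] = field(default_factory=list)


def analyse_file(entry: FileEntry, cfg: RunConfig) -> LeafResult:
    geom = io.ChamberGeometry(
        chamber_area=cfg.chamber.area_cm2,
        chamber_diameter=cfg.chamber.diameter_cm,
        leaf_width=entry.leaf_width_cm,
    )
    ts = io.read_irga(entry.path)
    ts = io.apply_area_correction(ts, geom, allow_oversize=entry.allow_oversize)
    ts = timecourse.derive_iwue(ts, gsw_floor=cfg.analysis.gsw_floor)
    if cfg.schedule is not None:
        phases = timecourse.segment_phases(ts, schedule=cfg.schedule_tuples())
    else:
        phases = timecourse.segment_phases(ts, detect=True)
    steady = timecourse.steady_states(phases, cfg.analysis.steady_window_s)
    windows = kinetics.transition_windows(phases, cfg.analysis.steady_window_s)
    fits = [
        kinetics.fit_transition(w, response_floor=cfg.analysis.response_floor)
        for w in windows
    ]
    if cfg.analysis.normalization == "relative":
        ts = timecourse.relative_normalize(
            ts, phases, cfg.analysis.reference_phase, "gsw", cfg.analysis.steady_window_s
        )
    elif cfg.analysis.normalization == "per_stoma":
        ts = timecourse.per_stoma_series(ts, entry.stomatal_density_mm2)
    return LeafResult(entry, ts, phases, steady, fits)


def individual_steady_table(results: list[LeafResult]) -> pd.DataFrame:
    """Long table of per-individual steady-state means (per leaf area)."""
    frames = []
    for r in results:
        t = r.steady.table.copy()
        t.insert(0, "individual", r.entry.individual)
        t.insert(0, "group", r.entry.group)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def group_steady_table(ind_table: pd.DataFrame) -> pd.DataFrame:
    """Cross-individual group means ± SE per phase and variable."""
    rows = []
    for (group, phase, variable), sub in ind_table.groupby(
        ["group", "phase", "variable"], sort=False
    ):
        vals = sub["mean"].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        rows.append(
            {
                "group": group,
                "phase": phase,
                "variable": variable,
                "mean": float(np.mean(vals)) if n else float("nan"),
                "se": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def per_stoma_steady_table(results: list[LeafResult]) -> pd.DataFrame:
    """Per-stoma group table: each individual normalised by its own density
    before cross-individual averaging (÷density ×10³ convention)."""
    frames = []
    for r in results:
        if r.entry.stomatal_density_mm2 is None:
            raise ValueError(
                f"per-stoma table needs stomatal_density_mm2 for {r.entry.individual}"
            )
        t = timecourse.per_stoma_summary(r.steady, r.entry.stomatal_density_mm2).table.copy()
        t.insert(0, "individual", r.entry.individual)
        t.insert(0, "group", r.entry.group)
        frames.append(t)
    return group_steady_table(pd.concat(frames, ignore_index=True))


def fit_table(results: list[LeafResult]) -> pd.DataFrame:
    return kinetics.fits_to_frame(
        (r.entry.group, r.entry.individual, f) for r in results for f in r.fits
    )


def kinetics_summary(results: list[LeafResult], iqr_factor: float = 1.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    return kinetics.summarize_kinetics(fit_table(results), iqr_factor=iqr_factor)


def model_curve_table(results: list[LeafResult], step_min: float = 0.25) -> pd.DataFrame:
    """Predicted-vs-observed conductance for every successful fit."""
    rows = []
    for r in results:
        windows = kinetics.transition_windows(r.phases)
        for w, f in zip(windows, r.fits):
            if not f.success:
                continue
            tau_obs = (w.data["t"].to_numpy(float) - w.t0) / 60.0
            obs = w.data["gsw"].to_numpy(float)
            grid = np.arange(0.0, tau_obs[-1] + step_min, step_min)
            pred = kinetics.predicted_curve(f, grid)
            for tt, vv in zip(tau_obs, obs):
                rows.append(
                    {"group": r.entry.group, "individual": r.entry.individual,
                     "transition": f.transition, "kind": "observed", "tau_min": float(tt),
                     "gsw": float(vv)}
                )
            for tt, vv in zip(grid, pred):
                rows.append(
                    {"group": r.entry.group, "individual": r.entry.individual,
                     "transition": f.transition, "kind": "predicted", "tau_min": float(tt),
                     "gsw": float(vv)}
                )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> list[LeafResult]:
    return [analyse_file(entry, cfg) for entry in cfg.files]
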