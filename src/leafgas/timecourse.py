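"""Light-phase segmentation, iWUE, steady states and trace normalizations.

A run is partitioned into contiguous constant-light phases (half-open
intervals, the record at a light switch belonging to the *new* phase).  Within
each phase the steady state is the mean over a window anchored at the phase
end — by convention the last 5 min of a 20-min step, i.e. 5 points at 60-s
logging.

Intrinsic water-use efficiency iWUE = A / g_SW is computed pointwise (mean of
ratios, not ratio of means) and is undefined where g_SW falls below a floor,
as in darkness.

Per-stoma normalization divides every per-leaf-area flux by the stomatal
density (mm⁻²) and scales by 10³, the convention used in published per-stoma
tables; the strict SI per-stoma factor 1/(density × 10⁶) (per m²) is recorded
in the metadata alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PhaseError, SteadyStateError
from .io import GasExchangeTimeseries

#: default steady-state window: 5 min at the end of each light step
DEFAULT_WINDOW_S = 300.0
#: conductance floor below which iWUE is flagged undefined (mol m⁻² s⁻¹)
GSW_FLOOR = 1e-3
#: columns rescaled by per-stoma normalization
PER_STOMA_COLUMNS = ("gsw", "A", "E", "iwue")


@dataclass
class LightPhase:
    """A contiguous constant-light interval of a run.

    The interval is half-open [t_start, t_end); ``data`` holds the member
    records.
    """

    label: str
    par_level: float
    t_start: float
    t_end: float
    data: pd.DataFrame

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SteadyStateSummary:
    """Per-phase, per-variable steady-state means with dispersion.

    ``table`` columns: phase, par_level, variable, mean, se, n, window_s.
    """

    table: pd.DataFrame
    window_s: float = DEFAULT_WINDOW_S

    def value(self, phase: str, variable: str) -> float:
        sub = self.table[(self.table["phase"] == phase) & (self.table["variable"] == variable)]
        if len(sub) != 1:
            raise KeyError(f"no unique steady state for ({phase}, {variable})")
        return float(sub["mean"].iloc[0])


def _label_phases(par_levels: list[float], zero_tol: float = 1.0) -> list[str]:
    """Name phases by their PAR level: darkness (≈0), high_light (= run max),
    low_light otherwise; repeated categories get ordinal suffixes."""
    pmax = max(par_levels)
    cats = []
    for p in par_levels:
        if p < zero_tol:
            cats.append("darkness")
        elif pmax > zero_tol and abs(p - pmax) / pmax < 0.05:
            cats.append("high_light")
        else:
            cats.append("low_light")
    counts = {c: cats.count(c) for c in set(cats)}
    seen: dict[str, int] = {}
    labels = []
    for c in cats:
        if counts[c] > 1:
            seen[c] = seen.get(c, 0) + 1
            labels.append(f"{c}_{seen[c]}")
        else:
            labels.append(c)
    return labels


def segment_phases(
    ts: GasExchangeTimeseries,
    schedule: list[tuple[float, float]] | None = None,
    detect: bool = False,
    rel_threshold: float = 0.20,
    expected_phases: int | None = None,
) -> list[LightPhase]:
    """Partition a run into constant-light phases.

    Parameters
    ----------
    schedule
        Ordered ``(par_level, duration_s)`` steps; boundaries are placed at
        cumulative durations from the first record's time.
    detect
        Place a boundary wherever the relative jump in q_in between
        consecutive records exceeds ``rel_threshold`` (default 20%); the
        boundary record starts the new phase.
    expected_phases
        With detection, raise :class:`~leafgas.errors.PhaseError` listing the
        detected boundaries if the count differs.
    """
    if (schedule is None) == (not detect):
        raise ValueError("provide exactly one of schedule= or detect=True")
    df = ts.data
    t = df["t"].to_numpy(float)
    q = df["q_in"].to_numpy(float)
    t0 = t[0]

    if schedule is not None:
        edges = [t0]
        for _, dur in schedule:
            if dur <= 0:
                raise PhaseError("schedule durations must be positive")
            edges.append(edges[-1] + dur)
        if t[-1] >= edges[-1]:
            raise PhaseError(
                f"run extends to t={t[-1]:g}s beyond the schedule end {edges[-1]:g}s"
            )
        par_levels = [float(p) for p, _ in schedule]
        bounds = edges
    else:
        q_floor = 1.0  # µmol m⁻² s⁻¹; avoids division blow-up around darkness
        cut_idx = [
            i
            for i in range(1, len(q))
            if abs(q[i] - q[i - 1]) > rel_threshold * max(abs(q[i - 1]), q_floor)
        ]
        bounds = [t0] + [t[i] for i in cut_idx] + [t[-1] + (t[-1] - t[-2] if len(t) > 1 else 1.0)]
        if expected_phases is not None and len(bounds) - 1 != expected_phases:
            raise PhaseError(
                f"detected {len(bounds) - 1} phases (expected {expected_phases}); "
                f"boundaries at t = {bounds[1:-1]}"
            )
        par_levels = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mask = (t >= lo) & (t < hi)
            par_levels.append(float(np.median(q[mask])))

    labels = _label_phases(par_levels)
    phases = []
    for label, par, lo, hi in zip(labels, par_levels, bounds[:-1], bounds[1:]):
        mask = (t >= lo) & (t < hi)
        phases.append(LightPhase(label, par, float(lo), float(hi), df.loc[mask].copy()))
    if sum(len(p.data) for p in phases) != len(df):
        raise PhaseError("phases do not partition the run")
    return phases


def derive_iwue(ts: GasExchangeTimeseries, gsw_floor: float = GSW_FLOOR) -> GasExchangeTimeseries:
    """Add the pointwise iWUE column A/g_SW (µmol CO₂ mol⁻¹ H₂O).

    Points with g_SW below ``gsw_floor`` are flagged undefined (NaN iWUE,
    ``iwue_defined`` False) rather than failing — darkness routinely drives
    g_SW to the floor.
    """
    out = ts.copy()
    gsw = out.data["gsw"].to_numpy(float)
    a = out.data["A"].to_numpy(float)
    defined = gsw >= gsw_floor
    iwue = np.full_like(gsw, np.nan)
    np.divide(a, gsw, out=iwue, where=defined)
    out.data["iwue"] = iwue
    out.data["iwue_defined"] = defined
    out.meta["iwue_gsw_floor"] = gsw_floor
    return out


def steady_state(
    phase: LightPhase,
    window_s: float = DEFAULT_WINDOW_S,
    variables: tuple[str, ...] | None = None,
) -> SteadyStateSummary:
    """Mean ± standard error over the last ``window_s`` seconds of a phase.

    The window is [t_end − window_s, t_end), closed on the left.  iWUE is
    averaged over its defined points only; if none are defined the mean is
    NaN with n = 0.
    """
    if window_s > phase.duration:
        raise SteadyStateError(
            f"window {window_s:g}s exceeds phase '{phase.label}' duration {phase.duration:g}s"
        )
    t = phase.data["t"].to_numpy(float)
    mask = (t >= phase.t_end - window_s) & (t < phase.t_end)
    sub = phase.data.loc[mask]
    if len(sub) < 2:
        raise SteadyStateError(
            f"fewer than 2 records in the {window_s:g}s window of phase '{phase.label}'"
        )
    if variables is None:
        variables = tuple(
            v for v in ("gsw", "A", "iwue", "E", "Ci", "Ca") if v in sub.columns
        )
    rows = []
    for var in variables:
        vals = sub[var].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else (0.0 if n == 1 else float("nan"))
        rows.append(
            {
                "phase": phase.label,
                "par_level": phase.par_level,
                "variable": var,
                "mean": mean,
                "se": se,
                "n": n,
                "window_s": window_s,
            }
        )
    return SteadyStateSummary(pd.DataFrame(rows), window_s)


def steady_states(
    phases: list[LightPhase],
    window_s: float = DEFAULT_WINDOW_S,
    variables: tuple[str, ...] | None = None,
) -> SteadyStateSummary:
    """Steady-state table across all phases of a run."""
    tables = [steady_state(p, window_s, variables).table for p in phases]
    return SteadyStateSummary(pd.concat(tables, ignore_index=True), window_s)


def per_stoma_series(
    ts: GasExchangeTimeseries,
    density_mm2: float,
    variables: tuple[str, ...] = PER_STOMA_COLUMNS,
) -> GasExchangeTimeseries:
    """Rescale per-leaf-area fluxes to per-stoma values.

    Each flux x becomes ``x / density_mm2 × 10³`` (the published-table
    convention); the strict SI per-stoma factor ``1 / (density_mm2 × 10⁶)``
    (stomata per m²) is recorded in ``meta["per_stoma_si_factor"]``.
    """
    if not density_mm2 > 0:
        raise ValueError("stomatal density must be strictly positive")
    out = ts.copy()
    for col in variables:
        if col in out.data.columns:
            out.data[col] = out.data[col] / density_mm2 * 1e3
    out.meta["per_stoma_density_mm2"] = density_mm2
    out.meta["per_stoma_factor"] = 1e3 / density_mm2
    out.meta["per_stoma_si_factor"] = 1.0 / (density_mm2 * 1e6)
    return out


def per_stoma_summary(
    summary: SteadyStateSummary,
    density_mm2: float,
    variables: tuple[str, ...] = PER_STOMA_COLUMNS,
) -> SteadyStateSummary:
    """Apply the per-stoma convention to a steady-state table (means and SE)."""
    if not density_mm2 > 0:
        raise ValueError("stomatal density must be strictly positive")
    table = summary.table.copy()
    mask = table["variable"].isin(variables)
    for col in ("mean", "se"):
        table.loc[mask, col] = table.loc[mask, col] / density_mm2 * 1e3
    return SteadyStateSummary(table, summary.window_s)


def per_stoma_value(x: float, density_mm2: float) -> float:
    """Single-value per-stoma normalization: x / density × 10³."""
    if not density_mm2 > 0:
        raise ValueError("stomatal density must be strictly positive")
    return x / density_mm2 * 1e3


def relative_normalize(
    ts: GasExchangeTimeseries,
    phases: list[LightPhase],
    reference_phase: str = "high_light_1",
    variable: str = "gsw",
    window_s: float = DEFAULT_WINDOW_S,
    floor: float = GSW_FLOOR,
) -> GasExchangeTimeseries:
    """Scale ``variable`` so the reference-phase steady-state mean is 1.

    Doubling all raw values leaves the relative trace unchanged
    (scale invariance).
    """
    ref = next((p for p in phases if p.label == reference_phase), None)
    if ref is None:
        raise PhaseError(f"reference phase '{reference_phase}' not found")
    ref_mean = steady_state(ref, window_s, (variable,)).value(reference_phase, variable)
    if not ref_mean > floor:
        raise SteadyStateError(
            f"reference mean {ref_mean:g} for '{variable}' is at or below the floor {floor:g}"
        )
    out = ts.copy()
    out.data[variable] = out.data[variable] / ref_mean
    out.meta["relative_reference"] = {
        "phase": reference_phase,
        "variable": variable,
        "mean": ref_mean,
        "window_s": window_s,
    }
    return out
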