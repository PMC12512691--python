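"""Stomatal opening/closing kinetics: Gompertz-type sigmoid fits per transition.

The conductance response to a step change in light is modelled with the
double-exponential (Gompertz-type) sigmoid

    g(t) = g_i + (g_f − g_i) · exp(−exp((λ − t) / k)),

with t in minutes since the light switch, g_i the pre-transition conductance
asymptote, g_f the post-transition asymptote, λ the lag time (min) — the
inflection point, where the slope magnitude is maximal — and k the time
parameter of the sigmoid (min).  The maximum slope is

    Sl_max = (g_f − g_i) / (k·e),

signed by direction (positive for opening, negative for closing), and is
reported in mmol m⁻² s⁻² (×10³ mol→mmol, ÷60 per-minute→per-second).  Because
published kinetics tables print k in min⁻¹, the reciprocal rate 1/k is
emitted alongside the fitted time constant.

One code path fits both directions; opening vs closing is carried by the sign
of g_f − g_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .timecourse import DEFAULT_WINDOW_S, LightPhase, steady_state

#: minimum conductance change treated as a real response (mol m⁻² s⁻¹)
RESPONSE_FLOOR = 0.01
#: unit conversion for Sl_max: mol m⁻² s⁻¹ min⁻¹ -> mmol m⁻² s⁻²
SLMAX_FACTOR = 1e3 / 60.0

K_BOUNDS_MIN = (0.1, 60.0)


def model_gsw(t, g_i: float, g_f: float, lam: float, k: float):
    """Evaluate the sigmoid g(t); t in minutes since the light switch.

    Monotone from g_i (t → −∞) to g_f (t → +∞); inflection at t = λ.
    """
    if k <= 0:
        raise ValueError("time parameter k must be strictly positive")
    t = np.asarray(t, dtype=float)
    inner = np.clip((lam - t) / k, -745.0, 709.0)
    out = g_i + (g_f - g_i) * np.exp(-np.exp(inner))
    return out if out.ndim else float(out)


@dataclass
class TransitionWindow:
    """Records from a light switch to the end of the following phase."""

    from_phase: str
    to_phase: str
    t0: float  # time of the light switch (s), == to_phase t_start
    data: pd.DataFrame
    g_i_hint: float | None = None  # preceding-phase steady-state mean

    @property
    def label(self) -> str:
        return f"{self.from_phase}->{self.to_phase}"


@dataclass
class KineticsFit:
    """Fitted transition parameters and diagnostics.

    ``flag`` is one of ``"ok"``, ``"no_response"`` or ``"failed"``; parameters
    are NaN unless the fit succeeded.  ``k`` is the sigmoid time parameter in
    minutes, ``k_rate`` its reciprocal in min⁻¹; ``sl_max`` is in
    mmol m⁻² s⁻².
    """

    transition: str = ""
    direction: str = ""
    g_i: float = math.nan
    g_f: float = math.nan
    lam: float = math.nan
    k: float = math.nan
    k_rate: float = math.nan
    sl_max: float = math.nan
    rss: float = math.nan
    r2: float = math.nan
    n_points: int = 0
    success: bool = False
    flag: str = "failed"
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "transition": self.transition,
            "direction": self.direction,
            "g_i": self.g_i,
            "g_f": self.g_f,
            "lam": self.lam,
            "k": self.k,
            "k_rate": self.k_rate,
            "sl_max": self.sl_max,
            "rss": self.rss,
            "r2": self.r2,
            "n_points": self.n_points,
            "success": self.success,
            "flag": self.flag,
        }


def transition_windows(
    phases: list[LightPhase],
    steady_window_s: float = DEFAULT_WINDOW_S,
) -> list[TransitionWindow]:
    """Build one window per light change, with g_i hints from the previous
    phase's steady state (fallback: mean of its last 5 records)."""
    windows = []
    for prev, cur in zip(phases[:-1], phases[1:]):
        if prev.par_level == cur.par_level:
            continue
        try:
            hint = steady_state(prev, steady_window_s, ("gsw",)).value(prev.label, "gsw")
        except Exception:
            hint = float(prev.data["gsw"].tail(5).mean())
        windows.append(
            TransitionWindow(
                from_phase=prev.label,
                to_phase=cur.label,
                t0=cur.t_start,
                data=cur.data.copy(),
                g_i_hint=hint,
            )
        )
    return windows


def _initial_guess(tau: np.ndarray, y: np.ndarray, g_i0: float, g_f0: float) -> tuple[float, float]:
    """λ₀ from the 10%-progress crossing, k₀ from (63% crossing − λ₀),
    floored at 0.5 min; direction-neutral via normalised progress."""
    delta = g_f0 - g_i0
    progress = (y - g_i0) / delta if delta != 0 else np.zeros_like(y)
    lam0 = 0.0
    for thresh, store in ((0.10, "lam"), (0.632, "k")):
        idx = np.nonzero(progress >= thresh)[0]
        t_cross = float(tau[idx[0]]) if len(idx) else float(tau[-1])
        if store == "lam":
            lam0 = t_cross
        else:
            k0 = max(0.5, t_cross - lam0)
    return lam0, k0


def fit_transition(
    w: TransitionWindow,
    init: dict | None = None,
    bounds: dict | None = None,
    response_floor: float = RESPONSE_FLOOR,
) -> KineticsFit:
    """Nonlinear least-squares fit of the sigmoid to one transition.

    Requires ≥ 6 records.  A trace whose conductance range (and whose
    initial-vs-final contrast) stays below ``response_floor`` is flagged
    ``"no_response"``; a non-converging fit returns a flagged failure object
    carrying diagnostics rather than raising.
    """
    t = w.data["t"].to_numpy(float)
    y = w.data["gsw"].to_numpy(float)
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if len(y) < 6:
        raise ValueError(f"transition '{w.label}' has {len(y)} points; need ≥ 6")
    tau = (t - w.t0) / 60.0  # minutes since the switch

    g_i0 = w.g_i_hint if w.g_i_hint is not None else float(y[0])
    g_f0 = float(np.mean(y[-5:]))
    data_range = float(np.max(y) - np.min(y))
    if data_range < response_floor and abs(g_f0 - g_i0) < response_floor:
        return KineticsFit(
            transition=w.label,
            n_points=len(y),
            flag="no_response",
            message=f"conductance range {data_range:.4g} below response floor {response_floor:g}",
        )

    lam0, k0 = _initial_guess(tau, y, g_i0, g_f0)
    if init:
        g_i0 = init.get("g_i", g_i0)
        g_f0 = init.get("g_f", g_f0)
        lam0 = init.get("lam", lam0)
        k0 = init.get("k", k0)

    tau_max = float(tau[-1])
    span = max(data_range, abs(g_f0 - g_i0), 1e-6)
    lo_g = min(np.min(y), g_i0) - 3 * span
    hi_g = max(np.max(y), g_i0) + 3 * span
    b = {
        "g_i": (lo_g, hi_g),
        "g_f": (lo_g, hi_g),
        "lam": (0.0, tau_max),
        "k": K_BOUNDS_MIN,
    }
    if bounds:
        b.update(bounds)
    lower = [b["g_i"][0], b["g_f"][0], b["lam"][0], b["k"][0]]
    upper = [b["g_i"][1], b["g_f"][1], b["lam"][1], b["k"][1]]
    p0 = np.clip([g_i0, g_f0, lam0, k0], lower, upper)

    try:
        popt, _ = curve_fit(
            model_gsw,
            tau,
            y,
            p0=p0,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=20000,
        )
    except Exception as exc:  # non-convergence -> flagged failure, not an exception
        return KineticsFit(
            transition=w.label, n_points=len(y), flag="failed", message=str(exc)
        )

    g_i, g_f, lam, k = (float(v) for v in popt)
    resid = y - model_gsw(tau, g_i, g_f, lam, k)
    rss = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    sl_max = (g_f - g_i) / (k * math.e) * SLMAX_FACTOR
    return KineticsFit(
        transition=w.label,
        direction="opening" if g_f > g_i else "closing",
        g_i=g_i,
        g_f=g_f,
        lam=lam,
        k=k,
        k_rate=1.0 / k,
        sl_max=sl_max,
        rss=rss,
        r2=r2,
        n_points=len(y),
        success=True,
        flag="ok",
    )


def predicted_curve(fit: KineticsFit, tau: np.ndarray) -> np.ndarray:
    """Model prediction of a successful fit on a minute grid."""
    if not fit.success:
        raise ValueError("cannot predict from an unsuccessful fit")
    return model_gsw(tau, fit.g_i, fit.g_f, fit.lam, fit.k)


def fits_to_frame(fits: Iterable[tuple[str, str, KineticsFit]]) -> pd.DataFrame:
    """Rows of (group, individual, fit) -> tidy per-fit table."""
    rows = []
    for group, individual, fit in fits:
        row = {"group": group, "individual": individual}
        row.update(fit.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _iqr_mask(values: np.ndarray, factor: float) -> np.ndarray:
    """True for values kept by the 1.5×IQR rule (quartiles by linear
    interpolation); degenerate IQR = 0 keeps only values equal to the median
    band."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - factor * iqr) & (values <= q3 + factor * iqr)


def summarize_kinetics(
    fit_frame: pd.DataFrame,
    group_cols: tuple[str, ...] = ("group", "transition"),
    parameters: tuple[str, ...] = ("lam", "k", "k_rate", "sl_max"),
    iqr_factor: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-individual summary: mean ± sd per parameter after outlier removal.

    Outliers are removed per parameter by the 1.5×IQR rule within each
    (group, transition) cell before averaging; removed fits are returned in a
    second table, never silently dropped.  A cell whose fits all failed yields
    a row with n_used = 0 and the failure count.
    """
    summaries = []
    removed = []
    for keys, cell in fit_frame.groupby(list(group_cols), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        key_dict = dict(zip(group_cols, keys))
        good = cell[cell["success"] == True]  # noqa: E712 - pandas mask
        n_failed = int(len(cell) - len(good))
        if len(good) == 0:
            for param in parameters:
                summaries.append(
                    {**key_dict, "parameter": param, "mean": math.nan, "sd": math.nan,
                     "n_used": 0, "n_removed": 0, "n_failed": n_failed}
                )
            continue
        direction = good["direction"].mode().iloc[0] if "direction" in good else ""
        for param in parameters:
            vals = good[param].to_numpy(float)
            keep = _iqr_mask(vals, iqr_factor)
            kept = vals[keep]
            for idx, flag in zip(good.index, keep):
                if not flag:
                    removed.append(
                        {**key_dict, "parameter": param,
                         "individual": good.loc[idx].get("individual", ""),
                         "value": float(good.loc[idx, param])}
                    )
            summaries.append(
                {**key_dict, "parameter": param, "direction": direction,
                 "mean": float(np.mean(kept)), "sd": float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0,
                 "n_used": int(len(kept)), "n_removed": int(len(vals) - len(kept)),
                 "n_failed": n_failed}
            )
    removed_cols = [*group_cols, "parameter", "individual", "value"]
    return (
        pd.DataFrame(summaries),
        pd.DataFrame(removed, columns=removed_cols) if removed else pd.DataFrame(columns=removed_cols),
    )
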