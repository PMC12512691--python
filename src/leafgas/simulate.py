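"""Synthetic gas-exchange runs and anatomy tables with known ground truth.

The run simulator emulates the measurement protocol the rest of the package
expects: records logged every 60 s through a four-step light schedule
(1000 → 100 → 1000 → 0 µmol m⁻² s⁻¹ PAR, 20 min each), with each light
transition following the Gompertz-type sigmoid of :mod:`leafgas.kinetics`.
Transitions are chained continuously: the pre-transition asymptote g_i of
each transition is the realised conductance at the end of the previous phase,
as in a real leaf.

Assimilation is coupled to conductance either linearly (A = c·g_sw, which
makes iWUE identically c) or with a saturating form A = A_max·g_sw/(g_sw+K).
Ci and E are simple consistent bookkeeping — Ci = Ca − A/(1.6·g_sw) clipped
at 0, E proportional to g_sw — phenomenological plumbing, not a leaf model.

The anatomy simulator draws per-field stomata counts from a Poisson with mean
density × field area and per-stoma sizes from truncated normals, optionally
imposing a between-individual density–size correlation.

Everything is reproducible from the seed, and every generator returns its
ground truth so downstream estimators can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GasExchangeTimeseries
from .kinetics import SLMAX_FACTOR, model_gsw

#: the standard four-phase light protocol: (PAR µmol m⁻² s⁻¹, duration s)
PAPER_SCHEDULE: tuple[tuple[float, float], ...] = (
    (1000.0, 1200.0),
    (100.0, 1200.0),
    (1000.0, 1200.0),
    (0.0, 1200.0),
)

# defaults emulate a well-watered C3 grass leaf (B. distachyon-like):
# high-light gsw ~0.27, low light ~0.08, darkness ~0.02 mol m⁻² s⁻¹;
# lags ~1-1.5 min and time parameters ~2-2.5 min reproduce published
# maximum-slope magnitudes of ~0.4-0.6 mmol m⁻² s⁻²
DEFAULT_PHASE_GSW = (0.273, 0.082, 0.252, 0.018)
DEFAULT_TRANSITIONS = ((1.24, 2.0), (1.44, 2.5), (1.05, 2.5))


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic run.

    noise_sd maps column name to the s.d. of i.i.d. Gaussian measurement
    noise (defaults: 0.005 mol m⁻² s⁻¹ on gsw, 0.1 µmol m⁻² s⁻¹ on A —
    IRGA-realistic magnitudes; set to 0 for noise-free traces).
    """

    schedule: tuple[tuple[float, float], ...] = PAPER_SCHEDULE
    phase_gsw: tuple[float, ...] = DEFAULT_PHASE_GSW
    transitions: tuple[tuple[float, float], ...] = DEFAULT_TRANSITIONS  # (λ min, k min)
    coupling: tuple[str, dict] = ("linear", {"c": 70.0})
    Ca: float = 400.0
    T_leaf: float = 28.0
    RH: float = 40.0
    E_per_gsw: float = 0.0127  # mol H2O per mol conductance at ~40% RH, 28 °C
    noise_sd: dict = field(default_factory=lambda: {"gsw": 0.005, "A": 0.1})
    interval_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(dur <= 0 for _, dur in self.schedule):
            raise ValueError("schedule durations must be positive")
        if min(dur for _, dur in self.schedule) < self.interval_s:
            raise ValueError("every schedule step must span at least one logging interval")
        if len(self.phase_gsw) != len(self.schedule):
            raise ValueError("phase_gsw must give one target per schedule step")
        if len(self.transitions) != len(self.schedule) - 1:
            raise ValueError("transitions must give (λ, k) per light change")
        if any(k <= 0 for _, k in self.transitions):
            raise ValueError("transition k must be strictly positive")
        if any(lam < 0 for lam, _ in self.transitions):
            raise ValueError("transition λ must be non-negative")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sd must be non-negative")


def _noiseless_gsw(spec: SimulationSpec, t: np.ndarray) -> tuple[np.ndarray, list[dict]]:
    """Chained sigmoid trace at times t (s from run start) plus per-transition
    ground truth (realised g_i, target g_f, λ, k, Sl_max)."""
    edges = np.concatenate([[0.0], np.cumsum([dur for _, dur in spec.schedule])])
    g = np.empty_like(t)
    transitions = []
    g_end_prev = spec.phase_gsw[0]
    for j in range(len(spec.schedule)):
        mask = (t >= edges[j]) & (t < edges[j + 1])
        if j == 0:
            g[mask] = spec.phase_gsw[0]
            g_end_prev = spec.phase_gsw[0]
            continue
        lam, k = spec.transitions[j - 1]
        target = spec.phase_gsw[j]
        tau = (t[mask] - edges[j]) / 60.0
        g[mask] = model_gsw(tau, g_end_prev, target, lam, k)
        transitions.append(
            {
                "index": j - 1,
                "t0_s": float(edges[j]),
                "g_i": float(g_end_prev),
                "g_f": float(target),
                "lam": float(lam),
                "k": float(k),
                "sl_max": float((target - g_end_prev) / (k * math.e) * SLMAX_FACTOR),
            }
        )
        tau_end = (edges[j + 1] - edges[j]) / 60.0
        g_end_prev = float(model_gsw(tau_end, g_end_prev, target, lam, k))
    return g, transitions


def _couple_A(spec: SimulationSpec, gsw: np.ndarray) -> np.ndarray:
    kind, coef = spec.coupling
    if kind == "linear":
        return coef["c"] * gsw
    if kind == "saturating":
        return coef["A_max"] * gsw / (gsw + coef["K"])
    raise ValueError(f"unknown coupling '{kind}'")


def simulate_run(spec: SimulationSpec) -> tuple[GasExchangeTimeseries, dict]:
    """Generate one logged run and its ground-truth record.

    Returns (timeseries, truth).  ``truth`` carries the full spec, the
    per-transition parameters (with realised g_i), and the noiseless
    steady-state means of gsw, A and iWUE over the last 5 min of each phase —
    exactly what the analysis pipeline should recover from a noise-free file.
    """
    total = sum(dur for _, dur in spec.schedule)
    t = np.arange(0.0, total, spec.interval_s)
    gsw0, transitions = _noiseless_gsw(spec, t)
    A0 = _couple_A(spec, gsw0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ci0 = np.clip(spec.Ca - A0 / (1.6 * gsw0), 0.0, None)
    E0 = spec.E_per_gsw * gsw0

    edges = np.concatenate([[0.0], np.cumsum([dur for _, dur in spec.schedule])])
    q = np.empty_like(t)
    for j, (par, _) in enumerate(spec.schedule):
        q[(t >= edges[j]) & (t < edges[j + 1])] = par

    rng = np.random.default_rng(spec.seed)
    cols = {"gsw": gsw0.copy(), "A": A0.copy(), "Ci": Ci0.copy(), "E": E0.copy()}
    for name, sd in spec.noise_sd.items():
        if sd > 0 and name in cols:
            cols[name] = cols[name] + rng.normal(0.0, sd, size=len(t))

    df = pd.DataFrame(
        {
            "t": t,
            "q_in": q,
            "gsw": cols["gsw"],
            "A": cols["A"],
            "Ci": cols["Ci"],
            "Ca": np.full_like(t, spec.Ca),
            "E": cols["E"],
            "T_leaf": np.full_like(t, spec.T_leaf),
            "RH": np.full_like(t, spec.RH),
        }
    )

    # noiseless steady states over the last 300 s of each phase
    window = 300.0
    steady = {}
    labels = _phase_labels(spec)
    for j, label in enumerate(labels):
        mask = (t >= edges[j + 1] - window) & (t < edges[j + 1])
        gs, aa = gsw0[mask], A0[mask]
        iwue = np.where(gs >= 1e-3, aa / np.where(gs >= 1e-3, gs, 1.0), np.nan)
        steady[label] = {
            "gsw": float(np.mean(gs)),
            "A": float(np.mean(aa)),
            "iwue": float(np.nanmean(iwue)) if np.any(~np.isnan(iwue)) else math.nan,
        }

    for tr, (frm, to) in zip(transitions, zip(labels[:-1], labels[1:])):
        tr["from_phase"], tr["to_phase"] = frm, to

    truth = {
        "spec": asdict(spec),
        "phase_labels": labels,
        "transitions": transitions,
        "steady_state": steady,
        "steady_window_s": window,
    }
    ts = GasExchangeTimeseries(df, meta={"source": "simulated", "seed": spec.seed})
    ts.validate()
    return ts, truth


def _phase_labels(spec: SimulationSpec) -> list[str]:
    from .timecourse import _label_phases

    return _label_phases([p for p, _ in spec.schedule])


def simulate_anatomy(
    n_individuals: int = 5,
    density_mean: float = 100.0,
    density_between_sd: float = 15.0,
    field_area_mm2: float = 0.198,
    n_fields: int = 3,
    length_mean: float = 24.1,
    length_within_sd: float = 2.8,
    length_between_sd: float = 2.0,
    width_mean: float = 6.4,
    width_within_sd: float = 0.6,
    width_between_sd: float = 0.4,
    n_measured: tuple[int, int] = (73, 100),
    density_size_rho: float = 0.0,
    seed: int = 0,
    prefix: str = "ind",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw field-count and size-measurement tables for one group.

    Per individual, a latent normal deviate sets the true density
    (mean ``density_mean``, sd ``density_between_sd``); per-field counts are
    Poisson(density × area).  Stomatal lengths/widths are truncated normals
    around per-individual centres; ``density_size_rho`` couples the density
    deviate to the length centre (negative values emulate the
    denser-means-smaller pattern).  Sizes respect length ≥ width.

    Returns (counts, measurements, truth).
    """
    if n_individuals < 1 or n_fields < 1 or field_area_mm2 <= 0:
        raise ValueError("invalid sampling design")
    if not -1.0 <= density_size_rho <= 1.0:
        raise ValueError("density_size_rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)

    counts_rows, meas_rows, truth_ind = [], [], []
    for i in range(n_individuals):
        ind = f"{prefix}{i + 1}"
        z = rng.standard_normal()
        eps = rng.standard_normal()
        density_i = max(1.0, density_mean + density_between_sd * z)
        w = density_size_rho * z + math.sqrt(1 - density_size_rho**2) * eps
        length_c = max(1.0, length_mean + length_between_sd * w)
        width_c = max(0.5, width_mean + width_between_sd * rng.standard_normal())

        for f in range(n_fields):
            counts_rows.append(
                {
                    "individual": ind,
                    "field": f + 1,
                    "n_stomata": int(rng.poisson(density_i * field_area_mm2)),
                    "field_area": field_area_mm2,
                }
            )

        n_meas = int(rng.integers(n_measured[0], n_measured[1] + 1))
        lengths = _trunc_normal(rng, length_c, length_within_sd, 0.1, n_meas)
        widths = _trunc_normal(rng, width_c, width_within_sd, 0.1, n_meas)
        widths = np.minimum(widths, lengths)  # complexes are longer than wide
        for L, W in zip(lengths, widths):
            meas_rows.append({"individual": ind, "length": float(L), "width": float(W)})

        truth_ind.append(
            {"individual": ind, "density": density_i, "length_centre": length_c,
             "width_centre": width_c, "n_measured": n_meas}
        )

    truth = {
        "density_mean": density_mean,
        "density_between_sd": density_between_sd,
        "length_mean": length_mean,
        "width_mean": width_mean,
        "density_size_rho": density_size_rho,
        "seed": seed,
        "individuals": truth_ind,
    }
    return pd.DataFrame(counts_rows), pd.DataFrame(meas_rows), truth


def _trunc_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, float(mean))
    from scipy.stats import truncnorm

    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
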