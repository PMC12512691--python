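"""Stomatal anatomy: density, size, anatomical g_smax and group statistics.

Stomatal density is estimated from counted microscope fields of known area
(pooled counts: Σn / Σarea per individual).  Anatomical maximum stomatal
conductance follows the diffusion equation

    g_smax = (d · D_w · a_max) / (v · (l + (π/2)·√(a_max/π))),

with d the stomatal density (m⁻²), D_w the diffusivity of water vapour in air
(m² s⁻¹), v the molar volume of air (m³ mol⁻¹), a_max the maximum stomatal
pore area (m²) and l the pore depth (m).  How a_max and l are estimated from
stomatal complex length (SL) and width at the apices (WA) is taxon-specific;
estimators are therefore a named, parameterised registry with no built-in
coefficients — users supply the parameterisation calibrated for their taxon.

Group comparisons use one-way ANOVA plus Tukey's HSD at α = 0.05 with a
deterministic compact-letter display (groups sorted by mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

#: diffusivity of water vapour in air, m² s⁻¹ (≈25 °C)
D_W_DEFAULT = 2.49e-5
#: molar volume of air, m³ mol⁻¹ (≈25 °C, 1 atm)
V_DEFAULT = 0.0224

# ---------------------------------------------------------------------------
# estimator registries: (SL µm, WA µm, **coefficients) -> µm² / µm

AMAX_MODELS: dict[str, Callable] = {
    # pore treated as an ellipse of axes c_l·SL and c_w·WA
    "scaled_ellipse": lambda SL, WA, c_l, c_w: np.pi * (c_l * SL / 2) * (c_w * WA / 2),
    # generic bilinear form alpha·SL·WA + beta
    "affine_product": lambda SL, WA, alpha, beta=0.0: alpha * SL * WA + beta,
    # fixed fraction of the circumscribing rectangle
    "rectangle_fraction": lambda SL, WA, f: f * SL * WA,
}

PORE_DEPTH_MODELS: dict[str, Callable] = {
    "fraction_of_width": lambda SL, WA, c: c * WA,
    "fraction_of_length": lambda SL, WA, c: c * SL,
    "constant": lambda SL, WA, value: value + 0.0 * SL,
}


@dataclass(frozen=True)
class GsmaxParams:
    """Physical constants and anatomical estimators for g_smax.

    ``amax_model`` / ``pore_depth_model`` are ``(name, coefficients)`` pairs
    resolved against the registries above; both are required — there are no
    default coefficients, since the calibration is taxon-specific.
    """

    amax_model: tuple[str, dict]
    pore_depth_model: tuple[str, dict]
    d_w: float = D_W_DEFAULT
    v: float = V_DEFAULT

    def __post_init__(self) -> None:
        if not (self.d_w > 0 and self.v > 0):
            raise ConfigurationError("d_w and v must be strictly positive")
        for attr, registry in (("amax_model", AMAX_MODELS), ("pore_depth_model", PORE_DEPTH_MODELS)):
            spec = getattr(self, attr)
            if (
                not isinstance(spec, tuple)
                or len(spec) != 2
                or spec[0] not in registry
                or not isinstance(spec[1], dict)
            ):
                raise ConfigurationError(
                    f"{attr} must be (name, coefficients) with name in "
                    f"{sorted(registry)}; supply the parameterisation calibrated "
                    f"for your taxon — no default coefficients are shipped"
                )

    def amax_um2(self, SL, WA):
        name, coef = self.amax_model
        out = AMAX_MODELS[name](np.asarray(SL, float), np.asarray(WA, float), **coef)
        if np.any(np.asarray(out) <= 0):
            raise ConfigurationError(f"amax model '{name}' returned a non-positive pore area")
        return out

    def pore_depth_um(self, SL, WA):
        name, coef = self.pore_depth_model
        out = PORE_DEPTH_MODELS[name](np.asarray(SL, float), np.asarray(WA, float), **coef)
        if np.any(np.asarray(out) <= 0):
            raise ConfigurationError(f"pore-depth model '{name}' returned a non-positive depth")
        return out


# ---------------------------------------------------------------------------


def stomatal_density(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-individual stomatal density from field counts.

    ``counts`` columns: individual, n_stomata, field_area (mm²).  The density
    is the pooled estimator Σn / Σarea; per-field densities are summarised
    alongside (mean, sd) for dispersion.
    """
    req = {"individual", "n_stomata", "field_area"}
    missing = req - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["field_area"] <= 0).any():
        raise ValueError("field_area must be strictly positive")
    if (counts["n_stomata"] < 0).any():
        raise ValueError("n_stomata must be non-negative")

    rows = []
    for ind, sub in counts.groupby("individual", sort=False):
        total_area = float(sub["field_area"].sum())
        if total_area <= 0:
            raise ValueError(f"zero total field area for individual {ind!r}")
        per_field = sub["n_stomata"].to_numpy(float) / sub["field_area"].to_numpy(float)
        rows.append(
            {
                "individual": ind,
                "density_mm2": float(sub["n_stomata"].sum()) / total_area,
                "n_fields": len(sub),
                "n_stomata_total": int(sub["n_stomata"].sum()),
                "field_density_mean": float(np.mean(per_field)),
                "field_density_sd": float(np.std(per_field, ddof=1)) if len(per_field) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def size_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-individual stomatal size statistics.

    ``measurements`` columns: individual, length (µm), width (µm).  The
    length/width ratio is computed per stoma then averaged
    (``ratio_mean``); the ratio of the two means (``ratio_of_means``) is
    also emitted because printed tables are often built from rounded means.
    """
    req = {"individual", "length", "width"}
    missing = req - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements table missing columns: {sorted(missing)}")
    if (measurements["length"] <= 0).any() or (measurements["width"] <= 0).any():
        raise ValueError("stomatal length and width must be strictly positive")

    rows = []
    for ind, sub in measurements.groupby("individual", sort=False):
        length = sub["length"].to_numpy(float)
        width = sub["width"].to_numpy(float)
        ratio = length / width
        sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        rows.append(
            {
                "individual": ind,
                "n": len(sub),
                "length_mean": float(length.mean()),
                "length_sd": sd(length),
                "width_mean": float(width.mean()),
                "width_sd": sd(width),
                "ratio_mean": float(ratio.mean()),
                "ratio_sd": sd(ratio),
                "ratio_of_means": float(length.mean() / width.mean()),
            }
        )
    return pd.DataFrame(rows)


def anatomical_gsmax(density_mm2, SL_um, WA_um, params: GsmaxParams):
    """Anatomical maximum stomatal conductance (mol m⁻² s⁻¹).

    Inputs are per individual (scalars or aligned arrays): density in mm⁻²,
    SL and WA in µm.  Linear in density and in a_max's contribution to the
    numerator; decreasing in pore depth.
    """
    d = np.asarray(density_mm2, float) * 1e6  # mm^-2 -> m^-2
    if np.any(d <= 0):
        raise ValueError("density must be strictly positive")
    amax = np.asarray(params.amax_um2(SL_um, WA_um), float) * 1e-12  # µm² -> m²
    depth = np.asarray(params.pore_depth_um(SL_um, WA_um), float) * 1e-6  # µm -> m
    g = (d * params.d_w * amax) / (params.v * (depth + (np.pi / 2) * np.sqrt(amax / np.pi)))
    return float(g) if np.ndim(g) == 0 else g


def operational_opening(gsw_high_light: float, gsmax: float) -> tuple[float, int]:
    """Measured high-light g_SW as a percentage of anatomical g_smax.

    Returns ``(percent, percent_rounded)`` with half-up rounding to an
    integer for table output; the unrounded value is retained.
    """
    if not gsmax > 0:
        raise ValueError("gsmax must be strictly positive")
    pct = 100.0 * gsw_high_light / gsmax
    return pct, int(math.floor(pct + 0.5))


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True

    @property
    def sign(self) -> int:
        return 0 if not self.defined or self.r == 0 else (1 if self.r > 0 else -1)


def density_size_correlation(density, size) -> CorrelationResult:
    """Two-sided Pearson correlation between stomatal density and size."""
    x = np.asarray(density, float)
    y = np.asarray(size, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need ≥ 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(math.nan, math.nan, len(x), defined=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc and compact letters."""

    f: float
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    group_means: dict[str, float] = dc_field(default_factory=dict)


def _compact_letters(groups: list[str], means: dict[str, float], nonsig: set[frozenset]) -> dict[str, str]:
    """Deterministic compact-letter display: groups sorted by descending mean;
    each letter covers a maximal run of mutually non-different groups."""
    order = sorted(groups, key=lambda g: (-means[g], g))

    def all_nonsig(block: list[str]) -> bool:
        return all(
            frozenset((a, b)) in nonsig for i, a in enumerate(block) for b in block[i + 1:]
        )

    blocks: list[list[str]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all_nonsig(order[i: j + 2]):
            j += 1
        block = order[i: j + 1]
        if not any(set(block) <= set(b) for b in blocks):
            blocks.append(block)
    letters = {g: "" for g in order}
    for letter_idx, block in enumerate(blocks):
        letter = chr(ord("a") + letter_idx)
        for g in block:
            letters[g] += letter
    return letters


def compare_groups(values, groups, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across ≥ 2 groups (≥ 2 values each) with Tukey HSD.

    Letters are assigned deterministically with groups sorted by mean:
    groups sharing a letter are not significantly different at ``alpha``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need ≥ 2 groups with ≥ 2 values each")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*samples)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})

    nonsig = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey.iterrows()
        if not bool(row["reject"])
    }
    means = {g: float(np.mean(s)) for g, s in zip(labels, samples)}
    letters = _compact_letters([str(g) for g in labels], {str(g): m for g, m in means.items()},
                               {frozenset(map(str, fs)) for fs in nonsig})
    return GroupComparison(float(f), float(p), tukey, letters, {str(g): m for g, m in means.items()})
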