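"""Reading, validating and area-correcting infrared gas-analyser (IRGA) exports.

The supported dialect is the LI-6800-style export: a header block consisting of
an (optional) group row, a variable-name row and a units row, followed by one
logged record per line.  Both tab-delimited text and ``.xlsx`` spreadsheets are
accepted; the dialect is auto-detected from the file extension and can be
overridden.

All values are converted to canonical units at this boundary:

==========  =================================  =====================
column      meaning                            canonical unit
==========  =================================  =====================
t           elapsed time                       s
q_in        incident light (PAR/PPFD)          µmol m⁻² s⁻¹
gsw         stomatal conductance to water      mol m⁻² s⁻¹
A           net CO₂ assimilation               µmol m⁻² s⁻¹
Ci          intercellular CO₂ mole fraction    µmol mol⁻¹
Ca          ambient CO₂ mole fraction          µmol mol⁻¹
E           transpiration                      mol m⁻² s⁻¹
T_leaf      leaf temperature                   °C
RH          relative humidity                  %
==========  =================================  =====================
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError, SchemaError

#: canonical column -> default LI-6800 source column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "t": "elapsed",
    "q_in": "Qin",
    "gsw": "gsw",
    "A": "A",
    "Ci": "Ci",
    "Ca": "Ca",
    "E": "E",
    "T_leaf": "Tleaf",
    "RH": "rh_s",
}

MANDATORY_COLUMNS = ("t", "q_in", "gsw", "A")
OPTIONAL_COLUMNS = ("Ci", "Ca", "E", "T_leaf", "RH")
#: per-leaf-area flux columns that scale with the area correction
FLUX_COLUMNS = ("gsw", "A", "E")

CANONICAL_UNITS: dict[str, str] = {
    "t": "s",
    "q_in": "umol m-2 s-1",
    "gsw": "mol m-2 s-1",
    "A": "umol m-2 s-1",
    "Ci": "umol mol-1",
    "Ca": "umol mol-1",
    "E": "mol m-2 s-1",
    "T_leaf": "degC",
    "RH": "%",
}

# molar-prefix scale relative to mol; canonical prefix scale per column
_PREFIX = {"mol": 1.0, "mmol": 1e-3, "umol": 1e-6, "µmol": 1e-6, "nmol": 1e-9}
_CANON_PREFIX = {"gsw": 1.0, "E": 1.0, "A": 1e-6, "q_in": 1e-6, "Ci": 1e-6, "Ca": 1e-6}
_TIME_FACTOR = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0, "ms": 1e-3}

_SUPERSCRIPTS = str.maketrans({"⁻": "-", "¹": "1", "²": "2", "³": "3", "⁰": "0"})


@dataclass(frozen=True)
class ChamberGeometry:
    """Single-aperture leaf-chamber geometry, in cm / cm².

    The effective leaf area inside the chamber is ``leaf_width *
    chamber_diameter`` (a narrow leaf crossing a circular aperture).
    """

    chamber_area: float  # cm^2
    chamber_diameter: float  # cm, along the leaf
    leaf_width: float  # cm

    def __post_init__(self) -> None:
        for name in ("chamber_area", "chamber_diameter", "leaf_width"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be strictly positive")

    @property
    def leaf_area(self) -> float:
        """Effective leaf area in the chamber (cm²)."""
        return self.leaf_width * self.chamber_diameter


@dataclass
class GasExchangeTimeseries:
    """One leaf/run of logged gas-exchange records in canonical units.

    ``data`` holds one row per logged record, indexed 0..n-1, with a subset of
    the canonical columns (mandatory: t, q_in, gsw, A).  ``meta`` carries run
    provenance: source path, skipped-row count, applied unit conversions and
    the area-correction factor once applied.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def copy(self) -> "GasExchangeTimeseries":
        return GasExchangeTimeseries(self.data.copy(), dict(self.meta))

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    def validate(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"mandatory column '{col}' missing")
        if len(df) == 0:
            raise SchemaError("empty data block: no records")
        t = df["t"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            if np.any(np.diff(t) == 0):
                raise SchemaError("duplicate timestamps in run")
            raise SchemaError("time must be strictly increasing")
        if np.any(df["q_in"].to_numpy(float) < 0):
            raise SchemaError("q_in must be non-negative")
        if "Ca" in df.columns and np.any(df["Ca"].dropna().to_numpy(float) <= 0):
            raise SchemaError("Ca must be strictly positive")
        if "RH" in df.columns:
            rh = df["RH"].dropna().to_numpy(float)
            if np.any((rh < 0) | (rh > 100)):
                raise SchemaError("RH must lie in [0, 100] %")


def _normalise_unit(text: str) -> str:
    s = str(text).translate(_SUPERSCRIPTS)
    s = s.replace("µ", "u").replace("µ", "u")
    return re.sub(r"\s+", " ", s.strip().lower())


def _unit_factor(column: str, unit_text: str) -> float:
    """Multiplier taking a value in ``unit_text`` to the canonical unit.

    Unrecognised or empty unit strings are assumed canonical (factor 1).
    """
    u = _normalise_unit(unit_text)
    if not u:
        return 1.0
    if column == "t":
        return _TIME_FACTOR.get(u.split()[0], 1.0)
    if column in _CANON_PREFIX:
        head = u.split()[0]
        head = head.replace("µ", "u")
        if head in _PREFIX:
            return _PREFIX[head] / _CANON_PREFIX[column]
    return 1.0


def _raw_rows_from_tsv(path: Path, sep: str = "\t") -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        rows.append([c.strip() for c in line.split(sep)])
    return rows


def _raw_rows_from_xlsx(path: Path) -> list[list[str]]:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows = []
    for row in ws.iter_rows(values_only=True):
        rows.append(["" if v is None else str(v).strip() for v in row])
    wb.close()
    return rows


def read_irga(
    file: str | Path,
    column_map: Mapping[str, str] | None = None,
    header_dialect: str | None = None,
) -> GasExchangeTimeseries:
    """Parse an LI-6800-style export into a canonical time series.

    Parameters
    ----------
    file
        Tab-delimited text or ``.xlsx`` export with a header block (optional
        group row, variable-name row, units row) followed by data rows.
    column_map
        Maps canonical field names (t, q_in, gsw, A, Ci, Ca, E, T_leaf, RH)
        to source column names; defaults to the LI-6800 dialect
        (elapsed, Qin, gsw, A, Ci, Ca, E, Tleaf, rh_s).
    header_dialect
        ``"tsv"`` or ``"xlsx"``; auto-detected from the extension if None.

    Non-numeric remark/event rows interleaved in the data block are skipped
    and counted (``meta["n_skipped"]``), never silently dropped.  Unresolved
    optional columns yield absent fields; a missing mandatory column raises
    :class:`~leafgas.errors.SchemaError` naming the column.
    """
    path = Path(file)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    dialect = header_dialect or ("xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "tsv")
    raw = _raw_rows_from_xlsx(path) if dialect == "xlsx" else _raw_rows_from_tsv(path)

    t_name = cmap["t"]
    header_idx = None
    for i, row in enumerate(raw):
        if t_name in row:
            header_idx = i
            break
    if header_idx is None:
        raise SchemaError(f"mandatory column '{cmap['t']}' (canonical 't') not found in header")
    names = raw[header_idx]

    col_idx: dict[str, int] = {}
    for canon, src in cmap.items():
        if src in names:
            col_idx[canon] = names.index(src)
    for canon in MANDATORY_COLUMNS:
        if canon not in col_idx:
            raise SchemaError(f"mandatory column '{canon}' (source name '{cmap[canon]}') missing")

    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    # the row right after the names is a units row iff its t-cell is not numeric
    units: dict[str, str] = {}
    data_start = header_idx + 1
    if data_start < len(raw):
        candidate = raw[data_start]
        t_cell = candidate[col_idx["t"]] if col_idx["t"] < len(candidate) else ""
        if not _is_number(t_cell):
            for canon, j in col_idx.items():
                units[canon] = candidate[j] if j < len(candidate) else ""
            data_start += 1

    records: list[dict[str, float]] = []
    n_skipped = 0
    for row in raw[data_start:]:
        if not any(cell for cell in row):
            continue
        rec: dict[str, float] = {}
        ok = True
        for canon, j in col_idx.items():
            cell = row[j] if j < len(row) else ""
            if _is_number(cell):
                rec[canon] = float(cell)
            elif canon in MANDATORY_COLUMNS:
                ok = False
                break
            else:
                rec[canon] = math.nan
        if ok:
            records.append(rec)
        else:
            n_skipped += 1

    if not records:
        raise SchemaError("empty data block: no parseable records")

    df = pd.DataFrame.from_records(records)
    # drop optional columns that are entirely absent
    df = df.dropna(axis=1, how="all")

    factors = {}
    for canon in df.columns:
        f = _unit_factor(canon, units.get(canon, ""))
        if f != 1.0:
            df[canon] = df[canon] * f
        factors[canon] = f

    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    ts = GasExchangeTimeseries(
        df,
        meta={
            "source": str(path),
            "dialect": dialect,
            "column_map": cmap,
            "units_in": units,
            "unit_factors": factors,
            "n_records": len(df),
            "n_skipped": n_skipped,
        },
    )
    ts.validate()
    return ts


def apply_area_correction(
    ts: GasExchangeTimeseries,
    geom: ChamberGeometry,
    allow_oversize: bool = False,
) -> GasExchangeTimeseries:
    """Rescale per-area fluxes from chamber area to true leaf area.

    The instrument reports fluxes per chamber aperture area; a narrow leaf
    covers only ``leaf_width × chamber_diameter``, so each flux (gsw, A, E) is
    multiplied by ``chamber_area / leaf_area``.  Concentrations, temperature,
    humidity and light are unchanged.  A leaf wider than the aperture
    (leaf_area > chamber_area) is physically a fully covered aperture: allowed
    only with ``allow_oversize=True``, in which case the factor is clamped
    to 1.
    """
    leaf_area = geom.leaf_area
    if leaf_area > geom.chamber_area:
        if not allow_oversize:
            raise GeometryError(
                f"leaf area {leaf_area:g} cm² exceeds chamber area "
                f"{geom.chamber_area:g} cm²; pass allow_oversize=True to clamp the factor to 1"
            )
        factor = 1.0
    else:
        factor = geom.chamber_area / leaf_area

    out = ts.copy()
    for col in FLUX_COLUMNS:
        if col in out.data.columns:
            out.data[col] = out.data[col] * factor
    out.meta["area_correction_factor"] = factor
    out.meta["geometry"] = {
        "chamber_area_cm2": geom.chamber_area,
        "chamber_diameter_cm": geom.chamber_diameter,
        "leaf_width_cm": geom.leaf_width,
        "leaf_area_cm2": leaf_area,
    }
    return out


def write_run(ts: GasExchangeTimeseries, csv_path: str | Path) -> Path:
    """Write a canonical run as a flat one-header-row CSV plus a JSON sidecar.

    The sidecar (same stem, ``.json``) records geometry, correction factor and
    skipped-row count.  Returns the CSV path.
    """
    csv_path = Path(csv_path)
    ts.data.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    meta = dict(ts.meta)
    meta["columns"] = {c: CANONICAL_UNITS.get(c, "") for c in ts.data.columns}
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return csv_path


def read_run(csv_path: str | Path) -> GasExchangeTimeseries:
    """Read back a canonical flat CSV written by :func:`write_run`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = {}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    ts = GasExchangeTimeseries(df, meta)
    ts.validate()
    return ts


def write_irga(
    ts: GasExchangeTimeseries,
    file: str | Path,
    header_dialect: str | None = None,
    group_label: str = "GasEx",
) -> Path:
    """Write a run in the IRGA export dialect that :func:`read_irga` accepts.

    Emits the three-row header (group row, LI-6800 variable names, canonical
    units) followed by full-precision data rows; used by the simulator and by
    round-trip tests.
    """
    path = Path(file)
    dialect = header_dialect or ("xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "tsv")
    cols = [c for c in ts.data.columns if c in DEFAULT_COLUMN_MAP]
    src_names = [DEFAULT_COLUMN_MAP[c] for c in cols]
    unit_row = [CANONICAL_UNITS.get(c, "") for c in cols]
    header = [[group_label] * len(cols), src_names, unit_row]
    body = [[repr(float(v)) for v in row] for row in ts.data[cols].itertuples(index=False)]

    if dialect == "xlsx":
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        for row in header:
            ws.append(row)
        for row in ts.data[cols].itertuples(index=False):
            ws.append([float(v) for v in row])
        wb.save(path)
    else:
        lines = ["\t".join(r) for r in header] + ["\t".join(r) for r in body]
        path.write_text("\n".join(lines) + "\n")
    return path
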