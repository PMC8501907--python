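"""Standardized nomenclature and unit enforcement for gas-exchange tables.

Instrument exports name the same quantity differently (net assimilation is
``A`` on a Li-Cor 6800 but ``PHOTO`` on a 6400).  This module translates any
source dialect into a canonical observation table — one row per instrument
observation, columns drawn from a fixed vocabulary with fixed units
(temperatures in K, fluxes in umol m-2 s-1, RH as a 0-1 fraction, water
potential in MPa).

The canonical table is a plain :class:`pandas.DataFrame`; unit bookkeeping
and provenance (which raw columns were carried through unmapped, which
varname map was applied) ride along in ``DataFrame.attrs``.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CANONICAL_VOCABULARY",
    "CANONICAL_UNITS",
    "StandardizeError",
    "UnitError",
    "load_varname_map",
    "standardize_columns",
    "invert_varname_map",
    "enforce_units",
    "read_table",
    "write_table",
]

#: Canonical column vocabulary and canonical units.
CANONICAL_UNITS: dict[str, str] = {
    "A_net": "umol/m2/s",
    "Q": "umol/m2/s",
    "C_i": "umol/mol",
    "C_a": "umol/mol",
    "C_s": "umol/mol",
    "g_sw": "mol/m2/s",
    "T_leaf": "K",
    "T_air": "K",
    "RH": "fraction",
    "D": "kPa",
    "phi_PSII": "dimensionless",
    "J_F": "umol/m2/s",
    "psi": "MPa",
    "PLC": "%",
    "mass": "g",
    "RWC": "%",
    "rate": "umol/m2/s",
}

CANONICAL_VOCABULARY = frozenset(CANONICAL_UNITS)

# Accepted source units per canonical column and the conversion to canonical.
# Each entry: unit-string -> callable applied to the numeric values.
_IDENT = lambda v: v  # noqa: E731
_CONVERSIONS: dict[str, dict[str, object]] = {
    "T_leaf": {"K": _IDENT, "degC": lambda v: v + 273.15, "C": lambda v: v + 273.15},
    "T_air": {"K": _IDENT, "degC": lambda v: v + 273.15, "C": lambda v: v + 273.15},
    "RH": {"fraction": _IDENT, "%": lambda v: v / 100.0, "percent": lambda v: v / 100.0},
    "PLC": {"%": _IDENT, "percent": _IDENT, "fraction": lambda v: v * 100.0},
    "RWC": {"%": _IDENT, "percent": _IDENT, "fraction": lambda v: v * 100.0},
    "D": {"kPa": _IDENT, "Pa": lambda v: v / 1000.0, "MPa": lambda v: v * 1000.0},
    "psi": {"MPa": _IDENT, "kPa": lambda v: v / 1000.0, "bar": lambda v: v / 10.0},
    "mass": {"g": _IDENT, "mg": lambda v: v / 1000.0, "kg": lambda v: v * 1000.0},
    "g_sw": {"mol/m2/s": _IDENT, "mmol/m2/s": lambda v: v / 1000.0},
    "phi_PSII": {"dimensionless": _IDENT},
}
for _flux in ("A_net", "Q", "J_F", "rate"):
    _CONVERSIONS[_flux] = {
        "umol/m2/s": _IDENT,
        "mmol/m2/s": lambda v: v * 1000.0,
        "mol/m2/s": lambda v: v * 1e6,
    }
for _frac in ("C_i", "C_a", "C_s"):
    _CONVERSIONS[_frac] = {
        "umol/mol": _IDENT,
        "mmol/mol": lambda v: v * 1000.0,
        "ppm": _IDENT,
    }

# Every unit string recognised anywhere (for distinguishing "unknown unit"
# from "known unit, wrong dimension").
_KNOWN_UNITS = frozenset(u for table in _CONVERSIONS.values() for u in table)


class StandardizeError(ValueError):
    """Raised when a varname map cannot be applied to a raw table."""


class UnitError(ValueError):
    """Raised for unknown or dimensionally incompatible unit declarations."""


def load_varname_map(dialect: str) -> dict[str, str]:
    """Load a built-in varname map (``"licor6400"`` or ``"licor6800"``).

    Maps canonical column names to the source column names used by that
    instrument dialect.  The maps are shipped as editable JSON config files.
    """
    try:
        text = resources.files("leafphys.dialects").joinpath(f"{dialect}.json").read_text()
    except FileNotFoundError:
        raise StandardizeError(f"unknown dialect {dialect!r}; built-ins: licor6400, licor6800")
    return json.loads(text)


def standardize_columns(raw_table: pd.DataFrame, varnames: Mapping[str, str]) -> pd.DataFrame:
    """Translate instrument column names into the canonical vocabulary.

    Parameters
    ----------
    raw_table
        The table as exported by the instrument.
    varnames
        Mapping from canonical name (e.g. ``"A_net"``) to the source column
        name (e.g. ``"PHOTO"``).  Every source column must exist in
        ``raw_table`` and no two canonical names may claim the same source.

    Returns
    -------
    DataFrame with canonical column names; unmapped raw columns are carried
    through untouched and listed in ``attrs["unmapped_columns"]``.
    """
    unknown = sorted(set(varnames) - CANONICAL_VOCABULARY)
    # Non-canonical keys are allowed only as group keys carried verbatim.
    missing = sorted(src for src in varnames.values() if src not in raw_table.columns)
    if missing:
        raise StandardizeError(f"source column(s) not in raw table: {', '.join(missing)}")
    sources = list(varnames.values())
    if len(sources) != len(set(sources)):
        dupes = sorted({s for s in sources if sources.count(s) > 1})
        raise StandardizeError(f"source column(s) mapped to multiple canonical names: {', '.join(dupes)}")
    rename = {src: canon for canon, src in varnames.items()}
    out = raw_table.rename(columns=rename)
    if out.columns.duplicated().any():
        dupes = sorted(out.columns[out.columns.duplicated()].unique())
        raise StandardizeError(f"duplicate canonical column(s) after renaming: {', '.join(map(str, dupes))}")
    out.attrs = dict(raw_table.attrs)
    out.attrs["varnames"] = dict(varnames)
    out.attrs["unmapped_columns"] = [c for c in out.columns if c not in varnames]
    if unknown:
        out.attrs["noncanonical_keys"] = unknown
    _sanity_warnings(out)
    return out


def invert_varname_map(varnames: Mapping[str, str]) -> dict[str, str]:
    """Return the canonical->source map inverted for round-tripping."""
    return {canon: src for canon, src in varnames.items()}


def _sanity_warnings(table: pd.DataFrame) -> None:
    if "T_leaf" in table:
        t = pd.to_numeric(table["T_leaf"], errors="coerce")
        if ((t < 263) | (t > 333)).any():
            warnings.warn(
                "T_leaf outside 263-333 K; check that temperatures are in Kelvin",
                stacklevel=3,
            )


def enforce_units(table: pd.DataFrame, declared_units: Mapping[str, str]) -> pd.DataFrame:
    """Convert declared source units to the canonical units, in place of ambiguity.

    ``declared_units`` maps canonical column names to the unit the values are
    currently in (e.g. ``{"T_leaf": "degC", "RH": "%"}``).  Columns whose unit
    is already recorded as canonical in ``table.attrs["units"]`` are left
    alone, which makes the operation idempotent.
    """
    out = table.copy()
    out.attrs = dict(table.attrs)
    units = dict(out.attrs.get("units", {}))
    for col, unit in declared_units.items():
        if col not in out.columns:
            raise UnitError(f"column {col!r} not present in table")
        accepted = _CONVERSIONS.get(col)
        if accepted is None:
            raise UnitError(f"no unit handling defined for column {col!r}")
        canonical = CANONICAL_UNITS[col]
        if units.get(col) == canonical:
            continue  # already converted
        if unit not in _KNOWN_UNITS:
            raise UnitError(f"unknown unit {unit!r} for column {col!r}")
        if unit not in accepted:
            raise UnitError(
                f"unit {unit!r} is dimensionally incompatible with column {col!r} "
                f"(canonical: {canonical})"
            )
        out[col] = accepted[unit](pd.to_numeric(out[col]))
        units[col] = canonical
    for col in out.columns:
        if col in CANONICAL_UNITS:
            units.setdefault(col, CANONICAL_UNITS[col])
    out.attrs["units"] = units
    _validate_ranges(out)
    return out


def _validate_ranges(table: pd.DataFrame) -> None:
    if "RH" in table:
        rh = pd.to_numeric(table["RH"], errors="coerce").dropna()
        if ((rh < 0) | (rh > 1)).any():
            raise UnitError("RH values outside [0, 1] after conversion; declare the source unit")
    if "PLC" in table:
        plc = pd.to_numeric(table["PLC"], errors="coerce").dropna()
        if ((plc < -1e-9) | (plc > 100 + 1e-9)).any():
            raise UnitError("PLC values outside [0, 100] after conversion")
    _sanity_warnings(table)


def read_table(
    path: str | Path,
    *,
    sep: str | None = None,
    header: int = 0,
    decimal: str = ".",
    comment: str | None = "#",
    varnames: Mapping[str, str] | str | None = None,
    declared_units: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV gas-exchange export and optionally standardize it.

    ``sep=None`` sniffs comma vs tab from the suffix.  ``varnames`` may be a
    mapping or the name of a built-in dialect.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, header=header, decimal=decimal, comment=comment)
    if isinstance(varnames, str):
        # a built-in dialect is a vocabulary: apply the entries the file has
        varnames = {c: s for c, s in load_varname_map(varnames).items()
                    if s in raw.columns}
    if varnames is not None:
        raw = standardize_columns(raw, varnames)
    if declared_units is not None:
        raw = enforce_units(raw, declared_units)
    return raw


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a canonical CSV plus a JSON sidecar with units and provenance."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {
        "units": table.attrs.get("units", {c: CANONICAL_UNITS[c] for c in table.columns if c in CANONICAL_UNITS}),
        "varnames": table.attrs.get("varnames"),
        "unmapped_columns": table.attrs.get("unmapped_columns"),
    }
    side_path = path.with_suffix(path.suffix + ".json")
    side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def drop_missing(table: pd.DataFrame, required: list[str]) -> pd.DataFrame:
    """Drop rows with missing values in ``required``, warning with the count."""
    mask = table[required].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} row(s) with missing {required}", stacklevel=2)
    out = table.loc[mask].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out
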