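"""Delimited-text readers and writers for the pipeline's tabular inputs.

Tables travel as pandas DataFrames validated against the typed invariants of
the records they carry. Readers accept comma- or tab-delimited text with a
header; column names are matched case-insensitively and through a
configurable alias map so that field-campaign headers (``Photo``, ``Cond``,
``Trmmol`` ...) bind without code changes.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A mandatory column is missing or the header cannot be bound."""


class ValidationError(ValueError):
    """One or more rows violate a typed invariant; message names them."""


#: default header aliases (lower-case alias -> canonical field)
DEFAULT_ALIASES: dict[str, str] = {
    "photo": "A",
    "cond": "gs",
    "trmmol": "E",
    "ci": "Ci",
    "ca": "Ca",
    "co2r": "Ca",
    "tair": "Tair",
    "tleaf": "Tleaf",
    "parin": "PAR",
    "par": "PAR",
    "q": "PAR",
    "rh_s": "RH",
    "rh": "RH",
    "genotype": "genotype_id",
    "geno": "genotype_id",
    "rep": "replicate",
}

GAS_EXCHANGE_REQUIRED = [
    "genotype_id", "replicate", "A", "gs", "E", "Ci", "Ca", "Tair", "Tleaf", "PAR",
]
GAS_EXCHANGE_OPTIONAL = ["RH"]

YIELD_REQUIRED = ["genotype_id", "year", "yield"]

WEATHER_REQUIRED = ["date", "tmax", "tmin", "rh"]
WEATHER_OPTIONAL = ["rain", "solar", "wind"]


def _bind_columns(
    df: pd.DataFrame,
    required: Iterable[str],
    optional: Iterable[str] = (),
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rename header columns onto canonical field names (case-insensitive)."""
    amap = dict(DEFAULT_ALIASES)
    if aliases:
        amap.update({k.lower(): v for k, v in aliases.items()})
    canonical = {c.lower(): c for c in [*required, *optional]}
    rename: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in canonical:
            rename[col] = canonical[key]
        elif key in amap:
            rename[col] = amap[key]
    out = df.rename(columns=rename)
    missing = [c for c in required if c not in out.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s) {missing}; found {list(df.columns)}"
        )
    return out


def _coerce_numeric(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    """Convert columns to float, reporting the first offending cell by row."""
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"data row {row + 1}"
            )
        df[col] = coerced
    return df


def _check(df: pd.DataFrame, mask: pd.Series, message: str) -> list[str]:
    """Collect violation messages (one per offending row) for a boolean mask."""
    rows = np.flatnonzero(mask.to_numpy())
    return [f"row {r + 1}: {message}" for r in rows]


def _raise_if_violations(violations: list[str], what: str) -> None:
    if violations:
        head = "; ".join(violations[:10])
        more = f" (+{len(violations) - 10} more)" if len(violations) > 10 else ""
        raise ValidationError(f"{what}: {head}{more}")


def read_delimited(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV file, sniffing the delimiter when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if "\t" in path.open().readline() else ","
    return pd.read_csv(path, sep=delimiter, float_precision="round_trip")


def validate_gas_exchange(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a bound gas-exchange table against the record invariants."""
    numeric = [c for c in GAS_EXCHANGE_REQUIRED if c != "genotype_id"]
    df = _coerce_numeric(df.copy(), numeric + ["RH"])
    v: list[str] = []
    v += _check(df, df["gs"] < 0, "gs must be >= 0")
    v += _check(df, df["E"] < 0, "E must be >= 0")
    v += _check(df, df["Ca"] <= 0, "Ca must be > 0")
    v += _check(df, df["Ci"] < 0, "Ci must be >= 0")
    v += _check(df, df["PAR"] < 0, "PAR must be >= 0")
    v += _check(df, df["replicate"] < 1, "replicate must be a positive integer")
    if "RH" in df.columns:
        present = df["RH"].notna()
        v += _check(df, present & ((df["RH"] < 0) | (df["RH"] > 100)),
                    "RH must lie in [0, 100]")
    _raise_if_violations(v, "gas-exchange table")
    return df


def read_gas_exchange_table(
    path: str | Path,
    delimiter: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format leaf gas-exchange table.

    Returns one row per instantaneous measurement with columns
    genotype_id, replicate, A, gs, E, Ci, Ca, Tair, Tleaf, PAR and,
    when present in the file, RH.
    """
    df = read_delimited(path, delimiter)
    df = _bind_columns(df, GAS_EXCHANGE_REQUIRED, GAS_EXCHANGE_OPTIONAL, aliases)
    return validate_gas_exchange(df)


def read_yield_table(
    path: str | Path,
    delimiter: str | None = None,
    aliases: Mapping[str, str] | None = None,
    require_two_years: bool = False,
) -> pd.DataFrame:
    """Read a genotype x year grain-yield table (kg ha⁻¹).

    Yields must be strictly positive (the stress index is built on geometric
    means). Genotypes observed in only one year are kept but flagged with a
    warning — the stress-index stage excludes them from the composite index.
    """
    df = read_delimited(path, delimiter)
    df = _bind_columns(df, YIELD_REQUIRED, aliases=aliases)
    df = _coerce_numeric(df, ["yield"])
    v = _check(df, df["yield"] <= 0, "yield must be > 0 (geometric mean)")
    _raise_if_violations(v, "yield table")
    years = df["year"].unique()
    if require_two_years and len(years) != 2:
        raise ValidationError(
            f"stress index needs exactly two year labels, found {sorted(map(str, years))}"
        )
    counts = df.groupby("genotype_id")["year"].nunique()
    lonely = counts[counts < len(years)].index.tolist()
    if lonely:
        warnings.warn(
            f"genotype(s) present in only one year: {lonely}", stacklevel=2
        )
    return df


def read_weather_table(
    path: str | Path,
    delimiter: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a daily weather table (date, tmax, tmin, rh[, rain, solar, wind])."""
    df = read_delimited(path, delimiter)
    df = _bind_columns(df, WEATHER_REQUIRED, WEATHER_OPTIONAL, aliases)
    df = _coerce_numeric(df, ["tmax", "tmin", "rh", "rain", "solar", "wind"])
    df["date"] = pd.to_datetime(df["date"])
    v: list[str] = []
    v += _check(df, df["tmax"] < df["tmin"], "tmax must be >= tmin")
    v += _check(df, (df["rh"] < 0) | (df["rh"] > 100), "rh must lie in [0, 100]")
    _raise_if_violations(v, "weather table")
    return df.sort_values("date").reset_index(drop=True)


def write_results_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> Path:
    """Write a result table as delimited text with full float precision.

    Floats are written with Python's shortest round-trippable repr, so
    re-reading the file reproduces every stored value exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"directory {path.parent} does not exist")
    df.to_csv(path, sep=delimiter, index=False)
    return path
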