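"""Measurement records and pH <-> hydrogen-ion concentration conversion.

Rumen acid status can be recorded either as pH or as hydrogen-ion
concentration [H+] in moles per litre, the two related by
pH = -log10([H+]).  Statistics in this package run on the [H+] scale by
default, because pH is a logarithm and arithmetic on it (means, linear
models) distorts the underlying chemistry; the pH scale remains
available everywhere through a flag.

A measurement table is a long-format :class:`pandas.DataFrame` with one
row per (animal, sampling day, post-prandial hour) and columns

    animal_id, day_label, day_offset, time_h, ph, h_conc

of which at least one of ``ph`` / ``h_conc`` must be supplied; the other
is filled in from the conversion.
"""

from __future__ import annotations

import numbers
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ph_to_h",
    "h_to_ph",
    "read_measurements",
    "validate_measurements",
    "write_measurements",
    "POSTPRANDIAL_HOURS",
]

#: Post-prandial sampling times (hours after morning feed delivery).
POSTPRANDIAL_HOURS: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0)

REQUIRED_COLUMNS = ("animal_id", "day_label", "time_h")

# Tolerance for agreement when a file supplies both scales.
_BOTH_SCALES_RTOL = 1e-6


def ph_to_h(ph):
    """Convert pH to hydrogen-ion concentration (moles per litre).

    Accepts scalars or arrays.  Strictly decreasing in pH.
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValidationError("pH values must be finite")
    out = np.power(10.0, -ph)
    return float(out) if out.ndim == 0 else out


def h_to_ph(h):
    """Convert hydrogen-ion concentration (moles per litre) to pH."""
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)) or np.any(h <= 0):
        raise ValidationError("[H+] values must be finite and > 0")
    out = -np.log10(h)
    return float(out) if out.ndim == 0 else out


_DEFAULT_DIALECT = {
    "animal_id": "animal_id",
    "day_label": "day_label",
    "day_offset": "day_offset",
    "time_h": "time_h",
    "ph": "ph",
    "h_conc": "h_conc",
}


def read_measurements(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
    allowed_hours: Iterable[float] | None = POSTPRANDIAL_HOURS,
) -> pd.DataFrame:
    """Read a delimited measurement file into a validated table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Optional mapping from canonical column names (``animal_id``,
        ``day_label``, ``day_offset``, ``time_h``, ``ph``, ``h_conc``)
        to the names used in the file, so external deposits can be
        ingested without editing.
    sep
        Field separator (default comma).
    allowed_hours
        Set of admissible post-prandial times; ``None`` disables the
        check.

    Returns
    -------
    pandas.DataFrame
        Canonical measurement table with both ``ph`` and ``h_conc``
        populated.
    """
    mapping = dict(_DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep=sep)
    rename = {v: k for k, v in mapping.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    return validate_measurements(df, allowed_hours=allowed_hours)


def validate_measurements(
    df: pd.DataFrame,
    allowed_hours: Iterable[float] | None = POSTPRANDIAL_HOURS,
) -> pd.DataFrame:
    """Validate a measurement table and fill the missing acid scale.

    Enforces: required columns present, numeric fields parseable,
    ``day_label`` a positive integer, unique (animal, day, hour)
    triplets, positive [H+], and — when both scales are supplied —
    agreement of ``h_conc`` with ``10**(-ph)`` within 1e-6 relative
    (disagreeing rows are rejected rather than silently preferring one
    scale).

    Raises
    ------
    ValidationError
        With row-indexed messages naming every offending row.
    """
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if "ph" not in df.columns and "h_conc" not in df.columns:
        raise ValidationError("at least one of 'ph' or 'h_conc' columns is required")
    for col in ("ph", "h_conc", "day_offset"):
        if col not in df.columns:
            df[col] = np.nan

    problems: list[str] = []

    for col in ("day_label", "time_h", "ph", "h_conc", "day_offset"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for idx in df.index[bad]:
            problems.append(f"row {idx}: unparseable numeric in '{col}': {df.at[idx, col]!r}")
        df[col] = coerced

    both = df["ph"].notna() & df["h_conc"].notna()
    if both.any():
        expected = np.power(10.0, -df.loc[both, "ph"])
        rel = np.abs(df.loc[both, "h_conc"] - expected) / expected
        for idx in rel.index[rel > _BOTH_SCALES_RTOL]:
            problems.append(
                f"row {idx}: ph and h_conc disagree "
                f"(ph={df.at[idx, 'ph']}, h_conc={df.at[idx, 'h_conc']})"
            )

    neither = df["ph"].isna() & df["h_conc"].isna()
    for idx in df.index[neither]:
        problems.append(f"row {idx}: neither ph nor h_conc given")

    nonpos = df["h_conc"].notna() & (df["h_conc"] <= 0)
    for idx in df.index[nonpos]:
        problems.append(f"row {idx}: h_conc must be > 0, got {df.at[idx, 'h_conc']}")

    with np.errstate(invalid="ignore"):
        bad_label = df["day_label"].notna() & (
            (df["day_label"] < 1) | (df["day_label"] != np.floor(df["day_label"]))
        )
    for idx in df.index[bad_label]:
        problems.append(f"row {idx}: day_label must be a positive integer")

    if allowed_hours is not None:
        allowed = set(float(h) for h in allowed_hours)
        bad_t = df["time_h"].notna() & ~df["time_h"].isin(allowed)
        for idx in df.index[bad_t]:
            problems.append(
                f"row {idx}: time_h={df.at[idx, 'time_h']} not in {sorted(allowed)}"
            )

    dup = df.duplicated(subset=["animal_id", "day_label", "time_h"], keep=False)
    if dup.any():
        trips = df.loc[dup, ["animal_id", "day_label", "time_h"]].drop_duplicates()
        for _, t in trips.iterrows():
            problems.append(
                "duplicate triplet (animal_id="
                f"{t['animal_id']}, day_label={t['day_label']}, time_h={t['time_h']})"
            )

    if problems:
        raise ValidationError("invalid measurement table:\n  " + "\n  ".join(problems))

    # fill the missing scale from the other
    fill_h = df["h_conc"].isna()
    df.loc[fill_h, "h_conc"] = np.power(10.0, -df.loc[fill_h, "ph"])
    fill_ph = df["ph"].isna()
    df.loc[fill_ph, "ph"] = -np.log10(df.loc[fill_ph, "h_conc"])

    df["day_label"] = df["day_label"].astype(int)
    return df.reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement table in the canonical CSV dialect."""
    cols = [c for c in ("animal_id", "day_label", "day_offset", "time_h", "ph", "h_conc")
            if c in df.columns]
    df.to_csv(path, columns=cols, index=False)
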