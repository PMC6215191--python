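"""Measurement-table I/O.

One fixed CSV schema carries every observation of the validation study:

    analyte_id,sample_type,nominal_conc,day,replicate,response,youden_combo

``sample_type`` is one of ``solvent_std``, ``matrix_std``, ``blank``,
``spike``, ``youden``; ``youden_combo`` (C1..C8) is nonempty exactly for
``youden`` rows; ``nominal_conc`` is 0 for blanks.  UTF-8, "." decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError

MEASUREMENT_COLUMNS = (
    "analyte_id",
    "sample_type",
    "nominal_conc",
    "day",
    "replicate",
    "response",
    "youden_combo",
)

SAMPLE_TYPES = ("solvent_std", "matrix_std", "blank", "spike", "youden")


def write_measurements(records: pd.DataFrame, path) -> None:
    """Write a measurement table to CSV (lossless float round-trip)."""
    df = records.loc[:, list(MEASUREMENT_COLUMNS)]
    df.to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement CSV.

    Raises :class:`ParseError` naming the offending 1-based line number for
    malformed rows, and for an empty file or wrong header.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty measurement table") from None
    if raw.empty and raw.columns.size == 0:
        raise ParseError(f"{path}: empty measurement table")
    if tuple(raw.columns) != MEASUREMENT_COLUMNS:
        raise ParseError(
            f"{path}: expected header {','.join(MEASUREMENT_COLUMNS)}, "
            f"got {','.join(raw.columns)}"
        )
    if len(raw) == 0:
        raise ParseError(f"{path}: no data rows")

    def _numeric(col: str, kind):
        try:
            return raw[col].astype(kind)
        except ValueError:
            # locate the first bad row for a precise message
            for i, v in enumerate(raw[col]):
                try:
                    kind(v)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric {col} {v!r}", line=i + 2
                    ) from None
            raise  # pragma: no cover

    df = pd.DataFrame(
        {
            "analyte_id": raw["analyte_id"],
            "sample_type": raw["sample_type"],
            "nominal_conc": _numeric("nominal_conc", float),
            "day": _numeric("day", int),
            "replicate": _numeric("replicate", int),
            "response": _numeric("response", float),
            "youden_combo": raw["youden_combo"],
        }
    )
    bad_type = ~df["sample_type"].isin(SAMPLE_TYPES)
    if bad_type.any():
        i = int(np.flatnonzero(bad_type)[0])
        raise ParseError(
            f"{path}: unknown sample_type {df['sample_type'].iloc[i]!r}", line=i + 2
        )
    if not np.isfinite(df["response"]).all():
        i = int(np.flatnonzero(~np.isfinite(df["response"]))[0])
        raise ParseError(f"{path}: non-finite response", line=i + 2)
    combo_mismatch = (df["youden_combo"] != "") != (df["sample_type"] == "youden")
    if combo_mismatch.any():
        i = int(np.flatnonzero(combo_mismatch)[0])
        raise ParseError(
            f"{path}: youden_combo must be nonempty exactly for youden rows",
            line=i + 2,
        )
    return df
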