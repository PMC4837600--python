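"""Reading wide-format plate tables and writing per-well summary tables.

The plate format is the convention used by plate-reader exports and
spreadsheet hand-offs: one header row, one time column (named "time" by
default, matched case-insensitively), and one column of readings per
well.  Comma and tab delimiters are auto-detected; anything else must be
passed explicitly — silent mis-parsing is worse than an error.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, PlateParseError
from .fitting import GrowthFitResult
from .preprocess import GrowthSample

__all__ = ["PlateTable", "read_plate_table", "write_summary", "SUMMARY_COLUMNS"]

#: Column order of the per-well summary CSV, fixed.
SUMMARY_COLUMNS = [
    "well",
    "K",
    "K_se",
    "N0",
    "N0_se",
    "r",
    "r_se",
    "sigma",
    "dof",
    "t_mid",
    "t_dt",
    "auc_l",
    "auc_e",
    "converged",
    "note",
]


@dataclass(frozen=True)
class PlateTable:
    """A plate: one shared time vector plus named per-well reading vectors.

    ``wells`` preserves file column order; ``blank_label`` optionally
    names a media-only well to use for blank-series correction.
    """

    times: np.ndarray
    wells: dict[str, np.ndarray]
    blank_label: str | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise InvalidInputError("times must be a non-empty 1-d vector")
        if not np.all(np.isfinite(times)):
            raise InvalidInputError("times must be finite")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        if not self.wells:
            raise InvalidInputError("plate must contain at least one well")
        checked: dict[str, np.ndarray] = {}
        for label, readings in self.wells.items():
            arr = np.asarray(readings, dtype=float)
            if arr.shape != times.shape:
                raise InvalidInputError(
                    f"well {label!r} has {arr.size} readings but {times.size} time points"
                )
            checked[label] = arr
        object.__setattr__(self, "wells", checked)
        if self.blank_label is not None and self.blank_label not in checked:
            raise InvalidInputError(f"blank well {self.blank_label!r} not in plate")

    @property
    def well_labels(self) -> list[str]:
        return list(self.wells)

    def sample(self, label: str) -> GrowthSample:
        """Extract one well as a GrowthSample (raw, uncorrected)."""
        if label not in self.wells:
            raise InvalidInputError(f"no well named {label!r}")
        return GrowthSample(well_id=label, times=self.times, raw=self.wells[label])

    def __len__(self) -> int:
        return len(self.wells)


def _detect_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    if "\t" in header and "," not in header:
        return "\t"
    if "," in header:
        return ","
    raise PlateParseError(
        f"{path}: could not detect a comma or tab delimiter in the header; "
        "pass delimiter explicitly"
    )


def read_plate_table(
    path,
    time_column: str = "time",
    delimiter: str | None = None,
) -> PlateTable:
    """Read a wide-format delimited plate table.

    Parameters
    ----------
    path : path-like
        CSV or TSV file with a header row.
    time_column : str
        Name of the time column, matched case-insensitively
        (default ``"time"``).
    delimiter : str, optional
        Field delimiter; auto-detected between comma and tab when omitted.

    Returns
    -------
    PlateTable
        Wells in file column order, rows sorted ascending by time.

    Raises
    ------
    PlateParseError
        Missing time column, non-numeric cell (named by row and column),
        duplicate well label, duplicate time value, or ragged rows.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    with open(path, newline="") as fh:
        raw_header = next(csv.reader(fh, delimiter=delimiter))
    seen: set[str] = set()
    for name in raw_header:
        if name in seen:
            raise PlateParseError(f"{path}: duplicate well label {name!r}")
        seen.add(name)
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise PlateParseError(f"{path}: {exc}") from exc
    matches = [c for c in df.columns if c.strip().lower() == time_column.strip().lower()]
    if not matches:
        raise PlateParseError(
            f"{path}: no column named {time_column!r} (case-insensitive) in header "
            f"{list(df.columns)}"
        )
    time_col = matches[0]
    well_cols = [c for c in df.columns if c != time_col]
    if not well_cols:
        raise PlateParseError(f"{path}: no well columns besides the time column")

    numeric = pd.DataFrame(index=df.index)
    for col in [time_col, *well_cols]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            cell = df[col].iloc[row]
            raise PlateParseError(
                f"{path}: non-numeric or missing value {cell!r} at data row "
                f"{row + 1}, column {col!r}"
            )
        # numpy's string parser is correctly rounded (pd.to_numeric is not),
        # which the bit-exact summary round-trip relies on
        numeric[col] = df[col].to_numpy(dtype=float)
    times = numeric[time_col].to_numpy()
    if np.unique(times).size != times.size:
        raise PlateParseError(f"{path}: duplicate time values in column {time_col!r}")
    order = np.argsort(times, kind="stable")
    numeric = numeric.iloc[order]
    return PlateTable(
        times=numeric[time_col].to_numpy(),
        wells={c: numeric[c].to_numpy() for c in well_cols},
    )


def _fmt(x: float | int | None) -> str:
    if x is None:
        return ""
    if isinstance(x, int):
        return str(x)
    if math.isnan(x):
        return "nan"
    return format(x, ".17g")


def write_summary(results, path) -> None:
    """Write per-well fit results as a summary CSV.

    One row per well, columns in :data:`SUMMARY_COLUMNS` order, floats at
    17 significant digits so a read-back reproduces every value
    bit-for-bit.  Non-converged wells have empty metric cells and their
    diagnostic note populated.
    """
    results = list(results)
    if not results:
        raise InvalidInputError("no results to write")
    rows = []
    for res in results:
        if not isinstance(res, GrowthFitResult):
            raise InvalidInputError(f"expected GrowthFitResult, got {type(res).__name__}")
        p = res.params
        rows.append(
            {
                "well": res.well_id,
                "K": _fmt(p.K if p else None),
                "K_se": _fmt(res.stderr_K),
                "N0": _fmt(p.N0 if p else None),
                "N0_se": _fmt(res.stderr_N0),
                "r": _fmt(p.r if p else None),
                "r_se": _fmt(res.stderr_r),
                "sigma": _fmt(res.sigma),
                "dof": _fmt(res.dof),
                "t_mid": _fmt(res.t_mid),
                "t_dt": _fmt(res.t_dt),
                "auc_l": _fmt(res.auc_l),
                "auc_e": _fmt(res.auc_e),
                "converged": "true" if res.converged else "false",
                "note": res.note,
            }
        )
    try:
        pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc
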