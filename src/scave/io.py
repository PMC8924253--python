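"""Readers and writers for the instrument CSV exports and result tables.

Two CSV dialects are supported, reflecting the German-market acquisition
software: ``"intl"`` (comma separator, dot decimal, ISO dates) and ``"de"``
(semicolon separator, comma decimal, DD.MM.YYYY dates).  ``dialect="auto"``
sniffs the header line.  Readers are strict by default (any malformed row
raises :class:`RowError` with its line number); ``lenient=True`` skips bad
rows with a logged warning instead.
"""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AntennaEvent,
    AssignmentResult,
    Direction,
    HourlySummary,
    WheelMinuteRecord,
)

logger = logging.getLogger(__name__)

DIALECTS = {
    "intl": {"sep": ",", "decimal": ".", "date_fmt": "%Y-%m-%d"},
    "de": {"sep": ";", "decimal": ",", "date_fmt": "%d.%m.%Y"},
}

#: canonical SCA column names, keyed by their case-folded form
_SCA_COLUMNS = {
    "date": "date",
    "time": "time",
    "cage": "cage",
    "animal": "animal",
    "antenna": "antenna",
    "enter": "enter",  # the export uses both "Enter" and "ENTER"
    "ms": "ms",
}

_VE_COLUMNS = {
    "right": "rot_right",
    "left": "rot_left",
    "sum r+l": "rot_total",
    "sum r + l": "rot_total",
    "sum time": "active_seconds",
    "sum runs": "run_count",
    "maxspeed": "max_speed_rpm",
    "avgspeed": "avg_speed_rpm",
    "maxlen": "max_run_len_s",
}


class SchemaError(ValueError):
    """A mandatory column is missing or the header is unrecognisable."""


class RowError(ValueError):
    """A data row could not be parsed (strict mode)."""


def detect_dialect(path: Union[str, Path]) -> str:
    """Sniff the dialect from the header line (semicolon => "de")."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "de" if ";" in header else "intl"


def _resolve_dialect(path, dialect: str) -> str:
    if dialect == "auto":
        return detect_dialect(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use auto, intl or de")
    return dialect


def _parse_dates(raw: pd.Series) -> pd.Series:
    """Accept both DD.MM.YYYY and YYYY-MM-DD date columns."""
    s = raw.str.strip()
    out = pd.to_datetime(s, format="%d.%m.%Y", errors="coerce")
    iso = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    return out.fillna(iso)


def _parse_times(raw: pd.Series) -> pd.Series:
    """HH:MM:SS with optional fractional seconds (dot or comma)."""
    s = raw.str.strip().str.replace(",", ".", regex=False)
    out = pd.to_datetime(s, format="%H:%M:%S.%f", errors="coerce")
    plain = pd.to_datetime(s, format="%H:%M:%S", errors="coerce")
    return out.fillna(plain)


def _read_frame(path, dialect: str) -> tuple[pd.DataFrame, str]:
    dialect = _resolve_dialect(path, dialect)
    opts = DIALECTS[dialect]
    df = pd.read_csv(
        path, sep=opts["sep"], dtype=str, skipinitialspace=True, encoding="utf-8"
    )
    df.columns = [str(c).strip().casefold() for c in df.columns]
    return df, dialect


def _bad_rows(mask: pd.Series, what: str, lenient: bool) -> pd.Series:
    """Handle rows failing ``mask``; returns the keep-mask."""
    if mask.all():
        return mask
    lines = (np.flatnonzero(~mask.to_numpy()) + 2).tolist()  # header = line 1
    if not lenient:
        raise RowError(f"unparseable {what} at line {lines[0]} (and possibly others)")
    logger.warning("skipping %d row(s) with unparseable %s: lines %s",
                   len(lines), what, lines[:20])
    return mask


def read_sca(
    path: Union[str, Path],
    dialect: str = "auto",
    lenient: bool = False,
) -> list[AntennaEvent]:
    """Read an RFID-platform (SCA) export into ordered antenna events.

    Rows keep file order; timestamps are assembled from the separate Date
    and Time columns at millisecond resolution.  Rows from multiple cages
    are retained with their cage id.
    """
    df, _ = _read_frame(path, dialect)
    missing = [c for c in _SCA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"SCA file missing column(s): {', '.join(sorted(missing))}")
    if df.empty:
        return []

    dates = _parse_dates(df["date"].astype(str))
    times = _parse_times(df["time"].astype(str))
    antenna = pd.to_numeric(df["antenna"], errors="coerce")
    direction = df["enter"].astype(str).str.strip().str.upper()

    keep = _bad_rows(dates.notna() & times.notna(), "timestamp", lenient)
    keep = _bad_rows(
        keep & antenna.isin([1, 2, 3, 4, 5, 6]), "antenna label", lenient
    ) & keep
    keep = _bad_rows(keep & direction.isin(["IN", "OUT"]), "direction", lenient) & keep

    ts = dates + (times - times.dt.normalize())
    ms = pd.to_numeric(df["ms"], errors="coerce")

    events: list[AntennaEvent] = []
    for i in np.flatnonzero(keep.to_numpy()):
        d = Direction(direction.iat[i])
        dwell = None
        if d is Direction.OUT and not np.isnan(ms.iat[i]):
            dwell = int(ms.iat[i])
        events.append(
            AntennaEvent(
                timestamp=ts.iat[i].to_pydatetime(),
                cage_id=str(df["cage"].iat[i]).strip(),
                animal_id=str(df["animal"].iat[i]).strip(),
                antenna=int(antenna.iat[i]),
                direction=d,
                dwell_ms=dwell,
            )
        )
    return events


def _parse_minute(raw: pd.Series) -> pd.Series:
    s = raw.str.strip()
    out = None
    for fmt in ("%Y-%m-%d %H:%M:%S", "%Y-%m-%d %H:%M",
                "%d.%m.%Y %H:%M:%S", "%d.%m.%Y %H:%M"):
        parsed = pd.to_datetime(s, format=fmt, errors="coerce")
        out = parsed if out is None else out.fillna(parsed)
    return out


def read_ve(
    path: Union[str, Path],
    dialect: str = "auto",
    lenient: bool = False,
) -> list[WheelMinuteRecord]:
    """Read a running-wheel (VE) export into per-minute records.

    The minute timestamp is taken from the first column (any datetime-like
    name and format is accepted); minutes must be strictly increasing.
    """
    df, d = _read_frame(path, dialect)
    missing = sorted(
        {"right", "left", "sum time", "sum runs", "maxspeed", "avgspeed", "maxlen"}
        - set(df.columns)
    )
    if "sum r+l" not in df.columns and "sum r + l" not in df.columns:
        missing.append("sum r+l")
    if missing:
        raise SchemaError(f"VE file missing column(s): {', '.join(missing)}")
    if df.empty:
        return []

    known = set(_VE_COLUMNS)
    time_cols = [c for c in df.columns if c not in known]
    if not time_cols:
        raise SchemaError("VE file has no timestamp column")
    minutes = _parse_minute(df[time_cols[0]].astype(str))
    keep = _bad_rows(minutes.notna(), "minute timestamp", lenient)

    decimal = DIALECTS[d]["decimal"]

    def num(col: str) -> pd.Series:
        s = df[col].astype(str).str.strip()
        if decimal == ",":
            s = s.str.replace(",", ".", regex=False)
        return pd.to_numeric(s, errors="coerce")

    cols = {canon: num(c) for c, canon in _VE_COLUMNS.items() if c in df.columns}
    for canon, series in cols.items():
        keep = _bad_rows(keep & series.notna(), canon, lenient) & keep

    records: list[WheelMinuteRecord] = []
    prev = None
    for i in np.flatnonzero(keep.to_numpy()):
        m = minutes.iat[i].to_pydatetime().replace(second=0, microsecond=0)
        if prev is not None and m <= prev:
            if lenient:
                logger.warning("non-increasing minute at line %d skipped", i + 2)
                continue
            raise RowError(f"minutes not strictly increasing at line {i + 2}")
        prev = m
        records.append(
            WheelMinuteRecord(
                minute_start=m,
                rot_right=int(cols["rot_right"].iat[i]),
                rot_left=int(cols["rot_left"].iat[i]),
                rot_total=int(cols["rot_total"].iat[i]),
                active_seconds=float(cols["active_seconds"].iat[i]),
                run_count=int(cols["run_count"].iat[i]),
                max_speed_rpm=float(cols["max_speed_rpm"].iat[i]),
                avg_speed_rpm=float(cols["avg_speed_rpm"].iat[i]),
                max_run_len_s=float(cols["max_run_len_s"].iat[i]),
            )
        )
    return records


def _fmt_time_ms(ts: datetime) -> str:
    return f"{ts:%H:%M:%S}.{ts.microsecond // 1000:03d}"


def _fmt_float(x: float, decimal: str) -> str:
    s = repr(float(x)) if x != int(x) else str(int(x))
    return s.replace(".", ",") if decimal == "," else s


def write_sca(
    events: Iterable[AntennaEvent], path: Union[str, Path], dialect: str = "intl"
) -> None:
    """Write antenna events in the SCA export layout (re-readable identically)."""
    if dialect not in DIALECTS:
        raise ValueError(f"writer requires an explicit dialect, got {dialect!r}")
    opts = DIALECTS[dialect]
    rows = [
        {
            "Date": e.timestamp.strftime(opts["date_fmt"]),
            "Time": _fmt_time_ms(e.timestamp),
            "CAGE": e.cage_id,
            "ANIMAL": e.animal_id,
            "Antenna": e.antenna,
            "Enter": e.direction.value,
            "MS": "" if e.dwell_ms is None else e.dwell_ms,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows, columns=["Date", "Time", "CAGE", "ANIMAL", "Antenna", "Enter", "MS"]
    )
    df.to_csv(path, sep=opts["sep"], index=False, lineterminator="\n")


def write_ve(
    records: Iterable[WheelMinuteRecord], path: Union[str, Path], dialect: str = "intl"
) -> None:
    """Write per-minute wheel records in the VE export layout."""
    if dialect not in DIALECTS:
        raise ValueError(f"writer requires an explicit dialect, got {dialect!r}")
    opts = DIALECTS[dialect]
    dec = opts["decimal"]
    rows = [
        {
            "Time": r.minute_start.strftime(opts["date_fmt"] + " %H:%M"),
            "Right": r.rot_right,
            "Left": r.rot_left,
            "Sum R+L": r.rot_total,
            "Sum Time": _fmt_float(r.active_seconds, dec),
            "Sum Runs": r.run_count,
            "MaxSpeed": _fmt_float(r.max_speed_rpm, dec),
            "AvgSpeed": _fmt_float(r.avg_speed_rpm, dec),
            "MaxLen": _fmt_float(r.max_run_len_s, dec),
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["Time", "Right", "Left", "Sum R+L", "Sum Time", "Sum Runs",
                 "MaxSpeed", "AvgSpeed", "MaxLen"],
    )
    df.to_csv(path, sep=opts["sep"], index=False, lineterminator="\n")


ResultRows = Union[Sequence[AssignmentResult], Sequence[HourlySummary], pd.DataFrame]


def write_results(results: ResultRows, path: Union[str, Path]) -> None:
    """Write result tables as tidy CSV.

    Accepts a sequence of :class:`AssignmentResult` (one row per wheel-active
    minute), a sequence of :class:`HourlySummary` (one row per animal-hour),
    or any DataFrame, which is written as-is.
    """
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False, lineterminator="\n")
        return
    results = list(results)
    if results and isinstance(results[0], AssignmentResult):
        df = pd.DataFrame(
            {
                "minute_start": [r.minute_start for r in results],
                "rot_total": [r.rot_total for r in results],
                "credited": [";".join(sorted(r.credited)) for r in results],
                "status": [r.status.value for r in results],
                "reason": [r.reason.value for r in results],
            }
        )
    else:
        df = pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in results],
                "hour_start": [r.hour_start for r in results],
                "field_changes": [r.field_changes for r in results],
                "rotations_credited": [r.rotations_credited for r in results],
                "wheel_active_seconds": [r.wheel_active_seconds for r in results],
            }
        )
    df.to_csv(path, index=False, lineterminator="\n")
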