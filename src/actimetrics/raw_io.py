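"""Reading and writing the raw-accelerometry CSV dialect and metric CSVs.

The interchange format is the ActiLife-style RAW CSV export: a fixed-size
metadata header block, one column-name line, then one ``x,y,z`` row per
sample in g.  The dialect (header size, column order, optional timestamp
column, sample rate) is declared explicitly, never sniffed; in particular the
sample rate is taken from the header's "... at NN Hz" line only when the
dialect does not state it, and a missing rate is an error rather than a
guess.

Epochs everywhere in the package are labelled by their start time, half-open
[t, t + H).  Timestamps in files are informational; the sample index plus the
declared rate is authoritative (this avoids timezone/DST ambiguity in long
recordings).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .core_metrics import DEFAULT_START, Metric, MetricSeries, TriaxialRecording

__all__ = [
    "RawCsvDialect",
    "read_raw_csv",
    "write_raw_csv",
    "read_metric_csv",
    "write_metric_csv",
]

_HZ_RE = re.compile(r"(\d+(?:\.\d+)?)\s*Hz", re.IGNORECASE)
_START_RE = re.compile(r"Start (?:Date|Time)\s+(.+)")


@dataclass(frozen=True)
class RawCsvDialect:
    """Declared layout of a raw tri-axial CSV file.

    ``header_lines`` metadata lines are skipped (10 for ActiLife RAW
    exports), then one line of column names, then the data.  ``sample_rate``
    of ``None`` means "parse the '... NN Hz' phrase from the header";
    ``column_order`` maps file columns onto device axes.
    """

    header_lines: int = 10
    column_order: tuple[str, str, str] = ("x", "y", "z")
    has_timestamp_column: bool = False
    sample_rate: int | None = None

    def __post_init__(self) -> None:
        if self.header_lines < 0:
            raise ValueError("header_lines must be non-negative")
        if sorted(self.column_order) != ["x", "y", "z"]:
            raise ValueError("column_order must be a permutation of ('x', 'y', 'z')")
        if self.sample_rate is not None and int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be positive")


def _header_sample_rate(header: list[str]) -> int | None:
    for line in header:
        m = _HZ_RE.search(line)
        if m:
            return int(float(m.group(1)))
    return None


def _header_start_time(header: list[str]) -> datetime | None:
    date = time = None
    for line in header:
        if line.startswith("Start Time"):
            time = line.split("Start Time", 1)[1].strip()
        elif line.startswith("Start Date"):
            date = line.split("Start Date", 1)[1].strip()
    if date and time:
        try:
            return datetime.strptime(f"{date} {time}", "%m/%d/%Y %H:%M:%S")
        except ValueError:
            return None
    return None


def read_raw_csv(
    path: str | Path, dialect: RawCsvDialect = RawCsvDialect()
) -> TriaxialRecording:
    """Parse a raw tri-axial CSV into a recording, in g.

    Malformed (non-numeric or wrong-width) data rows raise a ``ValueError``
    citing the 1-based file line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = [fh.readline().rstrip("\n") for _ in range(dialect.header_lines)]
        colnames_line = fh.readline().rstrip("\n")
        data_start_line = dialect.header_lines + 2  # 1-based line of first data row
        if not colnames_line:
            raise ValueError(f"{path}: no column-name line after the header block")
        n_named = len(colnames_line.split(","))
        n_expected = 3 + (1 if dialect.has_timestamp_column else 0)
        if n_named < n_expected:
            raise ValueError(
                f"{path}: expected {n_expected} columns, found {n_named} "
                f"({colnames_line!r})"
            )
        try:
            body = pd.read_csv(fh, header=None, dtype=str, skip_blank_lines=False)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty data section") from None
    if body.empty:
        raise ValueError(f"{path}: empty data section")
    if body.shape[1] != n_expected:
        raise ValueError(
            f"{path}: data rows have {body.shape[1]} columns, expected {n_expected}"
        )
    if dialect.has_timestamp_column:
        body = body.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | body.isna().any(axis=1)
    if bad.any():
        bad_idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric or missing value at line "
            f"{data_start_line + bad_idx} (data row {bad_idx + 1})"
        )
    # numpy's string conversion is correctly rounded, so a write/read round
    # trip at 17 significant digits reproduces the samples bit-exactly
    values = body.to_numpy(dtype=float)
    order = [dialect.column_order.index(ax) for ax in ("x", "y", "z")]
    values = values[:, order]

    rate = dialect.sample_rate or _header_sample_rate(header)
    if rate is None:
        raise ValueError(
            f"{path}: sample rate not declared in dialect and not found in header"
        )
    start = _header_start_time(header) or DEFAULT_START
    return TriaxialRecording(values, int(rate), start)


def write_raw_csv(
    rec: TriaxialRecording,
    path: str | Path,
    dialect: RawCsvDialect = RawCsvDialect(),
) -> None:
    """Write a recording as an ActiLife-style RAW CSV.

    Values are written with 17 significant digits so a write/read round trip
    reproduces the samples exactly.
    """
    path = Path(path)
    header = [
        "------------ Data File Created By actimetrics "
        f"RAW CSV export at {rec.sample_rate} Hz ------------",
        "Serial Number: SYNTHETIC",
        f"Start Time {rec.start_time.strftime('%H:%M:%S')}",
        f"Start Date {rec.start_time.strftime('%m/%d/%Y')}",
        "Epoch Period (hh:mm:ss) 00:00:00",
        "Download Time 00:00:00",
        "Download Date 01/01/2000",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.0     Mode = 12",
        "--------------------------------------------------",
    ]
    header = header[: dialect.header_lines]
    while len(header) < dialect.header_lines:
        header.append("-")
    name_of = {"x": "Accelerometer X", "y": "Accelerometer Y", "z": "Accelerometer Z"}
    colnames = [name_of[ax] for ax in dialect.column_order]
    col_idx = [("x", "y", "z").index(ax) for ax in dialect.column_order]
    data = rec.samples[:, col_idx]
    if dialect.has_timestamp_column:
        colnames = ["Timestamp"] + colnames
    with path.open("w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write(",".join(colnames) + "\n")
        if dialect.has_timestamp_column:
            step = 1.0 / rec.sample_rate
            for i, row in enumerate(data):
                ts = rec.start_time.timestamp() + i * step
                fh.write(f"{ts:.6f}," + ",".join(f"{v:.17g}" for v in row) + "\n")
        else:
            np.savetxt(fh, data, fmt="%.17g", delimiter=",")


_METRIC_COL_RE = re.compile(r"^(AI_ABS|AI_REL|ENMO)\[epoch=(\d+)s\]$")


def write_metric_csv(series: MetricSeries, path: str | Path) -> None:
    """Write a metric series as CSV: one header row naming the metric and
    epoch length, then (epoch_start_time, value) rows at full float
    precision."""
    path = Path(path)
    value_col = f"{series.metric_name.value}[epoch={series.epoch_length_seconds}s]"
    with path.open("w") as fh:
        fh.write(f"epoch_start_time,{value_col}\n")
        for t, v in zip(series.epoch_start_times, series.values):
            fh.write(f"{t.isoformat()},{v:.17g}\n")


def read_metric_csv(path: str | Path) -> MetricSeries:
    """Read a metric CSV written by :func:`write_metric_csv`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: metric CSV must have exactly two columns")
    m = _METRIC_COL_RE.match(df.columns[1])
    if not m:
        raise ValueError(
            f"{path}: value column {df.columns[1]!r} does not declare metric/epoch"
        )
    metric, epoch = Metric(m.group(1)), int(m.group(2))
    if df.empty:
        return MetricSeries(metric, epoch, np.array([]))
    start = datetime.fromisoformat(str(df.iloc[0, 0]))
    return MetricSeries(metric, epoch, df.iloc[:, 1].to_numpy(dtype=float), start)
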