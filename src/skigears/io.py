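"""Data model and CSV readers/writers for accelerometer streams and labels.

A stream is a timestamped triaxial acceleration recording from a
chest-worn sensor: the x axis is lateral, the y axis vertical, and the z
axis horizontal.  Values are specific force in m/s² (gravity included,
as raw phone accelerometers report).  Timestamps are seconds from an
arbitrary origin; only relative timing matters downstream, and sampling
may be irregular.

File formats (comma separator, ``.`` decimal, UTF-8, required header):

* stream CSV: ``time_s,ax,ay,az``
* label CSV:  ``start_s,end_s,gear``
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .gears import check_gear

STREAM_COLUMNS = ("time_s", "ax", "ay", "az")
LABEL_COLUMNS = ("start_s", "end_s", "gear")

_AXES = ("ax", "ay", "az")


@dataclass
class AccelerometerStream:
    """Timestamped triaxial acceleration samples, possibly irregularly sampled.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    ax, ay, az : arrays of float
        Acceleration in m/s² along the lateral, vertical and horizontal
        axes; same length as ``t``.
    meta : dict
        Free-form provenance (device, nominal rate, generator seed, ...).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        for name in _AXES:
            if getattr(self, name).shape != (n,):
                raise ValidationError(
                    f"channel {name!r} has length "
                    f"{getattr(self, name).size}, expected {n}"
                )
        for name, arr in (("time_s", self.t),) + tuple(
            (a, getattr(self, a)) for a in _AXES
        ):
            if arr.size and not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0]) + 1
                raise ValidationError(
                    f"non-finite value in column {name!r} at row {row}"
                )
        if n > 1 and not np.all(np.diff(self.t) > 0):
            row = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 2
            raise ValidationError(
                f"timestamps must be strictly increasing: violation at row {row}"
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Time span in seconds (0 for streams with <2 samples)."""
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    @property
    def values(self) -> np.ndarray:
        """(n, 3) array of the three acceleration channels."""
        return np.column_stack([self.ax, self.ay, self.az])

    def channel(self, name: str) -> np.ndarray:
        """One channel by name: ``x``/``y``/``z`` or ``magnitude``."""
        if name in ("x", "ax"):
            return self.ax
        if name in ("y", "ay"):
            return self.ay
        if name in ("z", "az"):
            return self.az
        if name == "magnitude":
            return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)
        raise ValidationError(f"unknown channel {name!r}")

    def shifted(self, dt: float) -> "AccelerometerStream":
        """Same stream with all timestamps shifted by *dt* seconds."""
        return AccelerometerStream(self.t + dt, self.ax, self.ay, self.az,
                                   dict(self.meta))


@dataclass(frozen=True)
class LabelInterval:
    """Ground-truth gear over a half-open time interval [start, end)."""

    start: float
    end: float
    gear: str

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise ValidationError(
                f"interval end ({self.end}) must exceed start ({self.start})"
            )
        check_gear(self.gear)

    @property
    def duration(self) -> float:
        return self.end - self.start


def _read_csv(path: str | os.PathLike, columns: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, skipinitialspace=True, encoding="utf-8")
    df.columns = [str(c).strip() for c in df.columns]
    if tuple(df.columns) != tuple(columns):
        raise FormatError(
            f"{path}: expected columns {','.join(columns)}, "
            f"found {','.join(df.columns)}"
        )
    return df


def read_stream(path: str | os.PathLike) -> AccelerometerStream:
    """Read a stream CSV (header ``time_s,ax,ay,az``) into a validated stream.

    Raises :class:`FormatError` for wrong columns and
    :class:`ValidationError` (naming the first offending data row,
    1-based) for NaN cells or non-monotonic timestamps.
    """
    df = _read_csv(path, STREAM_COLUMNS)
    for col in STREAM_COLUMNS:
        bad = df[col].isna()
        if bad.any():
            raise ValidationError(
                f"{path}: missing/NaN value in column {col!r} "
                f"at row {int(np.flatnonzero(bad)[0]) + 1}"
            )
    t = df["time_s"].to_numpy(float)
    if t.size > 1:
        nonmono = np.diff(t) <= 0
        if nonmono.any():
            row = int(np.flatnonzero(nonmono)[0]) + 2
            raise ValidationError(
                f"{path}: timestamps must be strictly increasing: "
                f"violation at row {row}"
            )
    return AccelerometerStream(
        t,
        df["ax"].to_numpy(float),
        df["ay"].to_numpy(float),
        df["az"].to_numpy(float),
        meta={"path": str(path)},
    )


def write_stream(stream: AccelerometerStream, path: str | os.PathLike) -> None:
    """Write a stream CSV; round-trips through :func:`read_stream` to 1e-9."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(STREAM_COLUMNS) + "\n")
        for row in zip(stream.t, stream.ax, stream.ay, stream.az):
            fh.write(",".join(f"{v:.10f}" for v in row) + "\n")


def read_labels(path: str | os.PathLike) -> list[LabelInterval]:
    """Read a label CSV (header ``start_s,end_s,gear``); sorted and validated.

    Gear strings are restricted to the five-gear vocabulary; overlapping
    intervals raise :class:`ValidationError`.
    """
    df = _read_csv(path, LABEL_COLUMNS)
    intervals = []
    for _, row in df.iterrows():
        if pd.isna(row["start_s"]) or pd.isna(row["end_s"]) or pd.isna(row["gear"]):
            raise ValidationError(f"{path}: missing value in label row")
        intervals.append(
            LabelInterval(float(row["start_s"]), float(row["end_s"]),
                          str(row["gear"]).strip())
        )
    intervals.sort(key=lambda iv: iv.start)
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start < prev.end - 1e-12:
            raise ValidationError(
                f"{path}: overlapping intervals "
                f"[{prev.start}, {prev.end}) and [{cur.start}, {cur.end})"
            )
    return intervals


def write_labels(intervals: Iterable[LabelInterval],
                 path: str | os.PathLike) -> None:
    """Write a label CSV; round-trips through :func:`read_labels`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(LABEL_COLUMNS) + "\n")
        for iv in intervals:
            fh.write(f"{iv.start:.10f},{iv.end:.10f},{iv.gear}\n")
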