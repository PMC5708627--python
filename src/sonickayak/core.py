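"""Domain types, sensor-log I/O, stream fusion, and geodesic utilities.

The atom of the package is a 1 Hz sensor record: a timestamped WGS84
position (:class:`GeoFix`) carrying two DS18B20 temperature channels
(:class:`SensorRecord`).  A trip's worth of records is a
:class:`TripLog`, stored internally as a :class:`pandas.DataFrame` for
vectorised analytics while exposing the record view other modules
expect.

Time is UTC everywhere, represented as float seconds since the Unix
epoch; the canonical on-disk form is ISO 8601 with a ``Z`` suffix.
Distances use a spherical Earth of radius 6 371 000 m.
"""

from __future__ import annotations

import io
import math
import xml.etree.ElementTree as _ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    EmptyLogError,
    ParameterError,
    SchemaError,
)

EARTH_RADIUS_M = 6_371_000.0

#: DS18B20 12-bit quantization step, 1/16 degree Celsius.
TEMP_STEP_C = 0.0625

#: DS18B20 operating range, degrees Celsius.
TEMP_RANGE_C = (-55.0, 125.0)

#: Canonical sensor-log columns, in order.
LOG_COLUMNS = ("time", "lat", "lon", "temp_a", "temp_b")

SEGMENT_LABELS = frozenset({"paused", "paddling", "out_of_water", "trip"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoFix:
    """A timestamped WGS84 position.

    Parameters
    ----------
    t : float
        UTC timestamp, seconds since the Unix epoch (sub-second allowed).
    lat, lon : float
        Decimal degrees, WGS84.
    """

    t: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ParameterError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ParameterError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class SensorRecord:
    """One 1 Hz log row: a position plus two temperature channels (deg C)."""

    fix: GeoFix
    temp_a: float
    temp_b: float


@dataclass(frozen=True)
class Segment:
    """A labelled time interval within a trip or recording."""

    t_start: float
    t_end: float
    label: str = "trip"

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ParameterError(
                f"segment end {self.t_end} not after start {self.t_start}"
            )
        if self.label not in SEGMENT_LABELS:
            raise ParameterError(f"unknown segment label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def overlap(self, other: "Segment") -> float:
        """Length in seconds of the intersection with ``other`` (>= 0)."""
        return max(0.0, min(self.t_end, other.t_end) - max(self.t_start, other.t_start))


@dataclass(frozen=True)
class AudioClip:
    """A sampled hydrophone pressure signal.

    ``samples`` are dimensionless counts in [-1, 1] full scale unless a
    calibration factor ``cal`` (micropascal per count) is attached, in
    which case ``samples * cal`` is pressure in micropascal.
    """

    rate: float
    samples: np.ndarray
    t0: float = 0.0
    cal: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ParameterError(f"sample rate must be positive, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if self.cal is not None and self.cal <= 0:
            raise ParameterError("calibration factor must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration


@dataclass
class ParseReport:
    """Accounting of rows dropped while reading or fusing a log."""

    n_total: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)

    def add(self, reason: str, count: int = 1) -> None:
        if count:
            self.n_dropped += count
            self.reasons[reason] = self.reasons.get(reason, 0) + count


class TripLog:
    """An ordered 1 Hz sensor log for one kayak.

    Wraps a DataFrame with columns ``time, lat, lon, temp_a, temp_b``
    (time as float UTC seconds).  Construction enforces the invariants:
    non-empty, strictly increasing timestamps, and — when a nominal rate
    is declared — a median inter-record interval within 10% of the
    nominal period.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        kayak_id: str = "",
        nominal_rate: Optional[float] = 1.0,
        parse_report: Optional[ParseReport] = None,
    ) -> None:
        missing = [c for c in LOG_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        frame = frame.loc[:, list(LOG_COLUMNS)].reset_index(drop=True)
        if len(frame) == 0:
            raise EmptyLogError("log has no records")
        t = frame["time"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError("record timestamps must be strictly increasing")
        if nominal_rate is not None and len(t) > 1:
            med = float(np.median(np.diff(t)))
            period = 1.0 / nominal_rate
            if not (0.9 * period <= med <= 1.1 * period):
                raise ParameterError(
                    f"median interval {med:.3f}s inconsistent with "
                    f"nominal rate {nominal_rate} Hz"
                )
        self.frame = frame
        self.kayak_id = kayak_id
        self.nominal_rate = nominal_rate
        self.parse_report = parse_report or ParseReport(n_total=len(frame))

    # -- array views --------------------------------------------------------

    @property
    def t(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.frame["lat"].to_numpy(dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return self.frame["lon"].to_numpy(dtype=float)

    @property
    def temp_a(self) -> np.ndarray:
        return self.frame["temp_a"].to_numpy(dtype=float)

    @property
    def temp_b(self) -> np.ndarray:
        return self.frame["temp_b"].to_numpy(dtype=float)

    @property
    def t_start(self) -> float:
        return float(self.frame["time"].iloc[0])

    @property
    def t_end(self) -> float:
        return float(self.frame["time"].iloc[-1])

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[SensorRecord]:
        for row in self.frame.itertuples(index=False):
            yield SensorRecord(
                fix=GeoFix(t=row.time, lat=row.lat, lon=row.lon),
                temp_a=row.temp_a,
                temp_b=row.temp_b,
            )

    @property
    def fixes(self) -> Iterator[GeoFix]:
        for row in self.frame.itertuples(index=False):
            yield GeoFix(t=row.time, lat=row.lat, lon=row.lon)

    def slice_time(self, t_start: float, t_end: float) -> "TripLog":
        """Records with t_start <= t <= t_end (raises if none)."""
        m = (self.frame["time"] >= t_start) & (self.frame["time"] <= t_end)
        sub = self.frame.loc[m]
        if len(sub) == 0:
            raise EmptyLogError(f"no records in [{t_start}, {t_end}]")
        return TripLog(sub, kayak_id=self.kayak_id, nominal_rate=None)

    @classmethod
    def from_arrays(
        cls,
        t: Sequence[float],
        lat: Sequence[float],
        lon: Sequence[float],
        temp_a: Sequence[float],
        temp_b: Sequence[float],
        **kwargs,
    ) -> "TripLog":
        frame = pd.DataFrame(
            {"time": t, "lat": lat, "lon": lon, "temp_a": temp_a, "temp_b": temp_b}
        )
        return cls(frame, **kwargs)


# ---------------------------------------------------------------------------
# Timestamp handling
# ---------------------------------------------------------------------------

def format_utc(t: float) -> str:
    """Render float UTC seconds as ISO 8601 with 'Z', millisecond precision.

    Whole seconds are written without a fractional part, so canonical
    1 Hz logs stay compact.
    """
    ms = round(t * 1000.0)
    sec, frac = divmod(ms, 1000)
    dt = datetime.fromtimestamp(sec, tz=timezone.utc)
    base = dt.strftime("%Y-%m-%dT%H:%M:%S")
    return f"{base}.{frac:03d}Z" if frac else f"{base}Z"


def parse_utc(value) -> float:
    """Parse an ISO 8601 timestamp (or plain number of seconds) to float."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    ts = pd.Timestamp(str(value))
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.timestamp()


# ---------------------------------------------------------------------------
# Sensor-log I/O
# ---------------------------------------------------------------------------

def _times_to_seconds(col: pd.Series) -> pd.Series:
    """Timestamp column -> float UTC seconds, NaN where unparseable."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="mixed")
    vals = parsed.to_numpy(dtype="datetime64[ns]")
    secs = vals.astype("int64") / 1e9
    secs[np.isnat(vals)] = np.nan
    out = pd.Series(secs, index=col.index)
    # fall back to numeric where ISO parsing failed but a number was given
    return out.where(numeric.isna(), numeric)


def read_sensor_log(
    source: Union[str, "io.TextIOBase"],
    kayak_id: str = "",
    column_map: Optional[dict] = None,
) -> TripLog:
    """Read a canonical sensor-log CSV into a :class:`TripLog`.

    The canonical dialect is comma-separated UTF-8 with a header row
    naming ``time, lat, lon, temp_a, temp_b``; timestamps are ISO 8601
    UTC (plain seconds are also accepted).  Rows with unparseable or
    out-of-range fields are dropped and counted in the returned log's
    ``parse_report``.  ``column_map`` renames source columns to the
    canonical names for non-canonical deposits.

    Raises
    ------
    SchemaError
        If a required column is absent.
    EmptyLogError
        If no valid rows remain.
    """
    raw = pd.read_csv(source, skipinitialspace=True)
    raw.columns = [str(c).strip() for c in raw.columns]
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in LOG_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    report = ParseReport(n_total=len(raw))
    out = pd.DataFrame(index=raw.index)
    out["time"] = _times_to_seconds(raw["time"])
    for c in ("lat", "lon", "temp_a", "temp_b"):
        out[c] = pd.to_numeric(raw[c], errors="coerce")

    bad_parse = out.isna().any(axis=1)
    report.add("unparseable field", int(bad_parse.sum()))
    out = out[~bad_parse]

    bad_range = (
        (out["lat"].abs() > 90.0)
        | (out["lon"].abs() > 180.0)
        | (out["temp_a"] < TEMP_RANGE_C[0])
        | (out["temp_a"] > TEMP_RANGE_C[1])
        | (out["temp_b"] < TEMP_RANGE_C[0])
        | (out["temp_b"] > TEMP_RANGE_C[1])
    )
    report.add("out-of-range field", int(bad_range.sum()))
    out = out[~bad_range]

    # enforce strictly increasing time by dropping offending rows
    if len(out) > 1:
        keep = np.ones(len(out), dtype=bool)
        t = out["time"].to_numpy(dtype=float)
        last = t[0]
        for i in range(1, len(t)):
            if t[i] <= last:
                keep[i] = False
            else:
                last = t[i]
        report.add("non-increasing timestamp", int((~keep).sum()))
        out = out[keep]

    if len(out) == 0:
        raise EmptyLogError("no valid rows in sensor log")
    return TripLog(out, kayak_id=kayak_id, nominal_rate=None, parse_report=report)


def write_sensor_log(log: TripLog, dest: Union[str, "io.TextIOBase"]) -> int:
    """Write a log as canonical CSV; returns the number of rows written.

    Coordinates are written with 6 decimals (~0.1 m), temperatures with
    4 decimals (representing the 1/16 degC lattice exactly), timestamps
    as ISO 8601 'Z' at millisecond precision.
    """
    frame = pd.DataFrame(
        {
            "time": [format_utc(t) for t in log.t],
            "lat": [f"{v:.6f}" for v in log.lat],
            "lon": [f"{v:.6f}" for v in log.lon],
            "temp_a": [f"{v:.4f}" for v in log.temp_a],
            "temp_b": [f"{v:.4f}" for v in log.temp_b],
        }
    )
    frame.to_csv(dest, index=False)
    return len(frame)


def read_gpx(source: Union[str, "io.TextIOBase"]) -> list[GeoFix]:
    """Extract track points from a GPX 1.1 document as GeoFix objects.

    Namespace-agnostic: any element whose tag ends in ``trkpt`` with a
    child time element is used.  Points without a timestamp are skipped.
    """
    tree = _ET.parse(source)
    fixes: list[GeoFix] = []
    for el in tree.iter():
        if el.tag.rpartition("}")[2] != "trkpt":
            continue
        t = None
        for child in el:
            if child.tag.rpartition("}")[2] == "time" and child.text:
                t = parse_utc(child.text)
        if t is None:
            continue
        fixes.append(GeoFix(t=t, lat=float(el.get("lat")), lon=float(el.get("lon"))))
    fixes.sort(key=lambda f: f.t)
    return fixes


# ---------------------------------------------------------------------------
# Stream fusion
# ---------------------------------------------------------------------------

def fuse_streams(
    fixes: Sequence[GeoFix],
    temps: Iterable[tuple[float, float, float]],
    max_gap: float = 1.0,
    kayak_id: str = "",
) -> TripLog:
    """Join temperature samples to the nearest-in-time GPS fix.

    Each ``(t, temp_a, temp_b)`` sample becomes one record positioned at
    the nearest fix; ties go to the earlier fix and the join is inclusive
    at exactly ``max_gap``.  Samples with no fix within ``max_gap``
    seconds are dropped and counted in the result's ``parse_report``.

    Both streams must be time-sorted.
    """
    temps = list(temps)
    if not temps:
        raise EmptyLogError("no temperature samples to fuse")
    if not fixes:
        raise EmptyLogError("no GPS fixes to fuse against")

    fix_t = np.array([f.t for f in fixes], dtype=float)
    fix_lat = np.array([f.lat for f in fixes], dtype=float)
    fix_lon = np.array([f.lon for f in fixes], dtype=float)
    if np.any(np.diff(fix_t) < 0):
        raise ParameterError("fixes must be time-sorted")

    t = np.array([s[0] for s in temps], dtype=float)
    ta = np.array([s[1] for s in temps], dtype=float)
    tb = np.array([s[2] for s in temps], dtype=float)
    if np.any(np.diff(t) < 0):
        raise ParameterError("temperature samples must be time-sorted")

    right = np.searchsorted(fix_t, t, side="left")
    left = np.clip(right - 1, 0, len(fix_t) - 1)
    right = np.clip(right, 0, len(fix_t) - 1)
    d_left = np.abs(t - fix_t[left])
    d_right = np.abs(fix_t[right] - t)
    # tie toward the earlier fix
    use_left = d_left <= d_right
    idx = np.where(use_left, left, right)
    dist = np.where(use_left, d_left, d_right)
    keep = dist <= max_gap

    report = ParseReport(n_total=len(t))
    report.add("no fix within max_gap", int((~keep).sum()))
    if not np.any(keep):
        raise EmptyLogError("no temperature sample had a fix within max_gap")

    return TripLog.from_arrays(
        t=t[keep],
        lat=fix_lat[idx[keep]],
        lon=fix_lon[idx[keep]],
        temp_a=ta[keep],
        temp_b=tb[keep],
        kayak_id=kayak_id,
        nominal_rate=None,
        parse_report=report,
    )


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------

def _haversine_arrays(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorised great-circle distance in metres on the spherical Earth."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_m(a: GeoFix, b: GeoFix) -> float:
    """Great-circle distance in metres between two fixes (sphere R=6371 km)."""
    return float(_haversine_arrays(a.lat, a.lon, b.lat, b.lon))


def track_speed(log: TripLog) -> np.ndarray:
    """Per-record ground speed in m/s.

    Interior points use a central difference (distance between the
    neighbours over their time gap); endpoints are one-sided.  Speeds
    are non-negative by construction.
    """
    if len(log) < 2:
        raise ParameterError("speed is undefined for fewer than 2 records")
    t, lat, lon = log.t, log.lat, log.lon
    n = len(t)
    v = np.empty(n, dtype=float)
    d = _haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt = np.diff(t)
    v[0] = d[0] / dt[0]
    v[-1] = d[-1] / dt[-1]
    if n > 2:
        dc = _haversine_arrays(lat[:-2], lon[:-2], lat[2:], lon[2:])
        v[1:-1] = dc / (t[2:] - t[:-2])
    return v


def local_xy_m(
    lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project positions to a local tangent plane centred at (lat0, lon0).

    Azimuthal equirectangular: x east, y north, metres.  Adequate for
    extents below ~10 km, which covers any kayak trip.
    """
    x = np.radians(np.asarray(lon) - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * EARTH_RADIUS_M
    return x, y


def xy_to_latlon(
    x: np.ndarray, y: np.ndarray, lat0: float, lon0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`local_xy_m`."""
    lat = lat0 + np.degrees(np.asarray(y) / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(
        np.asarray(x) / (EARTH_RADIUS_M * math.cos(math.radians(lat0)))
    )
    return lat, lon
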