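"""Temperature-track analytics.

Turns 1 Hz kayak temperature logs into the fine-scale water-temperature
products: detection of out-of-water artefacts (probe in air shows a
rapid temperature rise), splitting a day's log into consecutive trips,
min/max/mean summaries matching the published reporting convention,
spatial gridding on a local tangent plane, replicate comparison between
kayaks, and GeoJSON map export with a blue-to-red colour ramp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import math
import numpy as np
import pandas as pd

from .core import (
    GeoFix,
    Segment,
    TripLog,
    local_xy_m,
    xy_to_latlon,
)
from .errors import (
    EmptyLogError,
    OverlapError,
    ParameterError,
)


@dataclass(frozen=True)
class TripSummary:
    """Minimum, maximum and arithmetic-mean temperature with record count."""

    t_min: float
    t_max: float
    t_mean: float
    n: int

    def __post_init__(self) -> None:
        if not (self.t_min <= self.t_mean <= self.t_max):
            raise ParameterError("summary violates min <= mean <= max")
        if self.n < 1:
            raise ParameterError("summary needs n >= 1")

    def display(self, decimals: int = 3) -> str:
        """Truncated (not rounded) display matching printed 3-decimal values."""
        f = 10.0 ** decimals

        def trunc(v: float) -> float:
            return math.trunc(v * f) / f

        return (
            f"minimum temperature = {trunc(self.t_min):.{decimals}f} degC, "
            f"maximum temperature = {trunc(self.t_max):.{decimals}f} degC, "
            f"mean temperature = {trunc(self.t_mean):.{decimals}f} degC, "
            f"n = {self.n:,}"
        )


@dataclass
class CellStats:
    mean: float
    min: float
    max: float
    count: int


@dataclass
class TemperatureGrid:
    """Sparse spatial grid of temperature statistics.

    Cells are squares of ``cell_size`` metres on a local tangent plane
    centred at ``origin``; cell (i, j) covers x in [i*s, (i+1)*s),
    y in [j*s, (j+1)*s) with x east and y north.
    """

    cell_size: float
    origin: GeoFix
    cells: dict  # (i, j) -> CellStats

    def __post_init__(self) -> None:
        for key, c in self.cells.items():
            if c.count <= 0 or not (c.min <= c.mean <= c.max):
                raise ParameterError(f"invalid statistics in cell {key}")


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------

def _channel_values(log: TripLog, channel: str) -> np.ndarray:
    if channel == "a":
        return log.temp_a
    if channel == "b":
        return log.temp_b
    if channel == "both":
        return np.concatenate([log.temp_a, log.temp_b])
    if channel == "mean":
        return 0.5 * (log.temp_a + log.temp_b)
    raise ParameterError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------------
# Out-of-water detection
# ---------------------------------------------------------------------------

def detect_out_of_water(
    log: TripLog,
    rise_thresh: float = 2.0,
    window: float = 60.0,
    channel: str = "mean",
) -> list[Segment]:
    """Detect intervals where the probe left the water.

    An excursion starts where the temperature rises by at least
    ``rise_thresh`` degC within ``window`` seconds over the running
    pre-rise baseline (the minimum within the trailing window), and ends
    when the temperature returns within ``rise_thresh / 2`` of that
    baseline.  The reported start is walked back to the rise onset (the
    last sample still within ``rise_thresh / 2`` of baseline).  Slow
    tidal warming (order 0.1 degC/min) never triggers the default gate.
    """
    if log.duration < window:
        raise ParameterError("log shorter than the detection window")
    t = log.t
    temp = _channel_values(log, channel)
    n = len(t)
    segments: list[Segment] = []
    i = 0
    while i < n:
        # trailing-window minimum = pre-rise baseline candidate
        w0 = np.searchsorted(t, t[i] - window, side="left")
        baseline = float(np.min(temp[w0 : i + 1]))
        if temp[i] - baseline >= rise_thresh:
            half = rise_thresh / 2.0
            # walk back to the onset of the rise
            s = i
            while s > w0 and temp[s - 1] > baseline + half:
                s -= 1
            # walk forward to the return toward baseline
            e = i
            while e + 1 < n and temp[e + 1] > baseline + half:
                e += 1
            if e > s:
                segments.append(Segment(t_start=t[s], t_end=t[e], label="out_of_water"))
            i = e + 1
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# Trip splitting
# ---------------------------------------------------------------------------

def split_trips(
    log: TripLog,
    gap_thresh: float = 120.0,
    out_of_water: Optional[Sequence[Segment]] = None,
) -> list[TripLog]:
    """Split a log into consecutive trips.

    Splits at recording gaps strictly greater than ``gap_thresh``
    seconds and at the given out-of-water segments (whose records are
    excluded, so the concatenation of the parts preserves exactly the
    in-water records).  Each part is a valid non-empty log.
    """
    t = log.t
    in_water = np.ones(len(t), dtype=bool)
    for seg in out_of_water or ():
        in_water &= ~((t >= seg.t_start) & (t <= seg.t_end))

    trips: list[TripLog] = []
    start = None
    prev = None
    for i in range(len(t)):
        if not in_water[i]:
            if start is not None:
                trips.append(_sub_log(log, start, prev))
                start = None
            continue
        if start is None:
            start = i
        elif t[i] - t[prev] > gap_thresh:
            trips.append(_sub_log(log, start, prev))
            start = i
        prev = i
    if start is not None:
        trips.append(_sub_log(log, start, prev))
    return trips


def _sub_log(log: TripLog, i0: int, i1: int) -> TripLog:
    return TripLog(
        log.frame.iloc[i0 : i1 + 1], kayak_id=log.kayak_id, nominal_rate=None
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(log: TripLog, channel: str = "both") -> TripSummary:
    """Min / max / arithmetic-mean over the selected channel(s).

    ``channel='both'`` pools the two thermometers, so ``n`` counts
    temperature values (2 per record), matching a record-count
    convention only when a single channel is selected.
    """
    values = _channel_values(log, channel)
    if values.size == 0:
        raise EmptyLogError("no temperature values to summarise")
    return TripSummary(
        t_min=float(np.min(values)),
        t_max=float(np.max(values)),
        t_mean=float(np.mean(values)),
        n=int(values.size),
    )


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------

def grid_temperature(
    log: TripLog,
    cell_size: float,
    channel: str = "mean",
    origin: Optional[GeoFix] = None,
) -> TemperatureGrid:
    """Bin records into square cells on a local tangent plane.

    The plane is centred on the track centroid unless ``origin`` is
    given (pass a shared origin when grids are to be compared).  Cell
    statistics are the per-cell mean/min/max/count of the selected
    channel ('mean' averages the two thermometers per record).
    """
    if cell_size <= 0:
        raise ParameterError("cell_size must be positive")
    if channel == "mean":
        vals = 0.5 * (log.temp_a + log.temp_b)
    elif channel in ("a", "b"):
        vals = log.temp_a if channel == "a" else log.temp_b
    else:
        raise ParameterError("grid channel must be 'a', 'b' or 'mean'")
    if origin is None:
        origin = GeoFix(t=0.0, lat=float(np.mean(log.lat)), lon=float(np.mean(log.lon)))
    x, y = local_xy_m(log.lat, log.lon, origin.lat, origin.lon)
    i = np.floor(x / cell_size).astype(int)
    j = np.floor(y / cell_size).astype(int)
    frame = pd.DataFrame({"i": i, "j": j, "v": vals})
    agg = frame.groupby(["i", "j"])["v"].agg(["mean", "min", "max", "count"])
    cells = {
        (int(ii), int(jj)): CellStats(
            mean=float(r["mean"]), min=float(r["min"]), max=float(r["max"]),
            count=int(r["count"]),
        )
        for (ii, jj), r in agg.iterrows()
    }
    return TemperatureGrid(cell_size=cell_size, origin=origin, cells=cells)


def compare_replicates(g1: TemperatureGrid, g2: TemperatureGrid) -> dict:
    """Replicability statistics over cells occupied in both grids.

    Returns ``shared_cells``, ``mean_abs_diff`` (degC) and ``bias``
    (degC, grid1 minus grid2).  Grids must share cell size and origin.
    """
    if g1.cell_size != g2.cell_size:
        raise ParameterError("grids have different cell sizes")
    if (
        abs(g1.origin.lat - g2.origin.lat) > 1e-12
        or abs(g1.origin.lon - g2.origin.lon) > 1e-12
    ):
        raise ParameterError("grids have different origins; re-grid with a shared origin")
    shared = sorted(set(g1.cells) & set(g2.cells))
    if not shared:
        raise OverlapError("grids share no occupied cells")
    d = np.array([g1.cells[k].mean - g2.cells[k].mean for k in shared])
    return {
        "shared_cells": len(shared),
        "mean_abs_diff": float(np.mean(np.abs(d))),
        "bias": float(np.mean(d)),
    }


# ---------------------------------------------------------------------------
# Map export
# ---------------------------------------------------------------------------

def _ramp_hex(frac: float) -> str:
    """Linear blue (#0000ff) to red (#ff0000) colour ramp."""
    frac = min(1.0, max(0.0, frac))
    r = int(round(255 * frac))
    b = int(round(255 * (1.0 - frac)))
    return f"#{r:02x}00{b:02x}"


def export_map(
    obj: Union[TemperatureGrid, TripLog], dest=None, channel: str = "mean"
) -> int:
    """Export a grid (cell polygons) or a log (record points) as GeoJSON.

    Each feature carries temperature properties and a ``fill`` colour
    from a linear blue-to-red ramp over the object's min-to-max
    temperature range (blue = colder, red = warmer).  Returns the number
    of features written.  Raises on empty input.
    """
    if isinstance(obj, TemperatureGrid):
        fc = _grid_features(obj)
    elif isinstance(obj, TripLog):
        fc = _log_features(obj, channel)
    else:
        raise ParameterError(f"cannot export {type(obj).__name__}")
    if dest is not None:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(fc, fh)
    return len(fc["features"])


def _grid_features(grid: TemperatureGrid) -> dict:
    if not grid.cells:
        raise EmptyLogError("grid has no occupied cells")
    means = [c.mean for c in grid.cells.values()]
    vmin, vmax = min(means), max(means)
    span = (vmax - vmin) or 1.0
    s = grid.cell_size
    features = []
    for (i, j), c in sorted(grid.cells.items()):
        xs = np.array([i * s, (i + 1) * s, (i + 1) * s, i * s, i * s])
        ys = np.array([j * s, j * s, (j + 1) * s, (j + 1) * s, j * s])
        lat, lon = xy_to_latlon(xs, ys, grid.origin.lat, grid.origin.lon)
        ring = [[float(lo), float(la)] for lo, la in zip(lon, lat)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "i": i,
                    "j": j,
                    "temp_mean": c.mean,
                    "temp_min": c.min,
                    "temp_max": c.max,
                    "count": c.count,
                    "fill": _ramp_hex((c.mean - vmin) / span),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _log_features(log: TripLog, channel: str) -> dict:
    vals = _channel_values(log, "mean" if channel == "both" else channel)
    vmin, vmax = float(np.min(vals)), float(np.max(vals))
    span = (vmax - vmin) or 1.0
    features = []
    for t, la, lo, v in zip(log.t, log.lat, log.lon, vals):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(lo), float(la)]},
                "properties": {
                    "time": float(t),
                    "temp": float(v),
                    "fill": _ramp_hex((float(v) - vmin) / span),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def read_grid_geojson(path) -> dict:
    """Parse an exported grid back to a ``(i, j) -> CellStats`` mapping."""
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    cells = {}
    for feat in fc["features"]:
        p = feat["properties"]
        cells[(p["i"], p["j"])] = CellStats(
            mean=p["temp_mean"], min=p["temp_min"], max=p["temp_max"], count=p["count"]
        )
    return cells
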