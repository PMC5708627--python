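"""Three-layer sonification as a deterministic offline renderer.

The kayak's audio experience is mixed from three layers:

1. a continuous oscillator whose pitch follows the water temperature
   through a pitch mapping (linear or exponential in frequency),
2. the hydrophone feed, time-aligned and gain-scaled,
3. geofenced zone samples triggered when the GPS track enters circular
   sound zones and stopped when it exits.

Rendering is fully deterministic: identical log, zones, samples and
configuration produce bit-identical output.  Control parameters update
once per log record (the 1 Hz cadence) with linear interpolation in
between to avoid zipper noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .core import AudioClip, GeoFix, TripLog, haversine_m
from .errors import AssetError, ParameterError

#: Output peak ceiling, -1 dB re full scale.
PEAK_CEILING = 10.0 ** (-1.0 / 20.0)


@dataclass(frozen=True)
class SoundZone:
    """A circular geofenced trigger region with playback policy."""

    center: GeoFix
    radius: float
    sample_id: str
    mode: str = "loop"
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("zone radius must be positive")
        if not 0.0 <= self.gain <= 1.0:
            raise ParameterError("zone gain must lie in [0, 1]")
        if self.mode not in ("loop", "once"):
            raise ParameterError(f"unknown zone mode {self.mode!r}")


@dataclass(frozen=True)
class PitchMapping:
    """Maps temperature (degC) to oscillator frequency (Hz).

    ``linear`` interpolates frequency directly; ``exponential``
    interpolates pitch (log-frequency), so equal temperature steps give
    equal musical intervals.  Temperatures outside [t_lo, t_hi] clamp.
    """

    t_lo: float = 10.0
    t_hi: float = 30.0
    f_lo: float = 220.0
    f_hi: float = 880.0
    law: str = "exponential"

    def __post_init__(self) -> None:
        if not self.t_lo < self.t_hi:
            raise ParameterError("require t_lo < t_hi")
        if not 0 < self.f_lo < self.f_hi:
            raise ParameterError("require 0 < f_lo < f_hi")
        if self.law not in ("linear", "exponential"):
            raise ParameterError(f"unknown mapping law {self.law!r}")


@dataclass(frozen=True)
class TriggerEvent:
    t: float
    zone: SoundZone
    kind: str  # enter | exit


def temp_to_freq(temp, m: PitchMapping):
    """Temperature -> frequency under the mapping (scalar or array)."""
    temp = np.clip(temp, m.t_lo, m.t_hi)
    u = (temp - m.t_lo) / (m.t_hi - m.t_lo)
    if m.law == "linear":
        return m.f_lo + (m.f_hi - m.f_lo) * u
    return m.f_lo * (m.f_hi / m.f_lo) ** u


def zone_active(fix: GeoFix, zone: SoundZone) -> bool:
    """True iff the fix lies within the zone (boundary inclusive)."""
    return haversine_m(fix, zone.center) <= zone.radius


def trigger_timeline(
    track: Sequence[GeoFix], zones: Sequence[SoundZone]
) -> list[TriggerEvent]:
    """Enter/exit events for each zone along a time-sorted track.

    Enter fires at the first fix inside after being outside (or at the
    first fix if the track starts inside); exit at the first fix outside
    after being inside.  Events alternate per zone and come back
    time-sorted (ties keep zone order).
    """
    events: list[TriggerEvent] = []
    for zone in zones:
        inside = False
        for fix in track:
            now = zone_active(fix, zone)
            if now and not inside:
                events.append(TriggerEvent(t=fix.t, zone=zone, kind="enter"))
            elif inside and not now:
                events.append(TriggerEvent(t=fix.t, zone=zone, kind="exit"))
            inside = now
    events.sort(key=lambda e: e.t)
    return events


# ---------------------------------------------------------------------------
# Zone map I/O
# ---------------------------------------------------------------------------

def read_zones(path) -> list[SoundZone]:
    """Load zones from a GeoJSON FeatureCollection of Points.

    Each Point feature carries ``radius_m``, ``sample_id`` and optional
    ``mode`` / ``gain`` properties.
    """
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    zones = []
    for feat in fc.get("features", []):
        lon, lat = feat["geometry"]["coordinates"][:2]
        p = feat["properties"]
        zones.append(
            SoundZone(
                center=GeoFix(t=0.0, lat=lat, lon=lon),
                radius=float(p["radius_m"]),
                sample_id=str(p["sample_id"]),
                mode=p.get("mode", "loop"),
                gain=float(p.get("gain", 1.0)),
            )
        )
    return zones


def write_zones(zones: Sequence[SoundZone], path) -> int:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [z.center.lon, z.center.lat],
            },
            "properties": {
                "radius_m": z.radius,
                "sample_id": z.sample_id,
                "mode": z.mode,
                "gain": z.gain,
            },
        }
        for z in zones
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return len(features)


def load_sample_bank(directory) -> dict:
    """Read every ``<sample_id>.wav`` in a directory into AudioClips."""
    from .acoustics import read_wav

    bank = {}
    for p in sorted(Path(directory).glob("*.wav")):
        bank[p.stem] = read_wav(p)
    return bank


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _resample_to(clip: AudioClip, rate: float) -> np.ndarray:
    if clip.rate == rate:
        return clip.samples
    frac = Fraction(int(round(rate)), int(round(clip.rate))).limit_denominator(1000)
    return _sig.resample_poly(clip.samples, frac.numerator, frac.denominator)


def _render_tone(log: TripLog, m: PitchMapping, times: np.ndarray, rate: float) -> np.ndarray:
    # instantaneous frequency: per-record update, linear interpolation between
    freqs = temp_to_freq(log.temp_a, m)
    f_inst = np.interp(times, log.t, freqs)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / rate
    return np.sin(phase)


def _render_zone_layer(
    log: TripLog,
    zones: Sequence[SoundZone],
    bank: Mapping[str, AudioClip],
    n: int,
    rate: float,
) -> tuple[np.ndarray, list[TriggerEvent]]:
    out = np.zeros(n)
    events = trigger_timeline(list(log.fixes), zones)
    # pair enter/exit per zone; trailing enter runs to the end of the log
    open_at: dict[int, float] = {}
    intervals: list[tuple[SoundZone, float, float]] = []
    for ev in events:
        key = id(ev.zone)
        if ev.kind == "enter":
            open_at[key] = ev.t
        else:
            intervals.append((ev.zone, open_at.pop(key), ev.t))
    for key, t_in in open_at.items():
        zone = next(z for z in zones if id(z) == key)
        intervals.append((zone, t_in, log.t_end))

    t0 = log.t_start
    for zone, t_in, t_out in intervals:
        if zone.sample_id not in bank:
            raise AssetError(f"no sample for zone id {zone.sample_id!r}")
        wave = _resample_to(bank[zone.sample_id], rate)
        i0 = int(round((t_in - t0) * rate))
        span = int(round((t_out - t_in) * rate))
        if span <= 0:
            continue
        if zone.mode == "loop":
            reps = int(np.ceil(span / wave.size))
            chunk = np.tile(wave, reps)[:span]
        else:  # once: a single pass, truncated to the active interval
            chunk = wave[: min(span, wave.size)]
        i1 = min(n, i0 + chunk.size)
        out[i0:i1] += zone.gain * chunk[: i1 - i0]
    return out, events


def render_sonification(
    log: TripLog,
    hydro: Optional[AudioClip] = None,
    zones: Sequence[SoundZone] = (),
    mapping: PitchMapping = PitchMapping(),
    rate: float = 22_050.0,
    layer_gains: tuple[float, float, float] = (0.5, 1.0, 0.8),
    sample_bank: Optional[Mapping[str, AudioClip]] = None,
) -> tuple[AudioClip, list[TriggerEvent]]:
    """Render the three-layer mix for one trip.

    Returns the mixed clip (float, starting at the log's first
    timestamp, duration equal to the log duration) and the zone trigger
    events.  The mix is peak-normalised down to -1 dBFS when it would
    exceed that ceiling; an all-zero gain vector yields digital silence
    of the correct duration.

    Raises :class:`AssetError` when a zone's ``sample_id`` is missing
    from the bank and :class:`ParameterError` for rates below 8 kHz.
    """
    if rate < 8000:
        raise ParameterError("render rate below 8000 Hz")
    if len(log) < 2:
        raise ParameterError("need at least 2 records to render")
    bank = sample_bank or {}
    for z in zones:
        if z.sample_id not in bank:
            raise AssetError(f"no sample for zone id {z.sample_id!r}")
    g_tone, g_hydro, g_zone = layer_gains

    n = int(round(log.duration * rate))
    times = log.t_start + np.arange(n) / rate
    mix = np.zeros(n)

    if g_tone != 0.0:
        mix += g_tone * _render_tone(log, mapping, times, rate)

    if hydro is not None and g_hydro != 0.0:
        wave = _resample_to(hydro, rate)
        i0 = int(round((hydro.t0 - log.t_start) * rate))
        j0 = max(0, i0)
        j1 = min(n, i0 + wave.size)
        if j1 > j0:
            mix[j0:j1] += g_hydro * wave[j0 - i0 : j1 - i0]

    events: list[TriggerEvent] = []
    if zones:
        layer, events = _render_zone_layer(log, zones, bank, n, rate)
        mix += g_zone * layer

    peak = float(np.max(np.abs(mix))) if n else 0.0
    if peak > PEAK_CEILING:
        mix *= PEAK_CEILING / peak
    return AudioClip(rate=rate, samples=mix, t0=log.t_start), events


def events_to_frame(events: Sequence[TriggerEvent]):
    import pandas as pd

    return pd.DataFrame(
        {
            "time": [e.t for e in events],
            "kind": [e.kind for e in events],
            "sample_id": [e.zone.sample_id for e in events],
            "lat": [e.zone.center.lat for e in events],
            "lon": [e.zone.center.lon for e in events],
        }
    )
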