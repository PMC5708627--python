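"""Synthetic fixture generation with known ground truth.

Emulates the statistical structure of real kayak deployments so every
analysis stage can be verified without hardware:

* a 1 Hz GPS track as a smooth random-walk inside a bay bounding box,
  with scheduled paddling pauses and optional multi-session structure
  (recording gaps between trips);
* a deterministic water-temperature field — base level, eastward
  spatial gradient, and linear tidal warming — sampled along the track,
  degraded by bounded sensor noise and DS18B20 1/16 degC quantization;
* out-of-water excursions, where the probe reads an air-temperature
  ramp instead of the water field;
* a shallow-water soundscape of stationary Gaussian flow noise, tonal
  boat noise (fixed lines between 200 Hz and 10 kHz), and Poisson-timed
  broadband snapping-shrimp clicks, with analytically known per-segment
  band-limited levels.

All randomness derives from the single manifest seed through fixed
substreams, so regenerating any component is bit-identical and adding a
component never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeoFix,
    TEMP_RANGE_C,
    TEMP_STEP_C,
    TripLog,
    local_xy_m,
    xy_to_latlon,
)
from .errors import FieldDomainError, ParameterError, SensorRangeError

# substream indices (never renumber: determinism contract)
_SUB_TRACK = 1
_SUB_NOISE_A = 2
_SUB_NOISE_B = 3
_SUB_SOUND_NOISE = 4
_SUB_SOUND_CLICKS = 5
_SUB_SOUND_PHASE = 6


@dataclass
class TrackParams:
    """Bay geometry and kinematics of the simulated paddle."""

    center_lat: float = 50.155
    center_lon: float = -5.065
    box_half_m: float = 800.0
    duration_s: float = 1800.0
    cruise_speed: float = 1.2          # m/s, relaxed paddling
    heading_sd: float = 0.08           # rad per 1 s step
    ramp_s: float = 5.0                # speed ramp at pause edges
    pauses: tuple = ()                 # (start_s, end_s) relative to t0
    n_sessions: int = 1
    session_gap_s: float = 600.0       # recording gap between sessions


@dataclass
class FieldParams:
    """Deterministic water-temperature field plus sensor noise level."""

    base_c: float = 18.0
    gradient_c_per_km: float = 0.5     # eastward spatial gradient
    warming_c_per_hour: float = 0.3    # tidal warming trend
    noise_sd_c: float = 0.1            # per-channel Gaussian sd, clipped


@dataclass
class ExcursionParams:
    """Out-of-water intervals (probe in air)."""

    intervals: tuple = ()              # (start_s, end_s) relative to t0
    air_temp_c: float = 26.0
    tau_up_s: float = 15.0             # warming time constant in air
    tau_down_s: float = 5.0            # re-equilibration back in water


@dataclass
class SoundscapeParams:
    """Tonal boat noise + flow noise + shrimp clicks.

    ``segments`` is a sequence of (duration_s, flow_noise_db) pairs;
    flow-noise level is the RMS in dB re digital full scale.  Tone
    levels are per-tone RMS dBFS.
    """

    tone_freqs_hz: tuple = (315.0, 1250.0, 4000.0)
    tone_levels_db: tuple = (-35.0, -40.0, -45.0)
    click_rate_hz: float = 0.5
    click_amp: float = 0.05
    click_dur_s: float = 0.001
    segments: tuple = ((12.0, -40.0), (12.0, -35.0), (12.0, -30.0))


@dataclass
class GroundTruth:
    """What the generator knows that the analyses must recover."""

    field_min_c: Optional[float] = None
    field_max_c: Optional[float] = None
    field_mean_c: Optional[float] = None
    n_records: Optional[int] = None
    session_bounds: list = dc_field(default_factory=list)   # (t_start, t_end)
    excursions: list = dc_field(default_factory=list)       # (t_start, t_end)
    segment_spl_db: list = dc_field(default_factory=list)   # (t_start, t_end, spl)

    def validate(self) -> None:
        if self.field_min_c is not None:
            if not (self.field_min_c <= self.field_mean_c <= self.field_max_c):
                raise ParameterError("ground truth violates min <= mean <= max")


@dataclass
class FixtureManifest:
    """Complete, seedable description of one synthetic deployment."""

    seed: int = 0
    t0: float = 1473152400.0           # 2016-09-06T09:00:00Z
    track: TrackParams = dc_field(default_factory=TrackParams)
    field: FieldParams = dc_field(default_factory=FieldParams)
    excursions: ExcursionParams = dc_field(default_factory=ExcursionParams)
    soundscape: SoundscapeParams = dc_field(default_factory=SoundscapeParams)
    ground_truth: GroundTruth = dc_field(default_factory=GroundTruth)

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), substream]))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureManifest":
        def tup(section: dict, key: str) -> None:
            if key in section:
                section[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                                     for v in section[key])

        d = {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}
        track = d.get("track", {})
        tup(track, "pauses")
        exc = d.get("excursions", {})
        tup(exc, "intervals")
        snd = d.get("soundscape", {})
        for key in ("tone_freqs_hz", "tone_levels_db", "segments"):
            tup(snd, key)
        gt = d.get("ground_truth", {})
        return cls(
            seed=int(d.get("seed", 0)),
            t0=float(d.get("t0", cls.t0)),
            track=TrackParams(**track),
            field=FieldParams(**d.get("field", {})),
            excursions=ExcursionParams(**exc),
            soundscape=SoundscapeParams(**snd),
            ground_truth=GroundTruth(**gt) if gt else GroundTruth(),
        )

    def to_toml(self) -> str:
        return _dict_to_toml(self.to_dict())

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml(), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "FixtureManifest":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ParameterError(f"cannot serialise {type(v).__name__} to TOML")


def _dict_to_toml(d: dict) -> str:
    lines = []
    tables = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        elif v is not None:
            lines.append(f"{k} = {_toml_value(v)}")
    for name, table in tables:
        lines.append(f"\n[{name}]")
        for k, v in table.items():
            if v is not None and not isinstance(v, dict):
                lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------

def _speed_envelope(t_rel: np.ndarray, p: TrackParams) -> np.ndarray:
    """Cruise-speed multiplier in [0, 1]; cosine ramps into pauses."""
    env = np.ones_like(t_rel)
    for start, end in p.pauses:
        r = p.ramp_s
        env = np.where((t_rel >= start) & (t_rel <= end), 0.0, env)
        down = (t_rel > start - r) & (t_rel < start)
        env = np.where(down, np.minimum(env, 0.5 * (1 - np.cos(np.pi * (start - t_rel) / r))), env)
        up = (t_rel > end) & (t_rel < end + r)
        env = np.where(up, np.minimum(env, 0.5 * (1 - np.cos(np.pi * (t_rel - end) / r))), env)
    return env


def total_span_s(p: TrackParams) -> float:
    """Wall-clock span covering all sessions and the gaps between them."""
    return p.n_sessions * p.duration_s + (p.n_sessions - 1) * p.session_gap_s


def session_windows(manifest: FixtureManifest) -> list[tuple[float, float]]:
    """Absolute (t_start, t_end) of each recorded session."""
    p = manifest.track
    out = []
    for k in range(p.n_sessions):
        start = manifest.t0 + k * (p.duration_s + p.session_gap_s)
        out.append((start, start + p.duration_s))
    return out


def simulate_track(manifest: FixtureManifest) -> list[GeoFix]:
    """Simulate the full 1 Hz GPS track (gaps included; the log
    generator drops the between-session fixes).

    The heading performs a Gaussian random walk; speed follows the
    cruise profile with scheduled pauses; the kayak reflects off the
    bounding-box walls.  Same seed, same track — bit-identical.
    """
    p = manifest.track
    rng = manifest.rng(_SUB_TRACK)
    n = int(round(total_span_s(p))) + 1
    t_rel = np.arange(n, dtype=float)
    env = _speed_envelope(t_rel, p)
    heading = rng.normal(0.0, p.heading_sd, size=n).cumsum() + rng.uniform(0, 2 * np.pi)

    x = np.empty(n)
    y = np.empty(n)
    x[0] = y[0] = 0.0
    h = float(heading[0])
    for i in range(1, n):
        h = heading[i]
        step = p.cruise_speed * env[i]
        nx = x[i - 1] + step * math.cos(h)
        ny = y[i - 1] + step * math.sin(h)
        # reflect at the bay walls
        if abs(nx) > p.box_half_m:
            nx = math.copysign(2 * p.box_half_m, nx) - nx
        if abs(ny) > p.box_half_m:
            ny = math.copysign(2 * p.box_half_m, ny) - ny
        x[i], y[i] = nx, ny

    lat, lon = xy_to_latlon(x, y, p.center_lat, p.center_lon)
    t = manifest.t0 + t_rel
    return [GeoFix(t=float(tt), lat=float(la), lon=float(lo))
            for tt, la, lo in zip(t, lat, lon)]


# ---------------------------------------------------------------------------
# Temperature field
# ---------------------------------------------------------------------------

def _field_values(
    t: np.ndarray, lat: np.ndarray, lon: np.ndarray, manifest: FixtureManifest
) -> np.ndarray:
    p, f = manifest.track, manifest.field
    x, y = local_xy_m(lat, lon, p.center_lat, p.center_lon)
    if np.any(np.abs(x) > p.box_half_m * 1.001) or np.any(np.abs(y) > p.box_half_m * 1.001):
        raise FieldDomainError("position outside the field bounding box")
    east_km = x / 1000.0
    hours = (t - manifest.t0) / 3600.0
    return f.base_c + f.gradient_c_per_km * east_km + f.warming_c_per_hour * hours


def sample_field(fix: GeoFix, manifest: FixtureManifest) -> float:
    """Noiseless true water temperature at a position and time (degC)."""
    return float(
        _field_values(
            np.array([fix.t]), np.array([fix.lat]), np.array([fix.lon]), manifest
        )[0]
    )


def quantize_ds18b20(temp):
    """Snap to the DS18B20 1/16 degC lattice; ties round toward +inf."""
    temp = np.asarray(temp, dtype=float)
    if np.any(temp < TEMP_RANGE_C[0]) or np.any(temp > TEMP_RANGE_C[1]):
        raise SensorRangeError("temperature outside DS18B20 range [-55, 125] degC")
    q = np.floor(temp / TEMP_STEP_C + 0.5) * TEMP_STEP_C
    return float(q) if q.ndim == 0 else q


def _apply_excursions(
    t: np.ndarray, water: np.ndarray, manifest: FixtureManifest
) -> tuple[np.ndarray, np.ndarray]:
    """Replace water temps with air-temperature ramps inside excursions.

    Returns (temps, in_water mask).  In air the probe relaxes toward
    the air temperature with ``tau_up_s``; back in the water it relaxes
    to the field with ``tau_down_s``.
    """
    e = manifest.excursions
    out = water.copy()
    in_water = np.ones(len(t), dtype=bool)
    for start_rel, end_rel in e.intervals:
        s = manifest.t0 + start_rel
        en = manifest.t0 + end_rel
        mask = (t >= s) & (t <= en)
        if not np.any(mask):
            continue
        in_water &= ~mask
        w_s = water[mask][0]
        out[mask] = e.air_temp_c + (w_s - e.air_temp_c) * np.exp(
            -(t[mask] - s) / e.tau_up_s
        )
        after = t > en
        if np.any(after):
            t_e = t[mask][-1]
            v_e = out[mask][-1]
            decay = (v_e - water[after]) * np.exp(-(t[after] - t_e) / e.tau_down_s)
            out[after] = water[after] + decay
            # relaxation tail is only meaningful until the next excursion;
            # later excursions overwrite it on their own pass
    return out, in_water


def generate_log(manifest: FixtureManifest) -> tuple[TripLog, FixtureManifest]:
    """Generate the full sensor log and fill in the ground truth.

    Both channels see the same water field (and the same excursion
    ramps) with independent Gaussian noise, clipped at +-0.5 degC to
    honour the sensor's stated accuracy, then DS18B20-quantized.
    Ground truth records the noiseless field statistics over in-water
    records, the excursion intervals, and the session boundaries.
    """
    fixes = simulate_track(manifest)
    t = np.array([f.t for f in fixes])
    lat = np.array([f.lat for f in fixes])
    lon = np.array([f.lon for f in fixes])

    keep = np.zeros(len(t), dtype=bool)
    bounds = []
    for s, e in session_windows(manifest):
        m = (t >= s) & (t <= e)
        keep |= m
        bounds.append((float(t[m][0]), float(t[m][-1])))
    t, lat, lon = t[keep], lat[keep], lon[keep]

    water = _field_values(t, lat, lon, manifest)
    probed, in_water = _apply_excursions(t, water, manifest)

    sd = manifest.field.noise_sd_c
    channels = []
    for sub in (_SUB_NOISE_A, _SUB_NOISE_B):
        rng = manifest.rng(sub)
        noise = np.clip(rng.normal(0.0, sd, size=len(t)), -0.5, 0.5) if sd > 0 else 0.0
        channels.append(quantize_ds18b20(probed + noise))

    log = TripLog.from_arrays(
        t=t, lat=lat, lon=lon, temp_a=channels[0], temp_b=channels[1],
        kayak_id=f"synthetic-{manifest.seed}", nominal_rate=None,
    )

    truth = GroundTruth(
        field_min_c=float(np.min(water[in_water])),
        field_max_c=float(np.max(water[in_water])),
        field_mean_c=float(np.mean(water[in_water])),
        n_records=int(len(t)),
        session_bounds=bounds,
        excursions=[
            (manifest.t0 + a, manifest.t0 + b) for a, b in manifest.excursions.intervals
        ],
        segment_spl_db=list(manifest.ground_truth.segment_spl_db),
    )
    truth.validate()
    out = dataclasses.replace(manifest, ground_truth=truth)
    return log, out


# ---------------------------------------------------------------------------
# Soundscape
# ---------------------------------------------------------------------------

def synth_soundscape(
    manifest: FixtureManifest,
    rate: float = 44_100.0,
    band: tuple[float, float] = (10.0, 20_000.0),
) -> tuple["AudioClip", pd.DataFrame]:
    """Synthesize the soundscape and its per-segment true levels.

    The clip is the sum of stationary Gaussian flow noise (level per
    segment), fixed boat-noise tones, and Poisson-timed 1 ms
    raised-cosine broadband clicks (a minimal snapping-shrimp
    surrogate).  The returned table gives each segment's true
    band-limited relative SPL, computed analytically from the component
    powers weighted by the analysis filter's squared (forward-backward)
    magnitude response — tones by the response at their line frequency,
    broadband components by the filter's equivalent noise bandwidth.
    """
    from .acoustics import AudioClip, Band, band_power_fraction, _design_sos
    from scipy import signal as _sig

    p = manifest.soundscape
    nyq = rate / 2.0
    if max(p.tone_freqs_hz, default=0.0) * 2.0 > rate:
        raise ParameterError("tone frequency above Nyquist")

    seg_durs = [float(d) for d, _ in p.segments]
    seg_levels = [float(l) for _, l in p.segments]
    n_total = int(round(sum(seg_durs) * rate))
    tvec = np.arange(n_total) / rate

    # flow noise, level switching per segment
    rng_noise = manifest.rng(_SUB_SOUND_NOISE)
    white = rng_noise.standard_normal(n_total)
    sigma = np.empty(n_total)
    edges = np.concatenate([[0.0], np.cumsum(seg_durs)])
    for k, level in enumerate(seg_levels):
        i0, i1 = int(round(edges[k] * rate)), int(round(edges[k + 1] * rate))
        sigma[i0:i1] = 10.0 ** (level / 20.0)
    x = white * sigma

    # boat tones with seeded phases
    rng_phase = manifest.rng(_SUB_SOUND_PHASE)
    phases = rng_phase.uniform(0, 2 * np.pi, size=len(p.tone_freqs_hz))
    for f0, level, phi in zip(p.tone_freqs_hz, p.tone_levels_db, phases):
        amp = math.sqrt(2.0) * 10.0 ** (level / 20.0)
        x += amp * np.sin(2 * np.pi * f0 * tvec + phi)

    # Poisson shrimp clicks: raised-cosine envelope on broadband noise
    rng_clicks = manifest.rng(_SUB_SOUND_CLICKS)
    n_click = max(3, int(round(p.click_dur_s * rate)))
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_click) / n_click))
    n_events = rng_clicks.poisson(p.click_rate_hz * sum(seg_durs))
    starts = np.sort(rng_clicks.uniform(0, sum(seg_durs), size=n_events))
    for s in starts:
        i0 = int(round(s * rate))
        i1 = min(n_total, i0 + n_click)
        if i1 > i0:
            burst = p.click_amp * env[: i1 - i0] * rng_clicks.standard_normal(i1 - i0)
            x[i0:i1] += burst

    # analytic per-segment truth
    b = Band(*band)
    frac = band_power_fraction(b, rate)
    sos = _design_sos(b, rate)
    _, h = _sig.sosfreqz(sos, worN=np.asarray(p.tone_freqs_hz, dtype=float), fs=rate)
    tone_gain4 = np.abs(h) ** 4
    p_tones = sum(
        (math.sqrt(2.0) * 10.0 ** (level / 20.0)) ** 2 / 2.0 * g4
        for level, g4 in zip(p.tone_levels_db, tone_gain4)
    )
    p_click = p.click_rate_hz * p.click_amp**2 * float(np.mean(env**2)) * p.click_dur_s
    rows = []
    for k, (dur, level) in enumerate(zip(seg_durs, seg_levels)):
        p_noise = (10.0 ** (level / 20.0)) ** 2
        p_total = p_tones + (p_noise + p_click) * frac
        rows.append(
            {
                "t_start": float(edges[k]),
                "t_end": float(edges[k + 1]),
                "spl_db_true": 10.0 * math.log10(p_total),
            }
        )
    truth = pd.DataFrame(rows)
    return AudioClip(rate=rate, samples=x, t0=0.0), truth


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

def generate_fixture_set(manifest: FixtureManifest, outdir) -> dict:
    """Write CSV log + WAV soundscape + ground-truth JSON sidecar.

    Returns a mapping of artefact name to path.
    """
    from .acoustics import write_wav
    from .core import write_sensor_log

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log, filled = generate_log(manifest)
    clip, spl_truth = synth_soundscape(manifest)

    csv_path = outdir / "sensor_log.csv"
    wav_path = outdir / "soundscape.wav"
    truth_path = outdir / "ground_truth.json"

    write_sensor_log(log, csv_path)
    write_wav(clip, wav_path)
    truth = dataclasses.asdict(filled.ground_truth)
    truth["segment_spl_db"] = spl_truth.to_dict(orient="records")
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return {"csv": csv_path, "wav": wav_path, "truth": truth_path}
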