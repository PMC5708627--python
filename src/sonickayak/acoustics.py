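"""Hydrophone signal analysis.

Implements the broadband sound-level pipeline used on kayak hydrophone
recordings: band-limiting (10 Hz - 20 kHz by default), root-mean-square
sound pressure level per paused-paddling segment, Welch power spectra,
and tonal peak detection for vessel-noise lines.

Levels are reported either *absolute* in dB re 1 uPa — which requires a
hydrophone sensitivity (uPa per count) — or *relative* in dB re digital
full scale, where only level differences are physically meaningful.
The filter is a 4th-order Butterworth band-pass applied forward and
backward (zero phase), the standard bioacoustics choice when only the
band is specified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.io import wavfile as _wav

from .core import AudioClip, Segment, TripLog, track_speed
from .errors import (
    BandError,
    CoverageError,
    ParameterError,
    SilenceError,
    UnitError,
)

#: Reference pressure for absolute underwater SPL, micropascal.
P_REF_UPA = 1.0

#: Analysis band used throughout the package unless overridden.
DEFAULT_BAND = (10.0, 20_000.0)

FILTER_ORDER = 4


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi] in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise BandError(f"invalid band [{self.f_lo}, {self.f_hi}] Hz")

    def validate_for(self, rate: float) -> None:
        if self.f_hi > rate / 2.0:
            raise BandError(
                f"band upper edge {self.f_hi} Hz exceeds Nyquist {rate / 2.0} Hz"
            )


@dataclass(frozen=True)
class CalibrationSpec:
    """How raw counts map to pressure.

    ``absolute`` mode needs ``uPa_per_count`` (hydrophone sensitivity);
    ``relative`` mode references digital full scale (sample value 1.0 is
    0 dBFS), so all relative SPLs of in-range signals are <= 0 dB.
    """

    mode: str = "relative"
    uPa_per_count: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise UnitError(f"unknown calibration mode {self.mode!r}")
        if self.mode == "absolute":
            if self.uPa_per_count is None or self.uPa_per_count <= 0:
                raise UnitError("absolute mode requires uPa_per_count > 0")


@dataclass(frozen=True)
class SplResult:
    """Broadband RMS level for one segment."""

    segment: Segment
    spl_db: float
    band: Band
    mode: str


@dataclass(frozen=True)
class SpectralPeak:
    """A tonal line: frequency and prominence above the local background."""

    freq: float
    prominence: float


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided Welch PSD.  ``psd`` is linear (units^2 / Hz)."""

    freq: np.ndarray
    psd: np.ndarray
    rate: float

    @property
    def psd_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.psd)

    @property
    def df(self) -> float:
        return float(self.freq[1] - self.freq[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freq, "psd_db": self.psd_db})


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def read_wav(path, t0: float = 0.0, cal: Optional[float] = None) -> AudioClip:
    """Read a WAV file (PCM16/24/32 or float) as a full-scale float clip.

    Multichannel files use the first channel.  24-bit PCM arrives from
    scipy as int32 and is scaled accordingly.
    """
    rate, data = _wav.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    dtype = data.dtype
    if dtype in _INT_SCALE:
        if dtype == np.dtype("uint8"):
            data = (data.astype(np.float64) - 128.0) / _INT_SCALE[dtype]
        else:
            data = data.astype(np.float64) / _INT_SCALE[dtype]
    else:
        data = data.astype(np.float64)
    return AudioClip(rate=float(rate), samples=data, t0=t0, cal=cal)


def write_wav(clip: AudioClip, path) -> None:
    """Write a clip as 32-bit float WAV."""
    _wav.write(path, int(round(clip.rate)), clip.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# Filtering and levels
# ---------------------------------------------------------------------------

def _design_sos(band: Band, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if band.f_hi >= nyq * (1.0 - 1e-9):
        # band extends to Nyquist: high-pass only
        return _sig.butter(FILTER_ORDER, band.f_lo, btype="highpass", fs=rate, output="sos")
    return _sig.butter(
        FILTER_ORDER, (band.f_lo, band.f_hi), btype="bandpass", fs=rate, output="sos"
    )


def bandlimit(clip: AudioClip, band: Band) -> AudioClip:
    """Zero-phase Butterworth band-pass; same rate, length and timing."""
    band.validate_for(clip.rate)
    sos = _design_sos(band, clip.rate)
    filtered = _sig.sosfiltfilt(sos, clip.samples)
    return AudioClip(rate=clip.rate, samples=filtered, t0=clip.t0, cal=clip.cal)


def band_power_fraction(band: Band, rate: float, n_freq: int = 4096) -> float:
    """Fraction of white-noise power passed by the analysis filter.

    The equivalent noise bandwidth of the Butterworth design divided by
    the Nyquist bandwidth, from the integrated squared magnitude
    response.  Used by the synthetic-soundscape ground truth so analytic
    in-band levels refer to the same filter the analysis applies
    (forward-backward, hence |H|^4).
    """
    band.validate_for(rate)
    sos = _design_sos(band, rate)
    w, h = _sig.sosfreqz(sos, worN=n_freq, fs=rate)
    mag4 = np.abs(h) ** 4  # filtfilt applies the filter twice
    return float(np.trapezoid(mag4, w) / (rate / 2.0))


def _pressure_scale(clip: AudioClip, cal: CalibrationSpec) -> float:
    if cal.mode == "absolute":
        factor = clip.cal if clip.cal is not None else cal.uPa_per_count
        if factor is None or factor <= 0:
            raise UnitError("absolute mode requires a uPa-per-count factor")
        return factor
    return 1.0


def spl_rms(clip: AudioClip, cal: CalibrationSpec, band: Band) -> SplResult:
    """Broadband RMS sound level of a clip after band-limiting.

    SPL = 20 log10(p_rms / p_ref), p_ref = 1 uPa (absolute) or digital
    full scale (relative).  One RMS is computed over the whole clip.

    Raises :class:`SilenceError` on a digitally silent input rather than
    returning -inf, so dead channels fail loudly.
    """
    if not np.any(clip.samples):
        raise SilenceError("clip is digitally silent")
    filtered = bandlimit(clip, band)
    scale = _pressure_scale(clip, cal)
    p_rms = float(np.sqrt(np.mean((filtered.samples * scale) ** 2)))
    if p_rms == 0.0:
        raise SilenceError("clip is silent within the analysis band")
    ref = P_REF_UPA if cal.mode == "absolute" else 1.0
    seg = Segment(t_start=clip.t0, t_end=clip.t_end, label="trip")
    return SplResult(
        segment=seg, spl_db=20.0 * np.log10(p_rms / ref), band=band, mode=cal.mode
    )


def segment_pauses(
    log: TripLog, speed_thresh: float = 0.2, min_dur: float = 30.0
) -> list[Segment]:
    """Maximal paused-paddling intervals: speed below threshold for at
    least ``min_dur`` seconds.  Non-overlapping, time-ordered."""
    v = track_speed(log)
    t = log.t
    segments: list[Segment] = []
    i = 0
    n = len(v)
    while i < n:
        if v[i] < speed_thresh:
            j = i
            while j + 1 < n and v[j + 1] < speed_thresh:
                j += 1
            if j > i and t[j] - t[i] >= min_dur:
                segments.append(Segment(t_start=t[i], t_end=t[j], label="paused"))
            i = j + 1
        else:
            i += 1
    return segments


def segment_spl(
    clip: AudioClip,
    segments: Sequence[Segment],
    cal: CalibrationSpec,
    band: Band,
) -> list[SplResult]:
    """One :func:`spl_rms` per segment, on the audio strictly inside it."""
    results = []
    for seg in segments:
        if seg.t_end <= clip.t0 or seg.t_start >= clip.t_end:
            raise CoverageError(
                f"segment [{seg.t_start}, {seg.t_end}] outside clip span "
                f"[{clip.t0}, {clip.t_end}]"
            )
        i0 = max(0, int(np.ceil((seg.t_start - clip.t0) * clip.rate)))
        i1 = min(clip.samples.size, int(np.floor((seg.t_end - clip.t0) * clip.rate)))
        if i1 <= i0:
            raise CoverageError(f"segment [{seg.t_start}, {seg.t_end}] contains no samples")
        sub = AudioClip(
            rate=clip.rate,
            samples=clip.samples[i0:i1],
            t0=clip.t0 + i0 / clip.rate,
            cal=clip.cal,
        )
        r = spl_rms(sub, cal, band)
        results.append(SplResult(segment=seg, spl_db=r.spl_db, band=band, mode=cal.mode))
    return results


def spl_range(results: Sequence[SplResult]) -> float:
    """Span max - min of a set of levels sharing one mode and band."""
    if not results:
        raise ParameterError("spl_range requires at least one result")
    modes = {r.mode for r in results}
    bands = {r.band for r in results}
    if len(modes) > 1 or len(bands) > 1:
        raise UnitError("spl_range requires uniform calibration mode and band")
    levels = [r.spl_db for r in results]
    return max(levels) - min(levels)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def power_spectrum(clip: AudioClip, res_hz: float = 1.0) -> PowerSpectrum:
    """Averaged one-sided Welch PSD at <= ``res_hz`` resolution.

    Hann window, 50% overlap, no detrending (so the integrated density
    is Parseval-consistent with the time-domain mean square).
    """
    if res_hz <= 0:
        raise ParameterError("res_hz must be positive")
    if clip.duration < 2.0 / res_hz:
        raise ParameterError(
            f"clip too short ({clip.duration:.3f}s) for {res_hz} Hz resolution"
        )
    if not np.any(clip.samples):
        raise SilenceError("clip is digitally silent")
    nperseg = int(round(clip.rate / res_hz))
    freq, psd = _sig.welch(
        clip.samples,
        fs=clip.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return PowerSpectrum(freq=freq, psd=psd, rate=clip.rate)


def detect_tonal_peaks(
    psd: PowerSpectrum, band: Band, min_prom_db: float = 10.0
) -> list[SpectralPeak]:
    """Spectral lines within ``band`` with prominence >= ``min_prom_db``,
    sorted by descending prominence."""
    mask = (psd.freq >= band.f_lo) & (psd.freq <= band.f_hi)
    if not np.any(mask):
        raise BandError("PSD does not cover the requested band")
    levels = psd.psd_db[mask]
    freqs = psd.freq[mask]
    idx, props = _sig.find_peaks(levels, prominence=min_prom_db)
    peaks = [
        SpectralPeak(freq=float(freqs[i]), prominence=float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    peaks.sort(key=lambda p: -p.prominence)
    return peaks


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[SplResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_start": [r.segment.t_start for r in results],
            "t_end": [r.segment.t_end for r in results],
            "label": [r.segment.label for r in results],
            "spl_db": [r.spl_db for r in results],
            "f_lo_hz": [r.band.f_lo for r in results],
            "f_hi_hz": [r.band.f_hi for r in results],
            "mode": [r.mode for r in results],
        }
    )


def results_to_geojson(
    results: Sequence[SplResult], log: TripLog, dest=None
) -> dict:
    """Per-segment point features at the segment's midpoint position.

    Mirrors the per-segment sound-level map: each paused section becomes
    a Point (WGS84 lon-lat) with an ``spl_db`` property.
    """
    features = []
    for r in results:
        tm = 0.5 * (r.segment.t_start + r.segment.t_end)
        lat = float(np.interp(tm, log.t, log.lat))
        lon = float(np.interp(tm, log.t, log.lon))
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": {
                    "t_start": r.segment.t_start,
                    "t_end": r.segment.t_end,
                    "spl_db": r.spl_db,
                    "mode": r.mode,
                    "band_hz": [r.band.f_lo, r.band.f_hi],
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if dest is not None:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(fc, fh)
    return fc
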