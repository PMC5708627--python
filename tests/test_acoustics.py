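import numpy as np
import pytest

from sonickayak import acoustics as ac
from sonickayak.core import AudioClip, Segment
from sonickayak.errors import (
    BandError,
    CoverageError,
    ParameterError,
    SilenceError,
    UnitError,
)

from conftest import eastward_log, make_log

RATE = 44_100.0
BAND = ac.Band(10.0, 20_000.0)
REL = ac.CalibrationSpec("relative")
ABS1 = ac.CalibrationSpec("absolute", uPa_per_count=1.0)


def sine(freq, amp=1.0, dur=3.0, rate=RATE, t0=0.0):
    t = np.arange(int(dur * rate)) / rate
    return AudioClip(rate=rate, samples=amp * np.sin(2 * np.pi * freq * t), t0=t0)


# ---------------------------------------------------------------------------
# Band-limiting
# ---------------------------------------------------------------------------

def test_bandlimit_preserves_in_band_sine():
    clip = sine(1000.0, amp=0.5)
    out = ac.bandlimit(clip, BAND)
    in_rms = np.sqrt(np.mean(clip.samples**2))
    out_rms = np.sqrt(np.mean(out.samples**2))
    assert 20 * np.log10(out_rms / in_rms) == pytest.approx(0.0, abs=0.1)
    assert out.samples.size == clip.samples.size
    assert out.rate == clip.rate


def test_bandlimit_attenuates_out_of_band_sine():
    clip = sine(5.0, dur=10.0)
    out = ac.bandlimit(clip, BAND)
    # ignore filtfilt edge transients
    n = out.samples.size
    core_rms = np.sqrt(np.mean(out.samples[n // 4 : -n // 4] ** 2))
    assert 20 * np.log10(core_rms / np.sqrt(0.5)) < -40.0


def test_bandlimit_removes_dc_offset():
    t = np.arange(int(2 * RATE)) / RATE
    clip = AudioClip(rate=RATE, samples=0.3 + 0.1 * np.sin(2 * np.pi * 500 * t))
    out = ac.bandlimit(clip, BAND)
    assert abs(np.mean(out.samples)) < 1e-3


def test_bandlimit_rejects_band_above_nyquist():
    clip = sine(100.0, rate=8000.0)
    with pytest.raises(BandError):
        ac.bandlimit(clip, ac.Band(10.0, 5000.0))


# ---------------------------------------------------------------------------
# SPL
# ---------------------------------------------------------------------------

def test_spl_of_reference_amplitude_sine_is_zero_db():
    # amplitude sqrt(2) uPa -> p_rms = 1 uPa -> 0 dB re 1 uPa
    clip = sine(1000.0, amp=np.sqrt(2.0))
    r = ac.spl_rms(clip, ABS1, BAND)
    assert r.spl_db == pytest.approx(0.0, abs=0.05)
    assert r.mode == "absolute"


def test_spl_of_two_micropascal_sine():
    r = ac.spl_rms(sine(1000.0, amp=2.0), ABS1, BAND)
    assert r.spl_db == pytest.approx(20 * np.log10(np.sqrt(2.0)), abs=0.05)


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_spl_amplitude_scaling_law(k):
    rng = np.random.default_rng(11)
    x = rng.normal(0, 0.01, int(2 * RATE))
    base = ac.spl_rms(AudioClip(rate=RATE, samples=x), REL, BAND).spl_db
    scaled = ac.spl_rms(AudioClip(rate=RATE, samples=k * x), REL, BAND).spl_db
    assert scaled - base == pytest.approx(20 * np.log10(k), abs=0.01)


def test_spl_silence_is_a_hard_error():
    clip = AudioClip(rate=RATE, samples=np.zeros(1000))
    with pytest.raises(SilenceError):
        ac.spl_rms(clip, REL, BAND)


def test_spl_band_monotonicity():
    """Widening the band never decreases broadband level by more than
    the filter tolerance."""
    rng = np.random.default_rng(3)
    clip = AudioClip(rate=RATE, samples=rng.normal(0, 0.01, int(3 * RATE)))
    narrow = ac.spl_rms(clip, REL, ac.Band(100.0, 5000.0)).spl_db
    wide = ac.spl_rms(clip, REL, ac.Band(10.0, 20000.0)).spl_db
    assert wide >= narrow - 0.1


# ---------------------------------------------------------------------------
# Pause segmentation
# ---------------------------------------------------------------------------

def test_constant_speed_track_has_no_pauses():
    log = eastward_log(n=300, speed_mps=1.5)
    assert ac.segment_pauses(log, speed_thresh=0.2, min_dur=30.0) == []


def test_single_stationary_span_is_one_segment():
    # 60 s stationary, then motion at 1.5 m/s
    deg = 1.5 / (np.pi / 180 * 6_371_000 * np.cos(np.radians(50.0)))
    t = np.arange(180.0)
    lon = -5.0 + deg * np.maximum(0.0, t - 60.0)
    log = make_log(t, lat=np.full(180, 50.0), lon=lon)
    segs = ac.segment_pauses(log, speed_thresh=0.2, min_dur=30.0)
    assert len(segs) == 1
    # brute-force per-sample check: slow samples within +-2 samples of segment
    v = np.array([0.0] * 60 + [1.5] * 120)
    slow = np.where(v < 0.2)[0]
    assert abs(segs[0].t_start - t[slow[0]]) <= 2.0
    assert abs(segs[0].t_end - t[slow[-1]]) <= 2.0


def test_short_stationary_span_fails_duration_gate():
    deg = 1.5 / (np.pi / 180 * 6_371_000 * np.cos(np.radians(50.0)))
    t = np.arange(120.0)
    lon = -5.0 + deg * np.maximum(0.0, t - 10.0)
    log = make_log(t, lat=np.full(120, 50.0), lon=lon)
    assert ac.segment_pauses(log, speed_thresh=0.2, min_dur=30.0) == []


# ---------------------------------------------------------------------------
# Per-segment SPL
# ---------------------------------------------------------------------------

def test_equal_noise_segments_give_equal_spl():
    rng = np.random.default_rng(7)
    block = rng.normal(0, 0.01, int(5 * RATE))
    clip = AudioClip(rate=RATE, samples=np.concatenate([block, block]))
    segs = [Segment(0.0, 5.0, "paused"), Segment(5.0, 10.0, "paused")]
    r = ac.segment_spl(clip, segs, REL, BAND)
    assert r[0].spl_db == pytest.approx(r[1].spl_db, abs=0.1)


def test_ten_db_level_step_is_recovered():
    rng = np.random.default_rng(8)
    lo = rng.normal(0, 0.01, int(10 * RATE))
    hi = rng.normal(0, 0.01 * 10 ** 0.5, int(10 * RATE))
    clip = AudioClip(rate=RATE, samples=np.concatenate([lo, hi]))
    r = ac.segment_spl(
        clip, [Segment(0, 10, "paused"), Segment(10, 20, "paused")], REL, BAND
    )
    assert r[1].spl_db - r[0].spl_db == pytest.approx(10.0, abs=0.3)


def test_whole_clip_segment_equals_spl_rms():
    rng = np.random.default_rng(9)
    clip = AudioClip(rate=RATE, samples=rng.normal(0, 0.01, int(4 * RATE)))
    whole = ac.spl_rms(clip, REL, BAND).spl_db
    seg = ac.segment_spl(clip, [Segment(0.0, 4.0, "trip")], REL, BAND)[0].spl_db
    assert seg == pytest.approx(whole, abs=1e-9)


def test_segment_outside_clip_is_coverage_error():
    clip = sine(1000.0, dur=2.0)
    with pytest.raises(CoverageError):
        ac.segment_spl(clip, [Segment(10.0, 12.0, "paused")], REL, BAND)


def test_segment_additivity():
    """N equal-level equal-length segments concatenated have the same
    level as each segment."""
    rng = np.random.default_rng(10)
    blocks = [rng.normal(0, 0.01, int(4 * RATE)) for _ in range(3)]
    clip = AudioClip(rate=RATE, samples=np.concatenate(blocks))
    per = ac.segment_spl(
        clip, [Segment(4.0 * i, 4.0 * (i + 1), "paused") for i in range(3)], REL, BAND
    )
    whole = ac.spl_rms(clip, REL, BAND).spl_db
    for r in per:
        assert r.spl_db == pytest.approx(whole, abs=0.1)


# ---------------------------------------------------------------------------
# SPL range
# ---------------------------------------------------------------------------

def _result(db, mode="relative", band=BAND):
    return ac.SplResult(Segment(0, 1, "paused"), db, band, mode)


def test_spl_range_arithmetic():
    assert ac.spl_range([_result(-50.0)]) == 0.0
    # the reported broadband span of the sound tests, as max - min
    assert ac.spl_range([_result(-60.0), _result(-45.4)]) == pytest.approx(14.6)


def test_spl_range_translation_invariance():
    vals = [-60.0, -52.5, -45.4]
    base = ac.spl_range([_result(v) for v in vals])
    shifted = ac.spl_range([_result(v + 7.3) for v in vals])
    assert shifted == pytest.approx(base)


def test_spl_range_rejects_mixed_modes():
    with pytest.raises(UnitError):
        ac.spl_range([_result(-60.0), _result(120.0, mode="absolute")])


# ---------------------------------------------------------------------------
# Spectra and peaks
# ---------------------------------------------------------------------------

def test_power_spectrum_peak_at_tone_frequency():
    psd = ac.power_spectrum(sine(1000.0, dur=4.0), res_hz=1.0)
    assert psd.freq[np.argmax(psd.psd)] == pytest.approx(1000.0, abs=1.0)


def test_power_spectrum_parseval_consistency():
    rng = np.random.default_rng(12)
    x = rng.normal(0, 0.01, int(5 * RATE))
    clip = AudioClip(rate=RATE, samples=x)
    psd = ac.power_spectrum(clip, res_hz=1.0)
    integrated = np.sum(psd.psd) * psd.df
    time_power = np.mean(x**2)
    assert 10 * np.log10(integrated / time_power) == pytest.approx(0.0, abs=0.1)


def test_power_spectrum_too_short_clip_errors():
    with pytest.raises(ParameterError):
        ac.power_spectrum(sine(1000.0, dur=0.5), res_hz=1.0)


def test_power_spectrum_silence_errors():
    with pytest.raises(SilenceError):
        ac.power_spectrum(AudioClip(rate=RATE, samples=np.zeros(int(3 * RATE))))


def test_tonal_peak_detected_at_engine_line():
    rng = np.random.default_rng(13)
    t = np.arange(int(8 * RATE)) / RATE
    noise = rng.normal(0, 0.01, t.size)
    # a 315 Hz line 20 dB above the local PSD floor
    noise_psd = 0.01**2 / (RATE / 2)
    amp = np.sqrt(2 * (10**2) * noise_psd * 1.0)  # 20 dB above floor at 1 Hz res
    clip = AudioClip(rate=RATE, samples=noise + amp * np.sin(2 * np.pi * 315 * t))
    psd = ac.power_spectrum(clip, res_hz=1.0)
    peaks = ac.detect_tonal_peaks(psd, ac.Band(200.0, 10_000.0), min_prom_db=10.0)
    assert peaks
    assert peaks[0].freq == pytest.approx(315.0, abs=1.0)


def test_white_noise_yields_no_tonal_peaks():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        clip = AudioClip(rate=RATE, samples=rng.normal(0, 0.01, int(4 * RATE)))
        psd = ac.power_spectrum(clip, res_hz=10.0)
        peaks = ac.detect_tonal_peaks(psd, ac.Band(200.0, 10_000.0), min_prom_db=10.0)
        assert peaks == []


def test_out_of_band_tone_is_excluded():
    clip = sine(50.0, dur=4.0)
    psd = ac.power_spectrum(clip, res_hz=1.0)
    peaks = ac.detect_tonal_peaks(psd, ac.Band(200.0, 10_000.0), min_prom_db=10.0)
    assert all(p.freq >= 200.0 for p in peaks)
    assert not any(abs(p.freq - 50.0) < 5 for p in peaks)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def test_results_geojson_places_points_at_segment_midpoints(tmp_path):
    log = eastward_log(n=100, speed_mps=1.0)
    r = [ac.SplResult(Segment(20.0, 40.0, "paused"), -50.0, BAND, "relative")]
    fc = ac.results_to_geojson(r, log, tmp_path / "spl.geojson")
    assert len(fc["features"]) == 1
    lon = fc["features"][0]["geometry"]["coordinates"][0]
    assert lon == pytest.approx(np.interp(30.0, log.t, log.lon))
    import json

    on_disk = json.loads((tmp_path / "spl.geojson").read_text())
    assert on_disk == fc
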