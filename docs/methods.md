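# Methods

This note documents the models, conventions and numerical choices
behind each module, what the synthetic generator does and does not
emulate, and the known limitations.

## Time, position and the sensor log

All timestamps are UTC float seconds (GPS time base); no local-time
handling exists anywhere. The canonical log is a comma-separated
UTF-8 CSV with header `time, lat, lon, temp_a, temp_b`, ISO 8601 `Z`
timestamps at millisecond precision, coordinates at 6 decimals
(~0.1 m) and temperatures at 4 decimals — enough to represent the
DS18B20's 1/16 °C lattice exactly, so write∘read is the identity on
canonical files. The reader is permissive: it accepts numeric
timestamps, drops unparseable or out-of-range rows, and counts them in
a parse report; a `column_map` argument supports deposits with other
header names.

Stream fusion joins each temperature sample to the nearest-in-time GPS
fix, ties broken toward the earlier fix, inclusive at exactly
`max_gap` (default 1.0 s, the nominal cadence). Distances use the
haversine formula on a sphere of radius 6 371 000 m; track speed is a
central difference (one-sided at the endpoints), which is robust to
1 s jitter but smooths instantaneous manoeuvres. Spatial binning and
the synthetic field use a local azimuthal-equirectangular tangent
plane about the track centroid, accurate well below the ~10 km extents
a kayak can cover; planar approximations are never used above that
scale.

## Acoustics

The analysis band defaults to 10 Hz – 20 kHz. Band-limiting is a
4th-order Butterworth band-pass applied forward-backward
(`sosfiltfilt`, zero phase, hence an |H|⁴ effective power response) —
the conventional choice in ambient-noise work when only a band is
specified. If the upper edge reaches Nyquist the filter degenerates to
a high-pass.

SPL is one RMS over the whole segment (not an average of sub-window
levels), `20·log10(p_rms/p_ref)`. Absolute mode requires a
µPa-per-count sensitivity and references 1 µPa; relative mode
references digital full scale (sample value 1.0 ≡ 0 dBFS), so
in-range signals report ≤ 0 dB and only level *differences* carry
physical meaning. Digital silence raises an error rather than
returning −∞, so dead channels fail loudly. Pause segmentation marks
maximal runs with speed below 0.2 m/s lasting ≥ 30 s; both thresholds
are exposed, and the defaults assume a smoothed (low-jitter) track.

Spectra use Welch's method: Hann window, segment length `rate/res_hz`
(1 s at the default 1 Hz resolution), 50 % overlap, no detrending, so
the integrated one-sided density is Parseval-consistent with the
time-domain mean square to well under 0.1 dB on stationary noise.
Tonal peaks are local PSD maxima with prominence ≥ 10 dB (in dB
space), restricted to the requested band and sorted by prominence.

## Thermal analytics

Out-of-water detection triggers when the selected channel rises at
least `rise_thresh` (default 2.0 °C) above the trailing-window minimum
(window 60 s), walks back to the rise onset, and ends when the
temperature returns within `rise_thresh/2` of that baseline. The
defaults are set so tidal warming of order 0.1 °C/min can never
trigger; they assume air is warmer than water, the situation in the
summer estuary deployments this models (a cold-air excursion would
need a sign-flipped detector).

Trip splitting cuts at recording gaps strictly greater than
`gap_thresh` (default 120 s) and removes out-of-water records, so the
concatenation of the parts preserves exactly the in-water records.
Summaries are plain arithmetic over the selected channel(s); the
default pools both thermometers, so `n` counts temperature values,
2 per record. Printed values truncate (not round) to 3 decimals:
17.6875 displays as 17.687, matching the truncation convention of
12-bit sensor values reported at 3 decimals; storage keeps full
precision. Grid cells are `floor(x/s), floor(y/s)` squares on the
tangent plane; replicate comparison requires a shared origin and cell
size and reports mean absolute difference and signed bias over cells
occupied in both grids. GeoJSON export writes cell polygons (WGS84
lon-lat, RFC 7946) with full-precision temperature properties — the
export round-trips exactly — and a `fill` colour interpolated linearly
from blue `#0000ff` (coldest cell mean) to red `#ff0000` (warmest).

## Sonification

The pitch mapping is the package's own design choice (the original
installations' sound design is not claimed): linear maps temperature
to frequency directly; exponential maps it to log-frequency so equal
temperature steps give equal musical intervals, with the mid-range
temperature landing on the geometric mean √(f_lo·f_hi). Out-of-range
temperatures clamp — clamping, not error, is the contract. Both laws
are monotone non-decreasing, preserving the higher-is-warmer
audification convention.

The renderer is offline and deterministic. Layer 1 integrates an
instantaneous frequency that follows channel-a temperature, updated
per record (1 Hz) and linearly interpolated between records to avoid
zipper noise. Layer 2 places the hydrophone clip at its own UTC
timestamp; no drift correction is attempted. Layer 3 derives
enter/exit events from per-fix circular-zone membership (boundary
inclusive, first-fix-inside rule for tracks starting within a zone);
loop mode tiles the sample over the active interval, once mode plays a
single pass; overlapping zones mix additively with no priority scheme.
The mix is scaled down to a −1 dBFS peak when it would exceed it
(never scaled up), so quiet mixes and the all-zero-gain case are
preserved verbatim. Zones are circles only; polygons are future work.

## Synthetic generator

The generator's defaults describe a plausible half-hour estuary
deployment: an 800 m-half-width bay, 1.2 m/s cruise with a
Gaussian-random-walk heading (σ = 0.08 rad/s) reflecting off the bay
walls, water at 18 °C with a 0.5 °C/km eastward gradient and
0.3 °C/h tidal warming, per-channel Gaussian sensor noise of
σ = 0.1 °C clipped at ±0.5 °C to honour the DS18B20's stated accuracy
bound, then 1/16 °C quantization with midpoints rounding toward +∞.
Out-of-water excursions relax toward 26 °C air with a 15 s time
constant and re-equilibrate in water with a 5 s constant. The
soundscape is three 12 s segments of Gaussian flow noise at −40, −35
and −30 dBFS under three boat-noise lines (315, 1250, 4000 Hz at −35,
−40, −45 dBFS) and Poisson snapping-shrimp clicks (0.5 s⁻¹, 1 ms
raised-cosine envelopes on broadband noise, amplitude 0.05) — a
minimal surrogate whose spectral realism is a non-goal. All
randomness flows from one manifest seed through fixed substream
indices, so regeneration is bit-identical and adding a component never
perturbs the others.

Ground-truth segment levels are computed analytically from component
powers, weighted by the *actual* analysis filter: tones by |H(f)|⁴ at
their line frequency, broadband components by the filter's equivalent
noise bandwidth (integrated |H|⁴ from the designed second-order
sections). A brickwall in-band fraction would disagree with the
Butterworth response by ~0.2 dB near Nyquist; tying the truth to the
filter design leaves only statistical error (< 0.05 dB at ≥ 10 s
segments). Click power enters as its expectation
(rate × per-click energy), kept ~20 dB below the noise floor so
realisation variance is negligible.

What the generator does *not* emulate: GPS jitter (tracks are smooth,
so the default 0.2 m/s pause threshold works; real receivers need
track smoothing first), oceanographically realistic temperature fields
(no fronts, stratification or tide curves beyond a linear trend),
propagation loss or vessel source spectra, multipath, and electrical
self-noise. Passing tests therefore demonstrate the correctness of
the algorithms under the stated statistical structure, not field
performance on raw receiver output.

## Problem sizes and numerical choices

Test fixtures use 5–15 minute tracks and 36–120 s soundscapes at
44.1 kHz; the acceptance script uses 20 seeds per stochastic check,
five random signals for the scaling law, and 900 s thermal fixtures —
sizes chosen so each check is decisive at its stated tolerance.
Degenerate inputs are hard errors: empty logs, digital silence,
non-positive cell sizes, bands above Nyquist, segments outside the
clip. Tie-breaks are fixed and tested: fusion ties to the earlier fix,
zone membership is boundary-inclusive, trip gaps split only when
strictly greater than the threshold, quantization midpoints round up.

## Known limitations

Real-deposit column layouts must be mapped via `read_sensor_log`'s
`column_map`; the reader does not auto-sniff. Absolute SPL requires an
externally supplied sensitivity — the package performs no calibration
measurement. The 60 s out-of-water window means excursions shorter
than a few samples, or logs shorter than the window, are not
classified. `segment_pauses` on jittery GPS tracks will under-detect
pauses unless the track is smoothed upstream.
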