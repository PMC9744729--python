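"""Conditioning and beat segmentation of arterial pressure recordings.

A raw radial blood-pressure waveform is detrended (mean and sub-0.5 Hz
respiratory/baseline drift removed, zero phase), pulse onsets are located at
the waveform foot — the local minimum immediately preceding each maximal
upstroke — and the recording is cut into onset-to-onset beats that are then
quality-controlled against the median beat period and the pointwise-median
beat shape.

The foot serves as the phase reference t=0 for all downstream harmonic
phase angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .exceptions import InsufficientBeatsError, NoBeatsError, ValidationError

#: Minimum recording length accepted for analysis, seconds.
MIN_ANALYSIS_SECONDS = 10.0
#: Corner of the low-pass used to estimate baseline drift, Hz. The drift
#: estimate is subtracted, so the detrended passband starts just above this.
DRIFT_CUTOFF_HZ = 0.3
#: Beats whose period deviates from the median by more than this fraction
#: are rejected.
PERIOD_BAND_FRACTION = 0.30
#: Minimum Pearson correlation with the pointwise-median beat.
MIN_BEAT_CORRELATION = 0.8
#: Minimum number of beats that must survive QC.
MIN_ACCEPTED_BEATS = 20
#: Fundamental heart-rate search band, Hz (30–180 bpm).
F0_BAND_HZ = (0.5, 3.0)


@dataclass
class Recording:
    """A uniformly sampled single-channel pressure recording.

    Parameters
    ----------
    samples:
        Pressure samples in arbitrary units.
    sampling_rate:
        Sampling rate in Hz.
    rr_intervals:
        Optional ECG R–R interval series in seconds, used for HR_CV. When
        absent, inter-onset intervals stand in.
    """

    samples: np.ndarray
    sampling_rate: float
    rr_intervals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if self.rr_intervals is not None:
            self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class BeatSegment:
    """One cardiac cycle, referenced to its onset (foot).

    ``samples`` hold the detrended waveform over the half-open span
    ``[onset_index, onset_index + len(samples))`` of the parent recording.
    ``raw_mean`` is the mean of the *raw* (pre-detrend) signal over the same
    span — the beat's DC pressure level, which detrending removes.
    """

    samples: np.ndarray
    onset_index: int
    period_s: float
    raw_mean: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("beat segment must be nonempty")
        if not self.period_s > 0:
            raise ValidationError("period_s must be positive")


def detrend_filter(recording: Recording) -> Recording:
    """Remove the mean and sub-0.5 Hz baseline drift, zero phase.

    The drift estimate is a forward-backward (zero-phase) 4th-order
    Butterworth low-pass at 0.3 Hz applied to the mean-removed signal; the
    output is the residual. The cardiac band (0.5–25 Hz) passes with
    amplitude error well under 5%, and beat feet are not shifted in time.
    """
    x = recording.samples
    fs = recording.sampling_rate
    if x.size < MIN_ANALYSIS_SECONDS * fs:
        raise ValidationError(
            f"recording shorter than {MIN_ANALYSIS_SECONDS:.0f} s of samples"
        )
    ac = x - x.mean()
    b, a = _sig.butter(4, DRIFT_CUTOFF_HZ / (fs / 2.0), btype="low")
    padlen = int(min(x.size - 1, 5 * fs))
    drift = _sig.filtfilt(b, a, ac, padlen=padlen)
    return Recording(ac - drift, fs, recording.rr_intervals)


def _fundamental_period_samples(x: np.ndarray, fs: float) -> float:
    """Estimate the cardiac period in samples from the periodogram peak."""
    f, pxx = _sig.periodogram(x, fs)
    band = (f >= F0_BAND_HZ[0]) & (f <= F0_BAND_HZ[1])
    if not band.any() or not np.any(pxx[band] > 0):
        raise NoBeatsError("no cardiac-band energy in recording")
    f0 = f[band][int(np.argmax(pxx[band]))]
    return fs / f0


def detect_pulse_onsets(recording: Recording) -> np.ndarray:
    """Locate one onset per cardiac cycle at the waveform foot.

    Maximal-upstroke points are peaks of the first difference exceeding an
    adaptive (scale-free) threshold. Each onset is the intersecting-tangent
    foot of its cycle: where the tangent at the maximal upstroke (on a
    lightly smoothed trace) crosses the horizontal line through the
    preceding minimum level. The minimum *level* and the upstroke slope
    are both well-conditioned even though the minimum *position* of a
    band-limited pulse is not. Cycles whose search window would start
    before the recording (first partial cycle) are dropped, as is any
    trailing cycle without a closing upstroke.

    Returns strictly increasing 0-based sample indices.
    """
    x = recording.samples
    fs = recording.sampling_rate
    if x.size < 2 or np.ptp(x) == 0:
        raise NoBeatsError("flat signal")
    period = _fundamental_period_samples(x, fs)
    d = np.gradient(x)
    height = 0.3 * np.quantile(d, 0.99)
    if height <= 0:
        raise NoBeatsError("no positive upstrokes")
    peaks, _ = _sig.find_peaks(d, height=height, distance=max(1, int(0.5 * period)))
    # smoothing suppresses sample noise in the slope and level estimates;
    # sub-sample residue of the tangent construction cancels downstream in
    # the phase re-referencing
    smooth_w = max(3, int(0.04 * period)) | 1
    xs = np.convolve(x, np.ones(smooth_w) / smooth_w, mode="same")
    ds = np.gradient(xs)
    max_walk = max(1, int(0.35 * period))
    rise_floor = 0.25 * float(np.quantile(xs, 0.99) - np.quantile(xs, 0.01))
    onsets: list[int] = []
    for p in peaks:
        lo = p - max_walk
        if lo < 0:
            continue  # partial first cycle
        y_min = float(xs[lo : p + 1].min())
        slope = float(ds[p])
        y_peak = float(xs[p : min(x.size, p + max(2, int(0.15 * period)))].max())
        if slope <= 0 or y_peak - y_min < rise_floor:
            continue  # not a systolic upstroke (e.g. noise blip in diastole)
        idx = int(round(p - (xs[p] - y_min) / slope))
        idx = max(lo, min(idx, p))
        if not onsets or idx > onsets[-1]:
            onsets.append(idx)
    if len(onsets) < 2:
        raise NoBeatsError("fewer than two pulse onsets found")
    return np.asarray(onsets, dtype=int)


def segment_and_qc(
    recording: Recording,
    onsets: np.ndarray,
    raw: np.ndarray | None = None,
    *,
    period_band: float = PERIOD_BAND_FRACTION,
    min_correlation: float = MIN_BEAT_CORRELATION,
    min_beats: int = MIN_ACCEPTED_BEATS,
) -> list[BeatSegment]:
    """Cut onset-to-onset beats and reject artifacts.

    A beat is rejected when its period deviates more than ``period_band``
    from the median period, or when its correlation with the
    pointwise-median beat (after length normalization to a common grid)
    falls below ``min_correlation``.

    Each accepted segment is boundary-conditioned: the sawtooth carrying
    the discontinuity of the segment's periodic extension — the smoothed
    level at the next onset minus that at this onset — is removed, mean
    level restored. Identical consecutive beats are untouched exactly,
    while the endpoint mismatch left by beat-to-beat variability, onset
    jitter or residual drift would otherwise leak the large low harmonics
    into the small high ones during spectral analysis.

    Parameters
    ----------
    raw:
        Optional raw (pre-detrend) sample array of the same length; when
        given, each segment's ``raw_mean`` is filled with the raw mean over
        the beat span.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        raise ValidationError("need at least two onsets to segment")
    x = recording.samples
    fs = recording.sampling_rate
    periods = np.diff(onsets)
    med = float(np.median(periods))

    smooth_w = max(3, int(0.04 * med)) | 1
    xs = np.convolve(x, np.ones(smooth_w) / smooth_w, mode="same")

    beats: list[BeatSegment] = []
    for i in range(periods.size):
        s, e = int(onsets[i]), int(onsets[i + 1])
        rm = float(raw[s:e].mean()) if raw is not None else None
        seg = x[s:e]
        jump = xs[e] - xs[s]
        ramp = jump * np.arange(seg.size) / seg.size
        beats.append(
            BeatSegment(seg - ramp + ramp.mean(), s, periods[i] / fs, raw_mean=rm)
        )

    period_ok = np.abs(periods - med) <= period_band * med

    # common-length resampling for the shape test
    grid_n = 100
    grid = np.arange(grid_n) / grid_n
    resampled = [
        np.interp(grid, np.arange(b.samples.size) / b.samples.size, b.samples)
        for b in beats
    ]
    ref = [r for r, ok in zip(resampled, period_ok) if ok]
    if not ref:
        raise InsufficientBeatsError("no beats inside the period band")
    template = np.median(np.stack(ref), axis=0)

    accepted: list[BeatSegment] = []
    for b, r, ok in zip(beats, resampled, period_ok):
        if not ok:
            continue
        if r.std() < 1e-12 or template.std() < 1e-12:
            continue
        if np.corrcoef(r, template)[0, 1] >= min_correlation:
            accepted.append(b)
    if len(accepted) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(accepted)} beats survived QC (need {min_beats})"
        )
    return accepted
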