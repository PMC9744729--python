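"""Per-beat harmonic spectra and the 40 spectral pulse indices plus HR_CV.

Each beat is expanded in harmonics of its own fundamental (1/period):

    x(t) = A0 + sum_{n=1..10} A_n cos(2 pi n t / T + phi_n),   t=0 at onset.

Per recording, four index families are aggregated over beats for n=1..10:

* ``Cn``    — amplitude proportion, the beat-mean of normalized ``A_n``;
* ``CVn``   — coefficient of variation (sample SD / mean) of per-beat ``Cn``;
* ``Pn``    — mean phase angle, degrees;
* ``Pn_SD`` — beat-to-beat SD of the phase angle, degrees;

plus ``HR_CV``, the coefficient of variation of instantaneous heart rate
(60/RR) from the R–R interval series.

Normalization of ``Cn`` is switchable. The default, ``"dc"``, divides each
harmonic amplitude by the beat's DC pressure level ``A0``; under this
convention every ``Cn`` can shift in the same direction between groups —
the pattern reported for possible sarcopenia. ``"sum"`` divides by the sum
of amplitudes 1–10 (so the ten proportions sum to one) and ``"fundamental"``
divides by ``A1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .exceptions import (
    DegenerateSpectrumError,
    InsufficientBeatsError,
    ResolutionError,
    ValidationError,
)
from .segmentation import (
    BeatSegment,
    Recording,
    detect_pulse_onsets,
    detrend_filter,
    segment_and_qc,
)

#: Number of harmonics carried per beat.
N_HARMONICS = 10
#: Power-of-two length each beat is resampled to (harmonic n falls on bin n).
RESAMPLE_N = 512
#: Minimum samples per beat required to resolve ten harmonics comfortably.
MIN_BEAT_SAMPLES = 40
#: Default amplitude-proportion convention; see module docstring.
DEFAULT_NORMALIZATION = "dc"

NORMALIZATIONS = ("dc", "sum", "fundamental")

#: Column names of the 40 spectral indices, family-major.
SPECTRAL_FEATURE_NAMES: list[str] = (
    [f"C{n}" for n in range(1, 11)]
    + [f"CV{n}" for n in range(1, 11)]
    + [f"P{n}" for n in range(1, 11)]
    + [f"P{n}_SD" for n in range(1, 11)]
)
FEATURE_NAMES: list[str] = SPECTRAL_FEATURE_NAMES + ["HR_CV"]


def wrap_phase(phase: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    w = np.mod(phase, 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w) if np.ndim(w) else (
        w - 2.0 * np.pi if w > np.pi else w
    )


@dataclass
class BeatSpectrum:
    """Harmonic decomposition of a single beat.

    ``amplitude`` has length 11 (index 0 is the DC level, which may be ~0
    for detrended beats without a raw reference); ``phase`` has length 10
    for harmonics 1–10, radians in (-pi, pi].
    """

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != (N_HARMONICS + 1,):
            raise ValidationError("amplitude must have entries for n=0..10")
        if self.phase.shape != (N_HARMONICS,):
            raise ValidationError("phase must have entries for n=1..10")
        if np.any(self.amplitude[1:] < 0):
            raise ValidationError("harmonic amplitudes must be nonnegative")


@dataclass
class FeatureVector:
    """The 40 spectral indices plus HR_CV for one recording."""

    c: np.ndarray
    cv: np.ndarray
    p_deg: np.ndarray
    p_sd_deg: np.ndarray
    hr_cv: float = field(default=np.nan)

    def __post_init__(self) -> None:
        for name in ("c", "cv", "p_deg", "p_sd_deg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_HARMONICS,):
                raise ValidationError(f"{name} must have ten entries")
            setattr(self, name, arr)
        if np.any(self.cv < 0) or np.any(self.p_sd_deg < 0):
            raise ValidationError("dispersions must be nonnegative")

    def to_series(self) -> pd.Series:
        values = np.concatenate(
            [self.c, self.cv, self.p_deg, self.p_sd_deg, [self.hr_cv]]
        )
        return pd.Series(values, index=FEATURE_NAMES)


def beat_harmonics(beat: BeatSegment, n_resample: int = RESAMPLE_N) -> BeatSpectrum:
    """Discrete Fourier analysis of one beat over exactly one period.

    The beat is resampled to ``n_resample`` points by band-limited (Fourier)
    interpolation, so harmonic ``n`` of the beat's own fundamental falls
    exactly on DFT bin ``n``. Cosine convention with t=0 at the onset. When
    the segment carries a ``raw_mean``, it replaces the DFT DC term (which
    detrending zeroes out).
    """
    y = np.asarray(beat.samples, dtype=float)
    if y.size < MIN_BEAT_SAMPLES:
        raise ResolutionError(
            f"beat has {y.size} samples; need >= {MIN_BEAT_SAMPLES}"
        )
    yr = _sig.resample(y, n_resample)
    spec = np.fft.rfft(yr)
    a0 = spec[0].real / n_resample
    amps = 2.0 * np.abs(spec[1 : N_HARMONICS + 1]) / n_resample
    phases = wrap_phase(np.angle(spec[1 : N_HARMONICS + 1]))
    if beat.raw_mean is not None:
        a0 = beat.raw_mean
    return BeatSpectrum(np.concatenate([[a0], amps]), np.asarray(phases))


def amplitude_proportions(
    spectrum: BeatSpectrum, normalization: str = DEFAULT_NORMALIZATION
) -> np.ndarray:
    """Normalize harmonic amplitudes 1–10 into the ``Cn`` proportions."""
    if normalization not in NORMALIZATIONS:
        raise ValidationError(f"unknown normalization {normalization!r}")
    harm = spectrum.amplitude[1:]
    total = float(harm.sum())
    if total <= 0:
        raise DegenerateSpectrumError("all harmonic amplitudes are zero")
    if normalization == "sum":
        denom = total
    elif normalization == "fundamental":
        denom = float(spectrum.amplitude[1])
        if denom <= 0:
            raise DegenerateSpectrumError("zero fundamental amplitude")
    else:
        denom = float(spectrum.amplitude[0])
        if denom <= 0:
            raise DegenerateSpectrumError(
                "nonpositive DC level; dc normalization needs the raw mean"
            )
    return harm / denom


def reconstruction_foot_shift(
    amplitudes: np.ndarray, phases: np.ndarray, grid_n: int = 4096
) -> float:
    """Sub-sample position (fraction of the period) of the waveform foot.

    The foot is the intersecting-tangent point of the one-period
    reconstruction from harmonics 1-10: where the tangent at the maximal
    upstroke crosses the horizontal line through the waveform minimum.
    Every ingredient (upstroke slope and level, minimum level) is
    well-conditioned, unlike the position of the minimum of a band-limited
    pulse, whose foot region is flat.

    Generator profiles and extracted recording spectra are both referenced
    to this same analytic functional, so the phase origin agrees between
    the two by construction — independent of where integer-sample beat
    onsets happened to land.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if not np.any(amplitudes > 0):
        return 0.0
    n_idx = np.arange(1, N_HARMONICS + 1)

    def wave(t):
        arg = 2.0 * np.pi * np.multiply.outer(t, n_idx) + phases
        return np.sum(amplitudes * np.cos(arg), axis=-1)

    def slope(t):
        arg = 2.0 * np.pi * np.multiply.outer(t, n_idx) + phases
        return np.sum(-amplitudes * 2.0 * np.pi * n_idx * np.sin(arg), axis=-1)

    t = np.arange(grid_n) / grid_n
    w = wave(t)
    d = slope(t)
    # parabolic refinement of the maximal-upstroke time
    k = int(np.argmax(d))
    dm, d0, dp = d[(k - 1) % grid_n], d[k], d[(k + 1) % grid_n]
    denom = dm - 2.0 * d0 + dp
    delta = 0.5 * (dm - dp) / denom if denom < 0 else 0.0
    t_up = (k + delta) / grid_n
    s_up = float(slope(np.array([t_up]))[0])
    if s_up <= 0:
        return 0.0
    y_up = float(wave(np.array([t_up]))[0])
    t_foot = t_up - (y_up - float(w.min())) / s_up
    return float(t_foot % 1.0)


def _unwrap_to_running_mean(phases: np.ndarray) -> np.ndarray:
    """Align each phase to the running mean by the nearest multiple of 2pi.

    Prevents the +/-pi seam from inflating arithmetic phase statistics.
    """
    out = np.empty_like(phases)
    out[0] = phases[0]
    mean = phases[0]
    for i in range(1, phases.size):
        q = phases[i] + 2.0 * np.pi * np.round((mean - phases[i]) / (2.0 * np.pi))
        out[i] = q
        mean += (q - mean) / (i + 1)
    return out


def recording_features(
    beats: list[BeatSpectrum],
    normalization: str = DEFAULT_NORMALIZATION,
    min_beats: int = 20,
    foot_rereference: bool = True,
) -> FeatureVector:
    """Aggregate per-beat spectra into the 40 spectral indices.

    ``Cn`` is the across-beat mean of per-beat proportions, ``CVn`` its
    sample (n-1) SD over mean. Phases are unwrapped across beats (nearest
    multiple of 2 pi to the running mean) before the arithmetic mean ``Pn``
    (mapped to [0, 360) degrees) and SD ``Pn_SD``. ``HR_CV`` is left NaN
    here; fill it from the R–R series via :func:`hr_cv`.

    With ``foot_rereference`` (the default), the recording's phase origin
    is moved to the sub-sample foot of the reconstructed mean beat
    (:func:`reconstruction_foot_shift`). Integer-sample onset placement
    then cancels out of the mean phase angles; the constant rotation
    leaves ``Pn_SD`` untouched.
    """
    if len(beats) < min_beats:
        raise InsufficientBeatsError(
            f"{len(beats)} beats; need >= {min_beats} for stable indices"
        )
    cmat = np.stack([amplitude_proportions(b, normalization) for b in beats])
    cmean = cmat.mean(axis=0)
    csd = cmat.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(cmean != 0, csd / cmean, 0.0)

    pmat = np.stack([b.phase for b in beats])
    punw = np.empty_like(pmat)
    for n in range(N_HARMONICS):
        punw[:, n] = _unwrap_to_running_mean(pmat[:, n])
    p_mean = punw.mean(axis=0)
    if foot_rereference:
        amean = np.stack([b.amplitude[1:] for b in beats]).mean(axis=0)
        shift = reconstruction_foot_shift(amean, p_mean)
        p_mean = p_mean + 2.0 * np.pi * np.arange(1, N_HARMONICS + 1) * shift
    # report the mean phase in [0, 360): foot-referenced pulse harmonics
    # cluster far from that seam, unlike the +/-180 one
    p_deg = np.degrees(np.mod(p_mean, 2.0 * np.pi))
    p_sd_deg = np.degrees(punw.std(axis=0, ddof=1))
    return FeatureVector(cmean, cv, p_deg, p_sd_deg)


def hr_cv(rr_intervals: np.ndarray) -> float:
    """Coefficient of variation of instantaneous heart rate.

    Each R–R interval is converted to a rate 60/RR (beats/min); the CV is
    the sample SD over the mean of that series. Scale-invariant in RR.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size < 2:
        raise ValidationError("need at least two R-R intervals")
    if np.any(rr <= 0):
        raise ValidationError("R-R intervals must be positive")
    hr = 60.0 / rr
    return float(hr.std(ddof=1) / hr.mean())


def extract_features(
    recording: Recording,
    normalization: str = DEFAULT_NORMALIZATION,
    n_resample: int = RESAMPLE_N,
) -> FeatureVector:
    """Full single-recording pipeline: detrend, segment, 41 indices.

    Onsets and QC run on the detrended signal; the raw signal supplies the
    per-beat DC level. HR_CV uses the recording's R–R series when present,
    otherwise the detected inter-onset intervals.
    """
    det = detrend_filter(recording)
    onsets = detect_pulse_onsets(det)
    beats = segment_and_qc(det, onsets, raw=recording.samples)
    spectra = [beat_harmonics(b, n_resample) for b in beats]
    fv = recording_features(spectra, normalization)
    if recording.rr_intervals is not None and recording.rr_intervals.size >= 2:
        rr = recording.rr_intervals
    else:
        rr = np.diff(onsets) / recording.sampling_rate
    fv.hr_cv = hr_cv(rr)
    return fv
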