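"""Physiological-waveform preprocessing: beats, HR, HRV, RV, PETCO2, breathing rate.

Raw recordings (PPG, respiration belt, capnograph) are reduced to TR-locked
timecourses aligned with the BOLD volume grid, plus per-scan heart-rate
variability (HRV) summary metrics.  Volume *i* is taken to occur at
``t = i * tr_s`` relative to the recording's time origin (``start_time_s``
shifts the recording against that grid).

Conventions used throughout:

* 6-second windows centered at each volume, clipped (never padded) at the
  recording edges;
* quantiles by linear interpolation of order statistics;
* natural-log transforms for RMSSD and LF/HF band powers in summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import interpolate, signal as sps, stats

from .errors import ConfigurationError, DataError

__all__ = [
    "PhysioRecording",
    "BeatSeries",
    "PhysioTimecourse",
    "HRVSummary",
    "detect_beats",
    "clean_ibi",
    "hr_timecourse",
    "hrv_metrics",
    "rv_timecourse",
    "normalize_rv",
    "breathing_rate",
    "align_capnograph",
    "petco2_timecourse",
    "iqr_screen",
]

Modality = Literal["ppg", "respiration", "capnograph"]
TimecourseKind = Literal["hr_bpm", "rv_norm", "petco2_mmHg", "breathing_rate_bpm"]


@dataclass
class PhysioRecording:
    """A uniformly sampled physiological waveform."""

    samples: np.ndarray
    fs: float  # Hz
    modality: Modality
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.samples)) / self.fs


@dataclass
class BeatSeries:
    """Detected heartbeats: beat times plus inter-beat intervals (IBIs)."""

    beat_times_s: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # per-interval, True = flagged
    quality_warning: bool = False

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise DataError("beat times must be strictly increasing")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(max(len(self.beat_times_s) - 1, 0), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)

    @property
    def ibi_s(self) -> np.ndarray:
        return np.diff(self.beat_times_s)

    @property
    def ibi_midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.beat_times_s[:-1] + self.beat_times_s[1:])


@dataclass
class PhysioTimecourse:
    """A TR-locked derived series with one value per BOLD volume."""

    values: np.ndarray
    tr_s: float
    kind: TimecourseKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")

    @property
    def n_vols(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_vols) * self.tr_s


@dataclass
class HRVSummary:
    """Scan-level autonomic summary metrics (log power in ln ms^2)."""

    ln_rmssd: float
    ln_lf: float
    ln_hf: float
    avg_hr_bpm: float
    sd_rv: Optional[float] = None
    breathing_rate_bpm: Optional[float] = None
    avg_co2_mmHg: Optional[float] = None
    power_flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# beat detection and IBI cleaning


def detect_beats(ppg: PhysioRecording) -> BeatSeries:
    """Detect heartbeats in a PPG recording.

    The waveform is zero-phase band-passed at 0.5–2 Hz (2nd-order Butterworth,
    forward-backward), and local maxima at least 5% of the filtered signal's
    interquartile range high and 0.25 s apart are taken as beats.
    """
    if ppg.modality != "ppg":
        raise DataError(f"detect_beats expects a ppg recording, got {ppg.modality}")
    if ppg.duration_s < 10.0:
        raise DataError("PPG recording shorter than 10 s")
    sos = sps.butter(2, [0.5, 2.0], btype="bandpass", fs=ppg.fs, output="sos")
    filt = sps.sosfiltfilt(sos, ppg.samples)
    height = 0.05 * stats.iqr(filt)
    peaks, _ = sps.find_peaks(filt, height=height, distance=max(int(round(0.25 * ppg.fs)), 1))
    if len(peaks) < 2:
        raise DataError("no cardiac rhythm detected")
    return BeatSeries(beat_times_s=ppg.start_time_s + peaks / ppg.fs)


def _running_median(x: np.ndarray, width: int) -> np.ndarray:
    half = width // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def clean_ibi(
    beats: BeatSeries,
    ibi_bounds_s: tuple[float, float] = (0.33, 2.0),
    mad_threshold: float = 3.0,
    median_width: int = 15,
) -> BeatSeries:
    """Flag and interpolate artifactual inter-beat intervals.

    Intervals outside ``ibi_bounds_s`` or deviating more than ``mad_threshold``
    scaled median absolute deviations from a running median are replaced by
    linear interpolation between neighboring valid intervals, and the beat
    times are rebuilt cumulatively from the first beat.
    """
    ibi = beats.ibi_s
    if len(ibi) < 4:
        raise DataError("clean_ibi requires at least 4 intervals")
    runmed = _running_median(ibi, median_width)
    resid = ibi - runmed
    mad = 1.4826 * np.median(np.abs(resid))
    bad = (ibi < ibi_bounds_s[0]) | (ibi > ibi_bounds_s[1])
    if mad > 0:
        bad |= np.abs(resid) > mad_threshold * mad
    quality_warning = False
    if bad.all():
        raise DataError("all inter-beat intervals flagged as artifacts")
    if bad.mean() > 0.5:
        warnings.warn("more than 50% of IBIs flagged as artifacts", stacklevel=2)
        quality_warning = True
    clean = ibi.copy()
    if bad.any():
        idx = np.arange(len(ibi))
        clean[bad] = np.interp(idx[bad], idx[~bad], ibi[~bad])
    times = beats.beat_times_s[0] + np.concatenate([[0.0], np.cumsum(clean)])
    return BeatSeries(beat_times_s=times, artifact_mask=bad, quality_warning=quality_warning)


# ---------------------------------------------------------------------------
# TR-locked timecourses


def _interp_nan(values: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(values)
    if bad.any():
        idx = np.arange(len(values))
        values = values.copy()
        values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return values


def hr_timecourse(
    beats: BeatSeries, tr_s: float, n_vols: int, window_s: float = 6.0
) -> PhysioTimecourse:
    """Heart rate per volume: 60 / median IBI in a 6 s window centered at the volume."""
    mids = beats.ibi_midpoints_s
    ibi = beats.ibi_s
    if len(ibi) == 0:
        raise DataError("no inter-beat intervals available")
    vol_t = np.arange(n_vols) * tr_s
    half = window_s / 2.0
    values = np.full(n_vols, np.nan)
    for i, t in enumerate(vol_t):
        sel = (mids >= t - half) & (mids <= t + half)
        if sel.any():
            values[i] = 60.0 / np.median(ibi[sel])
    if not np.isfinite(values).any():
        raise DataError("no IBIs fall within any volume window")
    if not np.isfinite(values).all():
        warnings.warn("empty HR windows interpolated from neighbors", stacklevel=2)
        values = _interp_nan(values)
    return PhysioTimecourse(values=values, tr_s=tr_s, kind="hr_bpm")


def rv_timecourse(
    resp: PhysioRecording, tr_s: float, n_vols: int, window_s: float = 6.0
) -> PhysioTimecourse:
    """Respiratory variation: windowed SD of the raw respiration waveform per volume."""
    if resp.modality != "respiration":
        raise DataError(f"rv_timecourse expects respiration, got {resp.modality}")
    t = resp.times_s
    vol_t = np.arange(n_vols) * tr_s
    half = window_s / 2.0
    values = np.empty(n_vols)
    for i, tv in enumerate(vol_t):
        sel = (t >= tv - half) & (t <= tv + half)
        values[i] = resp.samples[sel].std() if sel.any() else 0.0
    if np.all(values == 0):
        warnings.warn("constant respiration waveform: RV is zero everywhere", stacklevel=2)
    return PhysioTimecourse(values=values, tr_s=tr_s, kind="rv_norm")


def normalize_rv(rv: PhysioTimecourse, pct: tuple[float, float] = (1.45, 98.55)) -> PhysioTimecourse:
    """Normalize an RV series to approximately [-1, 1].

    Bounds are the empirical 1.45th/98.55th percentiles; the mean of in-bounds
    values is subtracted from the data and from both bounds, then positive
    values are divided by the adjusted upper bound and negative values by the
    magnitude of the adjusted lower bound.
    """
    v = rv.values
    lo, hi = np.percentile(v, pct)
    inb = (v >= lo) & (v <= hi)
    if not inb.any():
        raise DataError("degenerate RV distribution")
    m = v[inb].mean()
    vc, loc, hic = v - m, lo - m, hi - m
    if hic == 0 or loc == 0:
        raise DataError("degenerate RV distribution")
    out = np.where(vc >= 0, vc / hic, vc / abs(loc))
    return PhysioTimecourse(values=out, tr_s=rv.tr_s, kind="rv_norm")


def breathing_rate(resp: PhysioRecording, min_sep_s: float = 1.5, smooth_s: float = 0.5) -> float:
    """Breathing rate in breaths per minute from respiration-belt peaks."""
    if resp.duration_s < 30.0:
        raise DataError("breathing_rate requires at least 30 s of signal")
    width = max(int(round(smooth_s * resp.fs)), 1)
    kern = np.ones(width) / width
    smoothed = np.convolve(resp.samples - resp.samples.mean(), kern, mode="same")
    peaks, _ = sps.find_peaks(smoothed, distance=max(int(round(min_sep_s * resp.fs)), 1))
    if len(peaks) < 2:
        raise DataError("fewer than 2 respiration peaks detected")
    return len(peaks) / resp.duration_s * 60.0


def align_capnograph(
    co2: PhysioRecording, resp: PhysioRecording, max_shift_s: float
) -> float:
    """Find the capnograph delay by minimizing its correlation with respiration.

    Returns the shift (s) in [-max_shift_s, +max_shift_s], on a one-sample
    grid, at which the advanced capnograph trace is most anti-correlated with
    the respiration waveform.  Positive shift = capnograph delayed relative to
    respiration.
    """
    if max_shift_s <= 0:
        raise ConfigurationError("max_shift_s must be positive")
    if abs(co2.fs - resp.fs) > 1e-9:
        raise DataError("capnograph and respiration must share a sampling rate")
    x, y = co2.samples, resp.samples
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    kmax = int(round(max_shift_s * co2.fs))
    best_k, best_r = 0, np.inf
    for k in range(-kmax, kmax + 1):
        if k >= 0:
            xi, yi = x[k:], y[: n - k]
        else:
            xi, yi = x[: n + k], y[-k:]
        if len(xi) < 3 or xi.std() == 0 or yi.std() == 0:
            continue
        r = np.corrcoef(xi, yi)[0, 1]
        if r < best_r:
            best_r, best_k = r, k
    if best_r >= 0:
        warnings.warn("capnograph/respiration correlation never negative", stacklevel=2)
    return best_k / co2.fs


def petco2_timecourse(
    co2: PhysioRecording, shift_s: float, tr_s: float, n_vols: int, min_sep_s: float = 1.5
) -> PhysioTimecourse:
    """End-tidal CO2 per volume: breath-wise capnograph maxima interpolated to the TR grid."""
    k = int(round(shift_s * co2.fs))
    samples = co2.samples[k:] if k >= 0 else co2.samples[: len(co2.samples) + k]
    if len(samples) < 3:
        raise DataError("capnograph too short after alignment shift")
    t0 = co2.start_time_s if k >= 0 else co2.start_time_s - k / co2.fs
    peaks, _ = sps.find_peaks(samples, distance=max(int(round(min_sep_s * co2.fs)), 1))
    if len(peaks) < 2:
        raise DataError("fewer than 2 breaths in capnograph trace")
    peak_t = t0 + peaks / co2.fs
    vol_t = np.arange(n_vols) * tr_s
    values = np.interp(vol_t, peak_t, samples[peaks])
    return PhysioTimecourse(values=values, tr_s=tr_s, kind="petco2_mmHg")


# ---------------------------------------------------------------------------
# HRV summary metrics

LF_BAND = (0.04, 0.15)  # Hz
HF_BAND = (0.15, 0.40)  # Hz
_RESAMPLE_HZ = 4.0
_WELCH_SEG_S = 120.0


def _band_powers(beats: BeatSeries) -> tuple[float, float]:
    """LF/HF power (ms^2) of the IBI series resampled to a uniform 4 Hz grid."""
    mids = beats.ibi_midpoints_s
    ibi_ms = beats.ibi_s * 1000.0
    t = np.arange(mids[0], mids[-1], 1.0 / _RESAMPLE_HZ)
    if len(mids) >= 4:
        even = interpolate.CubicSpline(mids, ibi_ms)(t)
    else:
        even = np.interp(t, mids, ibi_ms)
    even = even - even.mean()
    nperseg = min(len(even), int(_WELCH_SEG_S * _RESAMPLE_HZ))
    f, pxx = sps.welch(even, fs=_RESAMPLE_HZ, nperseg=nperseg, noverlap=nperseg // 2)

    def band(lo: float, hi: float) -> float:
        sel = (f >= lo) & (f <= hi)
        return float(np.trapezoid(pxx[sel], f[sel])) if sel.sum() >= 2 else 0.0

    return band(*LF_BAND), band(*HF_BAND)


def hrv_metrics(
    beats: BeatSeries,
    rv: Optional[PhysioTimecourse] = None,
    co2: Optional[PhysioTimecourse] = None,
    breathing_rate_bpm: Optional[float] = None,
) -> HRVSummary:
    """Compute scan-level HRV summary metrics from cleaned beats.

    RMSSD is the root-mean-square of successive IBI differences (ms); LF and
    HF are the integrated power of the evenly resampled IBI series in
    0.04–0.15 Hz and 0.15–0.4 Hz (ms^2).  RMSSD and band powers are reported
    natural-log transformed; non-positive powers yield NaN logs with a flag.
    """
    ibi = beats.ibi_s
    if beats.beat_times_s[-1] - beats.beat_times_s[0] < 120.0:
        raise DataError("hrv_metrics requires at least 2 minutes of beats")
    d = np.diff(ibi * 1000.0)
    rmssd = float(np.sqrt(np.mean(d**2))) if len(d) else 0.0
    lf, hf = _band_powers(beats)
    flags = {}

    def safe_log(x: float, name: str) -> float:
        if x <= 0:
            flags[name] = "non-positive, log undefined"
            return float("nan")
        return float(np.log(x))

    return HRVSummary(
        ln_rmssd=safe_log(rmssd, "rmssd"),
        ln_lf=safe_log(lf, "lf"),
        ln_hf=safe_log(hf, "hf"),
        avg_hr_bpm=float(60.0 / np.mean(ibi)),
        sd_rv=float(np.std(rv.values)) if rv is not None else None,
        breathing_rate_bpm=breathing_rate_bpm,
        avg_co2_mmHg=float(np.mean(co2.values)) if co2 is not None else None,
        power_flags=flags,
    )


def rmssd_ms(ibi_ms: np.ndarray) -> float:
    """RMSSD (ms) of an IBI sequence given in milliseconds."""
    d = np.diff(np.asarray(ibi_ms, dtype=float))
    if len(d) == 0:
        raise DataError("rmssd requires at least 2 intervals")
    return float(np.sqrt(np.mean(d**2)))


def iqr_screen(values: np.ndarray) -> np.ndarray:
    """Tukey-fence inclusion mask: keep values in [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation of order statistics; NaNs are excluded.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise DataError("iqr_screen requires at least 4 values")
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    return finite & (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
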