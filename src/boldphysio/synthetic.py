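"""Synthetic cohorts: physiological waveforms plus coupled BOLD data with ground truth.

The generator emulates the structure of a two-age-group resting-state study:

* **PPG** — a raised-cosine pulse per heartbeat, with inter-beat intervals
  modulated by a low-frequency (Mayer-wave, ~0.1 Hz) sinusoid, a
  high-frequency sinusoid at the breathing frequency (respiratory sinus
  arrhythmia), and a small broadband AR(1) jitter.
* **Respiration belt** — a quasi-sinusoid at the breathing rate with slow
  amplitude modulation.
* **Capnograph** — breath-synchronous plateaus around a mean end-tidal CO2,
  gated by the respiratory phase and delayed by a known shift.
* **BOLD** — each in-mask voxel is a weighted sum of response-function
  convolved physiological timecourses (shifted by a known latency and scaled
  by a group coupling gain) plus Legendre polynomial drift and AR(1) noise.
  Per-voxel amplitudes are solved exactly so that the realized variance
  fraction equals the requested ``true_pve``.

The "old" group defaults encode the qualitative age effects the pipeline is
meant to recover: halved coupling gain, a 2 s extra latency, and halved
high-frequency heart-rate variability.  All magnitudes are free modeling
choices.  Everything is deterministic given (seed, subject id, session).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigurationError, DataError
from .glm import BOLDVolume
from .io import save_nifti, write_physio
from .physio import (
    BeatSeries,
    PhysioRecording,
    PhysioTimecourse,
    hr_timecourse,
    normalize_rv,
    petco2_timecourse,
    rv_timecourse,
)
from .responses import CO2ResponseParams, CRF, RRF, co2_response

__all__ = [
    "GroupParams",
    "NoiseParams",
    "SimScenario",
    "GroundTruth",
    "tissue_masks",
    "simulate_physio",
    "simulate_timecourses",
    "simulate_bold",
    "simulate_lagged_voxels",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one age group."""

    coupling_gain: float = 1.0  # unitless multiplier on response amplitude
    latency_shift_s: float = 0.0  # extra vascular latency, s
    mean_hr_bpm: float = 69.0
    hrv_lf_amp_s: float = 0.03  # IBI modulation amplitude at ~0.1 Hz, s
    hrv_hf_amp_s: float = 0.04  # IBI modulation amplitude at breathing freq, s
    breathing_rate_bpm: float = 17.5
    co2_mean_mmHg: float = 39.0


@dataclass(frozen=True)
class NoiseParams:
    ar1_coef: float = 0.3
    sigma: float = 1.0  # stationary SD of the AR(1) noise


def default_group_params() -> dict:
    """Young baseline plus old group with halved gain, +2 s latency, halved HF."""
    return {
        "young": GroupParams(),
        "old": GroupParams(
            coupling_gain=0.5,
            latency_shift_s=2.0,
            mean_hr_bpm=67.0,
            hrv_lf_amp_s=0.015,
            hrv_hf_amp_s=0.02,
            breathing_rate_bpm=15.5,
            co2_mean_mmHg=40.0,
        ),
    }


@dataclass
class SimScenario:
    """Full specification of a synthetic cohort."""

    n_subjects_per_group: int = 2
    group_params: dict = field(default_factory=default_group_params)
    grid_shape: tuple = (6, 6, 6)
    n_vols: int = 64
    tr_s: float = 1.4
    physio_fs_hz: float = 25.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    drift: tuple = (0.0, 3.0, -2.0, 1.0, 0.5)  # Legendre coefficients
    seed: int = 0
    respiratory_measure: str = "rv"  # "rv" or "petco2"
    sessions: tuple = ("pre",)
    co2_delay_s: float = 2.0  # injected capnograph delay
    hrv_broadband_amp_s: float = 0.01  # AR(1) IBI jitter SD, s
    lf_freq_hz: float = 0.1
    lf_freq_jitter_hz: float = 0.02  # per-subject uniform jitter of the LF frequency
    # intervention effect applied in the "post" session of osc_plus subjects
    post_oscplus_gain_delta: float = 0.2
    post_oscplus_latency_delta_s: float = -1.0
    # tissue-wise baseline variance fractions before gain scaling
    base_pve: dict = field(
        default_factory=lambda: {"gray": 0.4, "white": 0.2, "ventricles": 0.3}
    )
    conv_dt_s: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")
        if self.physio_fs_hz < 10:
            raise ConfigurationError("physio_fs_hz must be at least 10 Hz")
        if self.n_vols < 16:
            raise ConfigurationError("n_vols must be at least 16")
        if not (0 <= self.noise.ar1_coef < 1):
            raise ConfigurationError("ar1_coef must be in [0, 1)")
        if self.respiratory_measure not in ("rv", "petco2"):
            raise ConfigurationError("respiratory_measure must be 'rv' or 'petco2'")
        for name, gp in self.group_params.items():
            if gp.coupling_gain < 0:
                raise ConfigurationError(f"coupling_gain must be >= 0 (group {name})")

    @property
    def scan_duration_s(self) -> float:
        return self.n_vols * self.tr_s

    def subjects(self) -> pd.DataFrame:
        """Cohort roster: subject id, age group, condition."""
        rows = []
        multi = len(self.sessions) > 1
        for group in self.group_params:
            for i in range(self.n_subjects_per_group):
                cond = ("osc_plus" if i % 2 == 0 else "osc_minus") if multi else "none"
                rows.append(
                    {"subject": f"{group}{i + 1:02d}", "age_group": group, "condition": cond}
                )
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Designed per-voxel quantities stored alongside the generated data."""

    true_betas: dict  # physio kind -> 3D amplitude map
    true_pve: np.ndarray  # 3D fraction in [0, 1]
    true_lag_s: np.ndarray  # 3D latency map
    injected_co2_shift_s: float
    coupling_gain: float = 1.0
    latency_shift_s: float = 0.0


def _rng(scenario: SimScenario, subject: str, stage: str, session: str = "pre") -> np.random.Generator:
    key = (
        zlib.crc32(subject.encode()),
        zlib.crc32(stage.encode()),
        zlib.crc32(session.encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=key))


def _group_of(scenario: SimScenario, subject: str) -> str:
    for group in scenario.group_params:
        if subject.startswith(group):
            return group
    raise ConfigurationError(f"subject {subject!r} not in any group of the scenario")


def _effective_params(
    scenario: SimScenario, subject: str, session: str, condition: str
) -> GroupParams:
    gp = scenario.group_params[_group_of(scenario, subject)]
    if session == "post" and condition == "osc_plus":
        gp = replace(
            gp,
            coupling_gain=max(gp.coupling_gain + scenario.post_oscplus_gain_delta, 0.0),
            latency_shift_s=max(
                gp.latency_shift_s + scenario.post_oscplus_latency_delta_s, 0.0
            ),
        )
    return gp


# ---------------------------------------------------------------------------
# physiological waveforms


def _beat_times(
    scenario: SimScenario, gp: GroupParams, subject: str, session: str, duration_s: float
) -> np.ndarray:
    rng = _rng(scenario, subject, "ibi", session)
    base = 60.0 / gp.mean_hr_bpm
    f_b = gp.breathing_rate_bpm / 60.0
    f_lf = scenario.lf_freq_hz + rng.uniform(
        -scenario.lf_freq_jitter_hz, scenario.lf_freq_jitter_hz
    )
    phi_lf = rng.uniform(0, 2 * np.pi)
    phi_hf = rng.uniform(0, 2 * np.pi)
    times = [0.0]
    bb = 0.0
    amp = scenario.hrv_broadband_amp_s
    while times[-1] < duration_s:
        t = times[-1]
        bb = 0.9 * bb + np.sqrt(1 - 0.81) * amp * rng.standard_normal() if amp > 0 else 0.0
        ibi = (
            base
            + gp.hrv_lf_amp_s * np.sin(2 * np.pi * f_lf * t + phi_lf)
            + gp.hrv_hf_amp_s * np.sin(2 * np.pi * f_b * t + phi_hf)
            + bb
        )
        times.append(t + max(ibi, 0.3))
    return np.array(times)


_PULSE_WIDTH_S = 0.4


def simulate_physio(scenario: SimScenario, subject: str, session: str = "pre") -> dict:
    """Generate raw PPG, respiration-belt and capnograph recordings for one scan.

    Returns a dict with keys ``ppg``, ``respiration`` and (always generated,
    used only by PETCO2 profiles) ``capnograph``, plus the true ``beats``.
    Deterministic given (scenario seed, subject, session).
    """
    scenario.validate()
    roster = scenario.subjects()
    row = roster[roster.subject == subject]
    condition = row.condition.iloc[0] if len(row) else "none"
    gp = _effective_params(scenario, subject, session, condition)
    fs = scenario.physio_fs_hz
    duration = scenario.scan_duration_s + 10.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    beats = _beat_times(scenario, gp, subject, session, duration)
    ppg = np.zeros(n)
    w = _PULSE_WIDTH_S
    for tb in beats:
        i0 = int(np.ceil(tb * fs))
        i1 = min(int(np.floor((tb + w) * fs)) + 1, n)
        if i0 >= n:
            break
        ti = t[i0:i1]
        ppg[i0:i1] += 0.5 * (1 - np.cos(2 * np.pi * (ti - tb) / w))

    rng = _rng(scenario, subject, "resp", session)
    f_b = gp.breathing_rate_bpm / 60.0
    phi = rng.uniform(0, 2 * np.pi)
    knot_t = np.arange(0, duration + 10.0, 10.0)
    knots = 1.0 + 0.15 * rng.standard_normal(len(knot_t))
    amp = np.clip(np.interp(t, knot_t, knots), 0.3, None)
    resp = amp * np.sin(2 * np.pi * f_b * t + phi)

    rng_co2 = _rng(scenario, subject, "co2", session)
    phase = f_b * t + phi / (2 * np.pi)
    breath_idx = np.floor(phase).astype(int) - int(np.floor(phase[0]))
    plateaus = gp.co2_mean_mmHg + 0.8 * rng_co2.standard_normal(breath_idx.max() + 1)
    gate = special.expit(-4.0 * np.sin(2 * np.pi * f_b * t + phi))
    co2_raw = plateaus[breath_idx] * gate
    shift_n = int(round(scenario.co2_delay_s * fs))
    co2 = np.concatenate([np.full(shift_n, co2_raw[0]), co2_raw[: n - shift_n]])

    return {
        "ppg": PhysioRecording(ppg, fs, "ppg"),
        "respiration": PhysioRecording(resp, fs, "respiration"),
        "capnograph": PhysioRecording(co2, fs, "capnograph"),
        "beats": BeatSeries(beat_times_s=beats),
    }


def simulate_timecourses(
    scenario: SimScenario, subject: str, session: str = "pre"
) -> dict:
    """Ground-truth TR-locked timecourses derived from the generated waveforms.

    Uses the true beat times (no detection step) for HR; RV/PETCO2 come from
    the standard preprocessing operators applied to the noiseless recordings.
    """
    recs = simulate_physio(scenario, subject, session)
    tcs = {
        "hr_bpm": hr_timecourse(recs["beats"], scenario.tr_s, scenario.n_vols)
    }
    if scenario.respiratory_measure == "rv":
        rv = rv_timecourse(recs["respiration"], scenario.tr_s, scenario.n_vols)
        tcs["rv_norm"] = normalize_rv(rv)
    else:
        tcs["petco2_mmHg"] = petco2_timecourse(
            recs["capnograph"], scenario.co2_delay_s, scenario.tr_s, scenario.n_vols
        )
    return tcs


# ---------------------------------------------------------------------------
# BOLD generation


def tissue_masks(grid_shape: tuple) -> dict:
    """Partition a rectangular grid into nested ventricle/white/gray compartments."""
    idx = np.indices(grid_shape).astype(float)
    center = (np.array(grid_shape, float)[:, None, None, None] - 1) / 2.0
    half = np.maximum(np.array(grid_shape, float)[:, None, None, None] / 2.0, 1.0)
    d = np.max(np.abs(idx - center) / half, axis=0)  # 0 at center, ~1 at faces
    vent = d < 0.25
    white = (d >= 0.25) & (d < 0.6)
    gray = d >= 0.6
    brain = np.ones(grid_shape, dtype=bool)
    return {"brain": brain, "gray": gray, "white": white, "ventricles": vent}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


_KIND_RF = {"hr_bpm": CRF, "rv_norm": RRF}
_KIND_WEIGHT = {"hr_bpm": 1.0, "rv_norm": 0.7, "petco2_mmHg": 0.7}


def _coupled_component(
    tc: PhysioTimecourse,
    kind: str,
    lag_s: float,
    n_vols: int,
    tr_s: float,
    conv_dt_s: float,
    co2_params: Optional[CO2ResponseParams] = None,
) -> np.ndarray:
    """Response-function convolved, latency-shifted, TR-sampled unit-variance driver."""
    rf = _KIND_RF.get(kind) or co2_response(co2_params)
    from scipy import signal as sps

    x = _zscore(sps.detrend(np.asarray(tc.values, float)))
    vol_t = np.arange(n_vols) * tr_s
    fine_t = np.arange(0.0, vol_t[-1] + conv_dt_s, conv_dt_s)
    xf = np.interp(fine_t, vol_t, x)
    kern_t = np.arange(0.0, rf.support_s + conv_dt_s, conv_dt_s)
    conv = np.convolve(xf, np.asarray(rf(kern_t), float))[: len(xf)] * conv_dt_s
    shifted = np.interp(vol_t - lag_s, fine_t, conv, left=conv[0])
    return _zscore(shifted)


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float, size: int) -> np.ndarray:
    """AR(1) noise with stationary SD sigma; shape (size, n)."""
    out = np.empty((size, n))
    out[:, 0] = sigma * rng.standard_normal(size)
    innov_sd = sigma * np.sqrt(1 - phi**2)
    eps = innov_sd * rng.standard_normal((size, n - 1))
    for t in range(1, n):
        out[:, t] = phi * out[:, t - 1] + eps[:, t - 1]
    return out


def _amp_for_pve(p: float, s: np.ndarray, rest: np.ndarray) -> float:
    """Amplitude a with var(a s) / var(a s + rest) == p exactly on the realized arrays."""
    vs = float(np.var(s))
    vr = float(np.var(rest))
    if p == 0 or vs == 0:
        return 0.0
    if vr == 0:
        return 1.0  # noiseless limit: voxel proportional to the driver
    c = float(np.mean((s - s.mean()) * (rest - rest.mean())))
    disc = p * p * c * c + p * (1 - p) * vs * vr
    return (p * c + np.sqrt(disc)) / (vs * (1 - p))


def _drift_series(coeffs: Sequence[float], n_vols: int) -> np.ndarray:
    from numpy.polynomial import legendre

    u = np.linspace(-1, 1, n_vols)
    return legendre.legval(u, np.asarray(coeffs, float))


def simulate_bold(
    scenario: SimScenario,
    physio: Mapping[str, PhysioTimecourse],
    subject: str,
    session: str = "pre",
    true_pve: Optional[np.ndarray] = None,
    true_lag_s: Optional[np.ndarray | float] = None,
    kind_weights: Optional[Mapping[str, float]] = None,
) -> tuple[BOLDVolume, GroundTruth]:
    """Generate a coupled 4D BOLD volume with exact per-voxel variance fractions.

    ``true_pve`` (3D, in [0, 1)) overrides the default tissue-based map
    ``base_pve * coupling_gain * subject jitter``; ``true_lag_s`` overrides
    the group latency.  Requested fractions >= 1 on voxels with nonzero
    drift/noise are a configuration error.
    """
    scenario.validate()
    roster = scenario.subjects()
    row = roster[roster.subject == subject]
    condition = row.condition.iloc[0] if len(row) else "none"
    gp = _effective_params(scenario, subject, session, condition)
    shape = scenario.grid_shape
    masks = tissue_masks(shape)
    n_vols = scenario.n_vols
    rng = _rng(scenario, subject, "bold", session)

    if true_pve is None:
        jitter = rng.uniform(0.9, 1.1)
        true_pve = np.zeros(shape)
        for tissue, base in scenario.base_pve.items():
            true_pve[masks[tissue]] = np.clip(base * gp.coupling_gain * jitter, 0.0, 0.9)
    else:
        true_pve = np.asarray(true_pve, dtype=float)
        if true_pve.shape != shape:
            raise ConfigurationError("true_pve shape must match grid_shape")
    if np.any(true_pve < 0) or np.any(true_pve >= 1.0):
        raise ConfigurationError("pve request outside [0, 1)")

    if true_lag_s is None:
        lag_map = np.full(shape, gp.latency_shift_s)
    else:
        lag_map = np.broadcast_to(np.asarray(true_lag_s, dtype=float), shape).copy()

    weights = dict(_KIND_WEIGHT)
    if kind_weights:
        weights.update(kind_weights)

    # a distinct driver per unique latency value (group-level scalar in practice)
    unique_lags = np.unique(lag_map)
    drivers = {}
    for lag in unique_lags:
        comps = [
            weights.get(kind, 1.0)
            * _coupled_component(tc, kind, float(lag), n_vols, scenario.tr_s, scenario.conv_dt_s)
            for kind, tc in physio.items()
        ]
        drivers[float(lag)] = _zscore(np.sum(comps, axis=0))

    drift = _drift_series(scenario.drift, n_vols)
    nvox = int(np.prod(shape))
    noise = _ar1(rng, n_vols, scenario.noise.ar1_coef, scenario.noise.sigma, nvox)
    data = np.empty(shape + (n_vols,))
    amps = np.zeros(shape)
    flat_pve = true_pve.ravel()
    flat_lag = lag_map.ravel()
    flat_amp = amps.ravel()
    flat_data = data.reshape(nvox, n_vols)
    # true_pve is the variance fraction of the drift-free series: amplitudes are
    # solved against the noise alone, and the (separately modeled, polynomial)
    # drift is added on top — matching how PVE is later measured.
    for v in range(nvox):
        rest = noise[v]
        s = drivers[float(flat_lag[v])]
        a = _amp_for_pve(float(flat_pve[v]), s, rest)
        flat_amp[v] = a
        flat_data[v] = a * s + rest + drift

    betas = {
        kind: amps * weights.get(kind, 1.0) for kind in physio
    }
    bold = BOLDVolume(data=data, tr_s=scenario.tr_s, masks=masks)
    gt = GroundTruth(
        true_betas=betas,
        true_pve=true_pve,
        true_lag_s=lag_map,
        injected_co2_shift_s=scenario.co2_delay_s,
        coupling_gain=gp.coupling_gain,
        latency_shift_s=gp.latency_shift_s,
    )
    return bold, gt


def simulate_lagged_voxels(
    tc: PhysioTimecourse,
    lags_s: Sequence[float],
    target_r: float = 0.6,
    ar1_coef: float = 0.3,
    seed: int = 0,
    fine_dt_s: float = 0.1,
) -> np.ndarray:
    """Voxels coupled to the *raw* physiological series at known latencies.

    Each output row is the latency-shifted, detrended physiological series
    plus AR(1) noise scaled for an expected zero-lag correlation of
    ``target_r`` — the model-free analogue of ``simulate_bold`` used to probe
    cross-correlation lag recovery.  Shape: (len(lags_s), n_vols).
    """
    if not 0 < target_r < 1:
        raise ConfigurationError("target_r must be in (0, 1)")
    from scipy import signal as sps

    rng = np.random.default_rng(seed)
    n_vols = tc.n_vols
    vol_t = np.arange(n_vols) * tc.tr_s
    x = _zscore(sps.detrend(np.asarray(tc.values, float)))
    fine_t = np.arange(0.0, vol_t[-1] + fine_dt_s, fine_dt_s)
    xf = np.interp(fine_t, vol_t, x)
    amp = target_r / np.sqrt(1 - target_r**2)
    out = np.empty((len(lags_s), n_vols))
    noise = _ar1(rng, n_vols, ar1_coef, 1.0, len(lags_s))
    for i, lag in enumerate(lags_s):
        shifted = _zscore(np.interp(vol_t - lag, fine_t, xf, left=xf[0]))
        out[i] = amp * shifted + noise[i]
    return out


# ---------------------------------------------------------------------------
# cohort on disk


def simulate_cohort(
    scenario: SimScenario, outdir: str | Path, overwrite: bool = False
) -> Path:
    """Write a full synthetic cohort: BOLD + physio + masks + manifest + ground truth.

    Returns the manifest path.  Refuses to overwrite an existing cohort unless
    ``overwrite`` is set.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise DataError(f"cohort already exists at {outdir}; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)

    masks = tissue_masks(scenario.grid_shape)
    mask_files = {}
    for name, m in masks.items():
        p = outdir / f"mask_{name}.nii.gz"
        save_nifti(m.astype(np.uint8), p)
        mask_files[name] = p.name

    rows = []
    gt_rows = []
    for _, sub in scenario.subjects().iterrows():
        for session in scenario.sessions:
            recs = simulate_physio(scenario, sub.subject, session)
            tcs = simulate_timecourses(scenario, sub.subject, session)
            bold, gt = simulate_bold(scenario, tcs, sub.subject, session)
            stem = f"{sub.subject}_{session}"
            save_nifti(bold.data, outdir / f"{stem}_bold.nii.gz")
            save_nifti(gt.true_pve, outdir / f"{stem}_truepve.nii.gz")
            phys = {k: recs[k] for k in ("ppg", "respiration")}
            if scenario.respiratory_measure == "petco2":
                phys["capnograph"] = recs["capnograph"]
            write_physio(phys, outdir / f"{stem}_physio")
            rows.append(
                {
                    "subject": sub.subject,
                    "age_group": sub.age_group,
                    "condition": sub.condition,
                    "session": session,
                    "bold": f"{stem}_bold.nii.gz",
                    "physio": f"{stem}_physio.tsv",
                    **{f"mask_{k}": v for k, v in mask_files.items()},
                    "true_pve": f"{stem}_truepve.nii.gz",
                }
            )
            gt_rows.append(
                {
                    "subject": sub.subject,
                    "session": session,
                    "age_group": sub.age_group,
                    "condition": sub.condition,
                    "coupling_gain": gt.coupling_gain,
                    "latency_shift_s": gt.latency_shift_s,
                    "injected_co2_shift_s": gt.injected_co2_shift_s,
                    **{
                        f"mean_true_pve_{t}": float(gt.true_pve[masks[t]].mean())
                        for t in ("gray", "white", "ventricles")
                    },
                }
            )
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    pd.DataFrame(gt_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    return manifest_path
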