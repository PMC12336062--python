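"""Model-free lagged cross-correlation between BOLD and physiological series.

No response-function convolution is applied here: Pearson correlations are
computed between each voxel (or tissue-averaged) BOLD series and the raw HR /
RV / PETCO2 timecourse over a grid of temporal lags.  The sign convention is
positive lag = physiological signal leads BOLD: at lag L the physiological
series is shifted forward by L before correlating, and the overlap shrinks
with |L| (no padding).  Both segments are linearly detrended before
correlation.

Tissue-level curves can optionally be computed on an upsampled grid (e.g.
0.2 s) to resolve peak lags below the TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import signal as sps

from .errors import DataError
from .glm import BOLDVolume
from .physio import PhysioTimecourse

__all__ = ["LagGrid", "LagCorrMap", "TissueXCorr", "xcorr_at_lags", "voxelwise_xcorr", "tissue_xcorr"]

MIN_OVERLAP = 30  # samples


@dataclass(frozen=True)
class LagGrid:
    """A uniform grid of lags (s); positive lag = physiology leads BOLD."""

    lags_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags_s", np.asarray(self.lags_s, dtype=float))
        d = np.diff(self.lags_s)
        if len(d) and not np.allclose(d, d[0]):
            raise DataError("lag grid must be uniformly spaced")

    @classmethod
    def from_range(cls, lo_s: float, hi_s: float, step_s: float) -> "LagGrid":
        n = int(round((hi_s - lo_s) / step_s))
        return cls(lo_s + step_s * np.arange(n + 1))

    @classmethod
    def from_trs(cls, tr_s: float, lo_tr: int, hi_tr: int) -> "LagGrid":
        return cls(tr_s * np.arange(lo_tr, hi_tr + 1))

    @property
    def step_s(self) -> float:
        return float(self.lags_s[1] - self.lags_s[0]) if len(self.lags_s) > 1 else 0.0

    def steps(self, step_s: float) -> np.ndarray:
        """Integer sample offsets for each lag on a grid with spacing step_s."""
        k = self.lags_s / step_s
        ki = np.round(k).astype(int)
        if not np.allclose(k, ki, atol=1e-6):
            raise DataError("each lag must be an integer multiple of the sampling step")
        return ki


@dataclass
class LagCorrMap:
    """Voxelwise Pearson r across lags: 4D (x, y, z, lag)."""

    values: np.ndarray
    grid: LagGrid
    physio_kind: str
    subject: Optional[str] = None
    session: Optional[str] = None

    def peak_lag_map(self) -> np.ndarray:
        """Lag (s) of the maximum |r| per voxel; NaN where all lags are NaN."""
        absr = np.abs(self.values)
        allnan = np.all(~np.isfinite(absr), axis=-1)
        idx = np.nanargmax(np.where(np.isfinite(absr), absr, -np.inf), axis=-1)
        out = self.grid.lags_s[idx].astype(float)
        out[allnan] = np.nan
        return out


@dataclass
class TissueXCorr:
    """Tissue-averaged cross-correlation curves: tissue name -> r per lag."""

    r: dict
    grid: LagGrid
    physio_kind: str
    upsample_dt_s: Optional[float] = None
    subject: Optional[str] = None
    session: Optional[str] = None

    def peak_lag(self, tissue: str) -> float:
        curve = self.r[tissue]
        return float(self.grid.lags_s[int(np.nanargmax(curve))])


def _detrend(x: np.ndarray) -> np.ndarray:
    return sps.detrend(x, type="linear", axis=0)


def _pearson_cols(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of vector x against each column of Y (both already detrended)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    num = xc @ Yc
    den = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _lagged_segments(x: np.ndarray, Y: np.ndarray, k: int):
    """Overlapping segments after shifting the physiological series x forward by k steps."""
    n = len(x)
    if k >= 0:
        return x[: n - k] if k else x, Y[k:]
    return x[-k:], Y[: n + k]


def xcorr_at_lags(
    x: np.ndarray, y: np.ndarray, step_s: float, grid: LagGrid
) -> np.ndarray:
    """Pearson r between physiological series ``x`` and BOLD series ``y`` at each lag.

    Both overlapping segments are linearly detrended before correlation; lags
    whose overlap falls below 30 samples return NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("series must have equal length")
    out = np.full(len(grid.lags_s), np.nan)
    short = False
    for i, k in enumerate(grid.steps(step_s)):
        xi, yi = _lagged_segments(x, y[:, None], int(k))
        if len(xi) < MIN_OVERLAP:
            short = True
            continue
        out[i] = _pearson_cols(_detrend(xi), _detrend(yi))[0]
    if short:
        warnings.warn("some lags skipped: overlap below 30 samples", stacklevel=2)
    return out


def voxelwise_xcorr(
    bold: BOLDVolume, physio: PhysioTimecourse, grid: LagGrid
) -> LagCorrMap:
    """Apply ``xcorr_at_lags`` to every in-mask voxel (TR-resolution lags)."""
    if physio.n_vols != bold.n_vols:
        raise DataError("physio timecourse and BOLD volume count differ")
    x = np.asarray(physio.values, dtype=float)
    Y = bold.series("brain")
    nvox = Y.shape[1]
    rmat = np.full((len(grid.lags_s), nvox), np.nan)
    short = False
    for i, k in enumerate(grid.steps(bold.tr_s)):
        xi, Yi = _lagged_segments(x, Y, int(k))
        if len(xi) < MIN_OVERLAP:
            short = True
            continue
        rmat[i] = _pearson_cols(_detrend(xi), _detrend(Yi))
    if short:
        warnings.warn("some lags skipped: overlap below 30 samples", stacklevel=2)
    values = np.full(bold.data.shape[:3] + (len(grid.lags_s),), np.nan)
    values[bold.masks["brain"]] = rmat.T
    return LagCorrMap(values=values, grid=grid, physio_kind=physio.kind)


def tissue_xcorr(
    bold: BOLDVolume,
    physio: PhysioTimecourse,
    grid: LagGrid,
    tissues: tuple = ("gray", "white", "ventricles"),
    upsample_dt_s: Optional[float] = None,
) -> TissueXCorr:
    """Cross-correlate tissue-averaged BOLD with a physiological series.

    If ``upsample_dt_s`` is given, both the averaged BOLD series and the
    physiological series are linearly interpolated to that step and the lag
    grid is refined to the same resolution (same endpoints).
    """
    if physio.n_vols != bold.n_vols:
        raise DataError("physio timecourse and BOLD volume count differ")
    x = np.asarray(physio.values, dtype=float)
    t = np.arange(bold.n_vols) * bold.tr_s
    if upsample_dt_s is not None:
        tf = np.arange(t[0], t[-1] + 0.5 * upsample_dt_s, upsample_dt_s)
        xu = np.interp(tf, t, x)
        use_grid = LagGrid.from_range(
            grid.lags_s[0], grid.lags_s[-1], upsample_dt_s
        )
        step = upsample_dt_s
    else:
        xu, tf, use_grid, step = x, t, grid, bold.tr_s

    curves: dict[str, np.ndarray] = {}
    for tissue in tissues:
        mask = bold.masks.get(tissue)
        if mask is None or not mask.any():
            warnings.warn(f"empty or missing {tissue} mask dropped", stacklevel=2)
            continue
        series = bold.data[mask].mean(axis=0)
        if upsample_dt_s is not None:
            series = np.interp(tf, t, series)
        curves[tissue] = xcorr_at_lags(xu, series, step, use_grid)
    return TissueXCorr(
        r=curves, grid=use_grid, physio_kind=physio.kind, upsample_dt_s=upsample_dt_s
    )
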