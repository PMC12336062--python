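"""Voxelwise coupling GLMs and percent-variance-explained (PVE) maps.

Three linear models relate each voxel's BOLD series to physiological
regressors: joint (cardiac + respiratory), cardiac-only, respiratory-only.
PVE is the fraction of voxel variance captured by the physiological columns —
computed as a partial R^2 with the polynomial drift terms projected out of
both numerator and denominator, so slow scanner drift neither inflates nor
deflates the physiological share.  Because the single-signal models are
nested in the joint model (same drift block), PVE(joint) >= PVE(cardiac) and
PVE(respiratory) holds exactly at every voxel; shared cardiac-respiratory
variance is deliberately left un-orthogonalized and may appear in both
single-signal maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np

from .errors import DataError
from .physio import PhysioTimecourse
from .responses import CO2ResponseParams, RegressorSet, build_regressors

__all__ = ["BOLDVolume", "PVEMap", "fit_voxelwise", "pve", "run_three_models"]


@dataclass
class BOLDVolume:
    """A preprocessed 4D BOLD array with tissue masks on the same grid."""

    data: np.ndarray  # (x, y, z, t)
    tr_s: float
    masks: dict  # name -> 3D bool; must include "brain"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DataError("BOLD data must be 4D (x, y, z, t)")
        if "brain" not in self.masks:
            raise DataError("masks must include a 'brain' mask")
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.data.shape[:3]:
                raise DataError(
                    f"mask {name} shape {m.shape} != volume grid {self.data.shape[:3]}"
                )
            self.masks[name] = m

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    def series(self, mask_name: str = "brain") -> np.ndarray:
        """In-mask voxel series as an (n_vols, n_voxels) matrix."""
        return self.data[self.masks[mask_name]].T


@dataclass
class PVEMap:
    """Per-voxel fraction of BOLD variance explained by physiological regressors."""

    values: np.ndarray  # 3D, NaN outside mask
    model_tag: Literal["joint", "cardiac", "respiratory"]
    subject: Optional[str] = None
    session: Optional[str] = None

    def mask_mean(self, mask: np.ndarray) -> float:
        v = self.values[np.asarray(mask, dtype=bool)]
        return float(np.nanmean(v))


def fit_voxelwise(bold: BOLDVolume, design: RegressorSet) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares per in-mask voxel.

    Returns ``(betas, fitted)`` with betas of shape (k, n_voxels) and fitted
    values of shape (n_vols, n_voxels), voxel order following the flattened
    brain mask.  Rank-deficient designs are rejected with the offending
    columns named.
    """
    X = design.columns
    if X.shape[0] != bold.n_vols:
        raise DataError(f"design has {X.shape[0]} rows, volume has {bold.n_vols}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full column rank
        bad = [
            lab
            for j, lab in enumerate(design.labels)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DataError(f"rank-deficient design; collinear columns: {bad}")
    Y = bold.series("brain")
    if Y.shape[1] == 0:
        raise DataError("brain mask is empty")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return betas, X @ betas


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def pve(
    bold: BOLDVolume,
    design: RegressorSet,
    denominator: Literal["detrended", "raw"] = "detrended",
    subject: Optional[str] = None,
    session: Optional[str] = None,
) -> PVEMap:
    """Percent variance explained by the physiological columns of ``design``.

    With the default ``denominator="detrended"`` the statistic is
    ``1 - RSS(full) / RSS(drift-only)``: the share of drift-removed voxel
    variance captured by the physiological regressors.  ``denominator="raw"``
    divides the same explained variance by the total variance of the raw
    voxel series instead.  Zero-variance voxels are returned as NaN.
    """
    fit_voxelwise(bold, design)  # validates shapes and rank
    X = design.columns
    Y = bold.series("brain")
    drift = design.drift_columns()
    rss_drift = _rss(drift, Y)
    rss_full = _rss(X, Y)
    explained = rss_drift - rss_full
    if denominator == "detrended":
        denom = rss_drift
    elif denominator == "raw":
        denom = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    else:
        raise DataError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, explained / denom, np.nan)
    frac = np.clip(frac, 0.0, 1.0, where=np.isfinite(frac), out=frac)
    values = np.full(bold.data.shape[:3], np.nan)
    values[bold.masks["brain"]] = frac
    return PVEMap(values=values, model_tag=design.model_tag, subject=subject, session=session)


def run_three_models(
    bold: BOLDVolume,
    physio: Mapping[str, PhysioTimecourse],
    drift_order: int = 4,
    co2_params: Optional[CO2ResponseParams] = None,
    denominator: Literal["detrended", "raw"] = "detrended",
    subject: Optional[str] = None,
    session: Optional[str] = None,
) -> dict:
    """Fit joint, cardiac-only and respiratory-only models; return PVE maps by tag.

    Models whose physiological inputs are missing are skipped with a warning
    (e.g. respiratory-only when neither RV nor PETCO2 is available).
    """
    import warnings

    maps: dict[str, PVEMap] = {}
    have_cardiac = "hr_bpm" in physio
    have_resp = ("rv_norm" in physio) or ("petco2_mmHg" in physio)
    wanted = []
    if have_cardiac and have_resp:
        wanted.append("joint")
    if have_cardiac:
        wanted.append("cardiac")
    if have_resp:
        wanted.append("respiratory")
    for tag in ("joint", "cardiac", "respiratory"):
        if tag not in wanted:
            warnings.warn(f"skipping {tag} model: required physio kind missing", stacklevel=2)
            continue
        design = build_regressors(
            physio, tag, bold.tr_s, bold.n_vols, drift_order=drift_order, co2_params=co2_params
        )
        maps[tag] = pve(
            bold, design, denominator=denominator, subject=subject, session=session
        )
    return maps
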