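"""Cardiac, respiratory and CO2 impulse-response bases and regressor construction.

The BOLD response to slow autonomic fluctuations is modeled as a convolution of
heart rate (HR), respiratory variation (RV) or end-tidal CO2 (PETCO2) with a
fixed impulse-response function:

* ``crf`` — canonical cardiac response function: an early positive gamma-like
  peak followed by a negative Gaussian trough near 12 s.
* ``rrf`` — canonical respiratory response function: positive peak near 3 s,
  broad undershoot peaking around 15 s.
* ``co2_rf`` — generic peak-normalized double-gamma CO2 response function with
  editable amplitude/shape parameters (the literature offers several
  parameterizations; defaults here place the positive peak at 8 s and a small
  undershoot near 18 s).

``build_regressors`` turns TR-locked physiological timecourses into a GLM
design matrix: detrend, z-score, upsample to a fine grid, convolve with each
basis (primary + temporal derivative + dispersive derivative), resample at
volume times, z-score again, and append Legendre drift polynomials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy import signal as sps

from .errors import ConfigurationError, DataError
from .physio import PhysioTimecourse

__all__ = [
    "crf",
    "rrf",
    "CO2ResponseParams",
    "co2_rf",
    "ResponseFunction",
    "derivative_basis",
    "RegressorSet",
    "build_regressors",
]


def crf(t_s: np.ndarray | float) -> np.ndarray:
    """Canonical cardiac response function.

    ``0.6 t^2.7 exp(-t/1.6) - (16/sqrt(18 pi)) exp(-(t-12)^2/18)`` for t >= 0,
    zero for t < 0 (causal).
    """
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = 0.6 * tp**2.7 * np.exp(-tp / 1.6) - (16.0 / np.sqrt(18.0 * np.pi)) * np.exp(
        -((tp - 12.0) ** 2) / 18.0
    )
    return out if out.ndim else float(out)


def rrf(t_s: np.ndarray | float) -> np.ndarray:
    """Canonical respiratory response function.

    ``0.6 t^2.1 exp(-t/1.6) - 0.0023 t^3.54 exp(-t/4.25)`` for t >= 0, zero
    for t < 0.
    """
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = 0.6 * tp**2.1 * np.exp(-tp / 1.6) - 0.0023 * tp**3.54 * np.exp(-tp / 4.25)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CO2ResponseParams:
    """Double-gamma CO2 response parameters.

    Each lobe is the peak-normalized gamma variate ``(t/(n tau))^n exp(n - t/tau)``
    whose mode is ``n * tau``.  Amplitudes are unitless multipliers; ``tau_*``
    in seconds.  Defaults are editable configuration values, not printed
    constants: the positive lobe peaks at 8 s, the undershoot at ~17.6 s.
    """

    a1: float = 1.0
    tau1: float = 1.6
    n1: float = 5.0
    a2: float = 0.3
    tau2: float = 1.6
    n2: float = 11.0

    def validate(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0 or self.n1 <= 0 or self.n2 <= 0:
            raise ConfigurationError("CO2 response shape parameters must be positive")


def _gamma_shape(t: np.ndarray, tau: float, n: float) -> np.ndarray:
    """Peak-normalized gamma variate; equals 1 at its mode t = n*tau, 0 at t=0."""
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(n * np.log(tp / (n * tau)) + n - tp / tau)
    return out


def co2_rf(t_s: np.ndarray | float, params: CO2ResponseParams | None = None) -> np.ndarray:
    """Double-gamma end-tidal CO2 response function (positive lobe minus undershoot)."""
    params = params or CO2ResponseParams()
    params.validate()
    t = np.asarray(t_s, dtype=float)
    out = params.a1 * _gamma_shape(t, params.tau1, params.n1) - params.a2 * _gamma_shape(
        t, params.tau2, params.n2
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ResponseFunction:
    """An impulse-response curve with a name and evaluation span."""

    name: Literal["CRF", "RRF", "CO2RF"]
    func: Callable[[np.ndarray], np.ndarray]
    support_s: float = 40.0

    def __call__(self, t_s: np.ndarray | float) -> np.ndarray:
        return self.func(np.asarray(t_s, dtype=float))


CRF = ResponseFunction("CRF", crf, support_s=40.0)
RRF = ResponseFunction("RRF", rrf, support_s=60.0)


def co2_response(params: CO2ResponseParams | None = None) -> ResponseFunction:
    p = params or CO2ResponseParams()
    return ResponseFunction("CO2RF", lambda t: co2_rf(t, p), support_s=60.0)


_DERIV_DT = 0.02  # grid for finite differences, s
_DISP_W = 1.1  # dispersion stretch factor


def derivative_basis(rf: ResponseFunction) -> list[Callable[[np.ndarray], np.ndarray]]:
    """Return the ordered basis [primary, temporal derivative, dispersive derivative].

    The temporal derivative is a central finite difference on a 0.02 s grid;
    the dispersive derivative is ``(rf(t/w)/w - rf(t)) / (w - 1)`` with
    ``w = 1.1`` — the sensitivity of the curve to a stretch of its time axis.
    All three are returned as callables evaluable on arbitrary time grids.
    """

    def temporal(t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (rf(t + _DERIV_DT) - rf(t - _DERIV_DT)) / (2.0 * _DERIV_DT)

    def dispersive(t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (rf(t / _DISP_W) / _DISP_W - rf(t)) / (_DISP_W - 1.0)

    return [rf.func, temporal, dispersive]


@dataclass
class RegressorSet:
    """A design matrix: physiological columns followed by Legendre drift terms."""

    columns: np.ndarray  # n_vols x k
    labels: list[str]
    model_tag: Literal["joint", "cardiac", "respiratory"]
    tr_s: float
    drift_order: int = 4

    def __post_init__(self) -> None:
        if self.columns.shape[1] != len(self.labels):
            raise DataError("labels must match design columns")
        if len(set(self.labels)) != len(self.labels):
            raise DataError("design labels must be unique")

    @property
    def n_vols(self) -> int:
        return self.columns.shape[0]

    @property
    def phys_mask(self) -> np.ndarray:
        """Boolean mask of the physiological (non-drift) columns."""
        return np.array([not lab.startswith("drift_") for lab in self.labels])

    def drift_columns(self) -> np.ndarray:
        return self.columns[:, ~self.phys_mask]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _convolved_columns(
    tc: PhysioTimecourse,
    basis: Sequence[Callable[[np.ndarray], np.ndarray]],
    labels: Sequence[str],
    n_vols: int,
    tr_s: float,
    conv_dt_s: float,
    support_s: float,
) -> tuple[list[np.ndarray], list[str]]:
    """Detrend/z-score a TR series, convolve with each basis on a fine grid, resample."""
    raw = np.asarray(tc.values, dtype=float)
    if np.ptp(raw) == 0:
        warnings.warn(
            f"constant {tc.kind} series: dropping columns {list(labels)}", stacklevel=3
        )
        return [], []
    x = sps.detrend(raw, type="linear")
    if x.std() <= 1e-12 * max(1.0, np.abs(raw).max()):
        warnings.warn(
            f"constant {tc.kind} series after detrending: dropping columns {list(labels)}",
            stacklevel=3,
        )
        return [], []
    x = _zscore(x)
    vol_t = np.arange(n_vols) * tr_s
    fine_t = np.arange(0.0, vol_t[-1] + conv_dt_s, conv_dt_s)
    xf = np.interp(fine_t, vol_t, x)
    kern_t = np.arange(0.0, support_s + conv_dt_s, conv_dt_s)
    cols, kept = [], []
    for b, lab in zip(basis, labels):
        kern = np.asarray(b(kern_t), dtype=float)
        conv = np.convolve(xf, kern)[: len(xf)] * conv_dt_s
        col = np.interp(vol_t, fine_t, conv)
        if col.std() == 0:
            warnings.warn(f"zero-variance column {lab} dropped", stacklevel=3)
            continue
        cols.append(_zscore(col))
        kept.append(lab)
    return cols, kept


def build_regressors(
    physio: Mapping[str, PhysioTimecourse],
    model_tag: Literal["joint", "cardiac", "respiratory"],
    tr_s: float,
    n_vols: int,
    drift_order: int = 4,
    conv_dt_s: float = 0.5,
    co2_params: CO2ResponseParams | None = None,
) -> RegressorSet:
    """Build the design matrix for one of the three coupling models.

    ``physio`` maps kinds to TR-locked timecourses; the cardiac measure is
    ``hr_bpm`` (3 CRF basis columns) and the respiratory measure is either
    ``rv_norm`` (3 RRF basis columns) or ``petco2_mmHg`` (CO2 primary +
    temporal-derivative columns).  Legendre polynomials of degree 0..drift_order
    (degree 0 being the intercept) are appended as drift terms.
    """
    for tc in physio.values():
        if len(tc.values) != n_vols:
            raise DataError(
                f"timecourse {tc.kind} has {len(tc.values)} values, expected {n_vols}"
            )
    cols: list[np.ndarray] = []
    labels: list[str] = []

    if model_tag in ("joint", "cardiac"):
        if "hr_bpm" not in physio:
            raise DataError("cardiac model requires an hr_bpm timecourse")
        basis = derivative_basis(CRF)
        c, l = _convolved_columns(
            physio["hr_bpm"], basis, ["hr_crf", "hr_crf_tderiv", "hr_crf_disp"],
            n_vols, tr_s, conv_dt_s, CRF.support_s,
        )
        cols += c
        labels += l
    if model_tag in ("joint", "respiratory"):
        if "rv_norm" in physio:
            basis = derivative_basis(RRF)
            c, l = _convolved_columns(
                physio["rv_norm"], basis, ["rv_rrf", "rv_rrf_tderiv", "rv_rrf_disp"],
                n_vols, tr_s, conv_dt_s, RRF.support_s,
            )
        elif "petco2_mmHg" in physio:
            rf = co2_response(co2_params)
            primary, temporal, _ = derivative_basis(rf)
            basis = [primary, temporal]
            c, l = _convolved_columns(
                physio["petco2_mmHg"], basis, ["co2_rf", "co2_rf_tderiv"],
                n_vols, tr_s, conv_dt_s, rf.support_s,
            )
        else:
            raise DataError("respiratory model requires rv_norm or petco2_mmHg")
        cols += c
        labels += l

    # Legendre drift terms on [-1, 1]; degree 0 is the intercept.
    u = np.linspace(-1.0, 1.0, n_vols)
    for deg in range(drift_order + 1):
        coef = np.zeros(deg + 1)
        coef[deg] = 1.0
        cols.append(legendre.legval(u, coef))
        labels.append(f"drift_P{deg}")

    return RegressorSet(
        columns=np.column_stack(cols),
        labels=labels,
        model_tag=model_tag,
        tr_s=tr_s,
        drift_order=drift_order,
    )
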