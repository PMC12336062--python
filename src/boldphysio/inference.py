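"""Group-level statistics: two-sample t maps, TFCE, permutation FWE correction.

Voxelwise maps (PVE or lag-correlation) are compared between groups with
pooled-variance two-sample t statistics; familywise error is controlled by
enhancing each t map with Threshold-Free Cluster Enhancement (TFCE) and
building the null distribution of the map-maximum TFCE score by shuffling
group labels (sizes preserved).  Both directions (A>B and B>A) are reported.
Tissue-level lag curves are compared per lag with Bonferroni correction over
lags, and scan-level physiological summaries with Welch t tests (two-sample)
and paired t tests (pre vs post).

The pooled-variance choice for map statistics keeps the permutation null
exchangeable; summary tables use Welch for robustness — an intentional
asymmetry.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DataError
from .xcorr import TissueXCorr

__all__ = [
    "GroupStatResult",
    "TissueGroupTest",
    "two_sample_tmap",
    "paired_diff_maps",
    "tfce_enhance",
    "permutation_test",
    "lagwise_tissue_test",
    "cohort_summary_tests",
]


# ---------------------------------------------------------------------------
# t statistics


def _stack(maps: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim < 2:
        raise DataError("expected a stack of maps (subjects x voxels...)")
    return arr


def _pooled_t(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t along axis 0; NaN where pooled variance is 0."""
    nA, nB = A.shape[0], B.shape[0]
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    ssA = ((A - mA) ** 2).sum(axis=0)
    ssB = ((B - mB) ** 2).sum(axis=0)
    sp2 = (ssA + ssB) / (nA + nB - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mA - mB) / np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    t[sp2 == 0] = np.nan
    return t


def two_sample_tmap(
    maps_A: Sequence[np.ndarray],
    maps_B: Sequence[np.ndarray],
    covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-voxel two-sample t (A minus B), pooled variance.

    With ``covariates`` (one row per subject, A stacked above B), the returned
    statistic is the t test of the group-indicator coefficient in a per-voxel
    linear model with intercept and covariate columns.  Voxels with zero
    within-group variance (or collinear covariates) come back NaN.
    """
    A, B = _stack(maps_A), _stack(maps_B)
    if A.shape[1:] != B.shape[1:]:
        raise DataError("group map stacks are not co-registered")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise DataError("need at least 3 subjects per group")
    shape = A.shape[1:]
    if covariates is None:
        return _pooled_t(A.reshape(A.shape[0], -1), B.reshape(B.shape[0], -1)).reshape(shape)

    n = A.shape[0] + B.shape[0]
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        raise DataError("covariate rows must match total subjects (A then B)")
    g = np.concatenate([np.ones(A.shape[0]), np.zeros(B.shape[0])])
    X = np.column_stack([np.ones(n), g, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("covariates collinear with the group indicator")
    Y = np.concatenate([A.reshape(A.shape[0], -1), B.reshape(B.shape[0], -1)])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - X.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
    t[sigma2 == 0] = np.nan
    return t.reshape(shape)


def paired_diff_maps(
    pre: dict, post: dict
) -> tuple[np.ndarray, list[str]]:
    """Per-subject post-minus-pre maps from subject-keyed dictionaries.

    Returns a (n_subjects, ...) stack and the subject order.  Subjects present
    in only one session raise an error naming the ids.
    """
    missing = sorted(set(pre) ^ set(post))
    if missing:
        raise DataError(f"unmatched subjects between sessions: {missing}")
    ids = sorted(pre)
    return np.stack([np.asarray(post[s], float) - np.asarray(pre[s], float) for s in ids]), ids


# ---------------------------------------------------------------------------
# TFCE


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise DataError("connectivity must be 6, 18 or 26")


def tfce_enhance(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: Optional[float] = None,
    connectivity: int = 26,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a 3D map.

    ``TFCE(v) = sum_h e(h, v)^E * h^H * dh`` over midpoint thresholds
    ``h_j = (j - 1/2) dh`` up to the map maximum, where ``e(h, v)`` is the
    voxel count of the supra-threshold connected component containing ``v``
    (26-connectivity by default).  Values <= 0 enhance to 0; pass ``-map`` to
    enhance the negative tail.  ``dh`` defaults to max/n_steps.
    """
    m = np.asarray(stat_map, dtype=float)
    if m.ndim != 3:
        raise DataError("tfce_enhance expects a 3D statistic map")
    if not np.all(np.isfinite(m)):
        raise DataError("non-finite values in statistic map")
    out = np.zeros_like(m)
    hmax = m.max()
    if hmax <= 0:
        return out
    if dh is None:
        dh = hmax / n_steps
    if dh <= 0:
        raise DataError("dh must be positive")
    struct = _structure(connectivity)
    h = 0.5 * dh
    while h < hmax:
        supra = m > h
        labels, nlab = ndimage.label(supra, structure=struct)
        if nlab == 0:
            break
        extent = np.bincount(labels.ravel())
        contrib = (extent.astype(float) ** E) * (h**H) * dh
        contrib[0] = 0.0
        out += contrib[labels]
        h += dh
    return out


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class GroupStatResult:
    """Observed t map, TFCE maps, and familywise-corrected p maps for both directions."""

    t_map: np.ndarray
    tfce_pos: np.ndarray
    tfce_neg: np.ndarray
    p_corr_pos: np.ndarray  # direction A > B
    p_corr_neg: np.ndarray  # direction B > A
    n_perm: int
    seed: int
    exact: bool = False
    mask: Optional[np.ndarray] = None
    covariates: Optional[np.ndarray] = None


def _label_assignments(nA: int, n: int, n_perm: int, rng: np.random.Generator):
    """Yield boolean group-A membership vectors; enumerate exactly when feasible."""
    total = math.comb(n, nA)
    if total <= n_perm:
        for combo in itertools.combinations(range(n), nA):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            yield sel
        return
    for _ in range(n_perm):
        sel = np.zeros(n, dtype=bool)
        sel[rng.permutation(n)[:nA]] = True
        yield sel


def permutation_test(
    maps: Sequence[np.ndarray],
    group_labels: Sequence[str],
    n_perm: int = 5000,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    connectivity: int = 26,
    n_steps: int = 100,
    covariates: Optional[np.ndarray] = None,
) -> GroupStatResult:
    """TFCE permutation test of a two-group map difference.

    ``maps`` stacks one 3D map per subject; ``group_labels`` names each
    subject's group (exactly two distinct labels; the lexicographically first
    is "A", so positive t means A > B).  The familywise-corrected p-value at
    voxel v is ``(1 + #{perm : max-voxel TFCE_perm >= TFCE_obs(v)}) / (n_perm + 1)``,
    computed separately for each direction with shared label shuffles.  When
    fewer distinct label assignments than ``n_perm`` exist they are enumerated
    exhaustively and the test is exact.
    """
    if n_perm < 100:
        raise DataError("n_perm must be at least 100")
    Y = _stack(maps)
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise DataError(f"expected exactly two group labels, got {uniq}")
    isA = labels == uniq[0]
    nA, n = int(isA.sum()), len(labels)
    shape = Y.shape[1:]
    mask = np.all(np.isfinite(Y), axis=0)
    Yf = np.where(mask, Y, 0.0)

    def tmap_for(sel: np.ndarray) -> np.ndarray:
        assert sel.sum() == nA, "permutation must preserve group sizes"
        if covariates is not None:
            t = two_sample_tmap(Y[sel], Y[~sel], covariates=np.concatenate(
                [np.atleast_2d(covariates)[sel], np.atleast_2d(covariates)[~sel]]
            ))
        else:
            t = _pooled_t(
                Yf[sel].reshape(sel.sum(), -1), Yf[~sel].reshape(n - nA, -1)
            ).reshape(shape)
        return np.where(mask, np.nan_to_num(t), 0.0)

    t_obs = tmap_for(isA)
    tfce_pos = tfce_enhance(t_obs, E=E, H=H, connectivity=connectivity, n_steps=n_steps)
    tfce_neg = tfce_enhance(-t_obs, E=E, H=H, connectivity=connectivity, n_steps=n_steps)

    rng = np.random.default_rng(seed)
    assignments = list(_label_assignments(nA, n, n_perm, rng))
    exact = len(assignments) < n_perm
    null_max_pos = np.empty(len(assignments))
    null_max_neg = np.empty(len(assignments))
    for i, sel in enumerate(assignments):
        t_p = tmap_for(sel)
        null_max_pos[i] = tfce_enhance(
            t_p, E=E, H=H, connectivity=connectivity, n_steps=n_steps
        ).max()
        null_max_neg[i] = tfce_enhance(
            -t_p, E=E, H=H, connectivity=connectivity, n_steps=n_steps
        ).max()
    n_eff = len(assignments)

    def pmap(obs: np.ndarray, null_max: np.ndarray) -> np.ndarray:
        exceed = (null_max[:, None] >= obs.ravel()[None, :]).sum(axis=0)
        p = (1.0 + exceed) / (n_eff + 1.0)
        out = p.reshape(shape)
        return np.where(mask, out, np.nan)

    t_out = np.where(mask, t_obs, np.nan)
    return GroupStatResult(
        t_map=t_out,
        tfce_pos=np.where(mask, tfce_pos, np.nan),
        tfce_neg=np.where(mask, tfce_neg, np.nan),
        p_corr_pos=pmap(tfce_pos, null_max_pos),
        p_corr_neg=pmap(tfce_neg, null_max_neg),
        n_perm=n_eff,
        seed=seed,
        exact=exact,
        mask=mask,
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# tissue-level and summary tests


@dataclass
class TissueGroupTest:
    """Per-lag t tests of tissue cross-correlation curves with Bonferroni correction."""

    lags_s: np.ndarray
    t: dict  # tissue -> t per lag
    p: dict  # tissue -> p per lag
    sig_corrected: dict  # tissue -> bool per lag (p < alpha / n_lags)
    sig_uncorrected: dict  # tissue -> bool per lag (p < alpha)
    bonferroni_alpha: float
    alpha: float
    paired: bool = False


def lagwise_tissue_test(
    xc_A: Sequence[TissueXCorr],
    xc_B: Sequence[TissueXCorr],
    alpha: float = 0.05,
    paired: bool = False,
) -> TissueGroupTest:
    """Compare tissue cross-correlation curves between two stacks at each lag.

    Uses pooled two-sample t per lag (or paired t when ``paired=True`` and the
    stacks are subject-matched in order).  Lags are flagged significant at
    both the Bonferroni-corrected level alpha/n_lags and the uncorrected
    alpha.
    """
    lags = xc_A[0].grid.lags_s
    for xc in list(xc_A) + list(xc_B):
        if len(xc.grid.lags_s) != len(lags) or not np.allclose(xc.grid.lags_s, lags):
            raise DataError("tissue cross-correlation stacks have mismatched lag grids")
    tissues = [t for t in xc_A[0].r if all(t in xc.r for xc in list(xc_A) + list(xc_B))]
    n_lags = len(lags)
    corrected = alpha / n_lags
    t_d, p_d, sc, su = {}, {}, {}, {}
    for tissue in tissues:
        A = np.stack([xc.r[tissue] for xc in xc_A])
        B = np.stack([xc.r[tissue] for xc in xc_B])
        if paired:
            if A.shape[0] != B.shape[0]:
                raise DataError("paired test requires matched stacks")
            res = stats.ttest_rel(A, B, axis=0)
        else:
            res = stats.ttest_ind(A, B, axis=0, equal_var=True)
        t_d[tissue], p_d[tissue] = np.asarray(res.statistic), np.asarray(res.pvalue)
        sc[tissue] = p_d[tissue] < corrected
        su[tissue] = p_d[tissue] < alpha
    return TissueGroupTest(
        lags_s=lags, t=t_d, p=p_d, sig_corrected=sc, sig_uncorrected=su,
        bonferroni_alpha=corrected, alpha=alpha, paired=paired,
    )


def cohort_summary_tests(
    summaries: pd.DataFrame,
    metrics: Sequence[str],
    group_col: str = "age_group",
    session_col: Optional[str] = None,
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Group comparisons of scan-level physiological summary metrics.

    For each metric: Welch two-sample t between the two groups (on the
    baseline session if ``session_col`` is given), plus paired pre-vs-post t
    within each group when sessions are present.  Metrics with fewer than 4
    valid values in a group are skipped with a note.  IQR outlier screening is
    expected to have been applied per metric beforehand (``iqr_screen``).
    """
    groups = sorted(summaries[group_col].dropna().unique())
    if len(groups) != 2:
        raise DataError(f"expected two groups in {group_col}, got {groups}")
    rows = []
    base = summaries
    if session_col is not None:
        base = summaries[summaries[session_col] == "pre"]
    for metric in metrics:
        a = base.loc[base[group_col] == groups[0], metric].dropna()
        b = base.loc[base[group_col] == groups[1], metric].dropna()
        row = {"metric": metric, "group_a": groups[0], "group_b": groups[1],
               "mean_a": a.mean(), "var_a": a.var(), "mean_b": b.mean(), "var_b": b.var()}
        if len(a) < 4 or len(b) < 4:
            row["note"] = "skipped: fewer than 4 valid values in a group"
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row["t"], row["p"] = float(t), float(p)
        if session_col is not None:
            for g in groups:
                sub = summaries[summaries[group_col] == g].pivot_table(
                    index=subject_col, columns=session_col, values=metric
                ).dropna()
                if {"pre", "post"} <= set(sub.columns) and len(sub) >= 4:
                    d = (sub["post"] - sub["pre"]).to_numpy()
                    if np.ptp(d) == 0:  # all differences identical (e.g. pre == post)
                        t = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
                        p = 1.0 if d[0] == 0 else 0.0
                    else:
                        t, p = stats.ttest_rel(sub["post"], sub["pre"])
                    row[f"t_postpre_{g}"], row[f"p_postpre_{g}"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows)
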