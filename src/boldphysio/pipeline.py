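"""End-to-end orchestration: physio -> regressors -> PVE -> xcorr -> group.

Each stage writes its outputs under ``<outdir>/<stage>/`` and drops a
``.done`` marker; a completed stage is skipped unless ``force`` is given.
Every run records provenance (config hash, seed, package version).  All
outputs are byte-reproducible for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import DataError, PipelineError
from .glm import run_three_models
from .inference import lagwise_tissue_test, permutation_test
from .io import load_manifest, load_subject, save_nifti
from .physio import (
    PhysioTimecourse,
    align_capnograph,
    breathing_rate,
    clean_ibi,
    detect_beats,
    hr_timecourse,
    hrv_metrics,
    normalize_rv,
    petco2_timecourse,
    rv_timecourse,
)
from .responses import build_regressors
from .xcorr import tissue_xcorr, voxelwise_xcorr

__all__ = ["STAGES", "run_pipeline"]

log = logging.getLogger("boldphysio")

STAGES = ("physio", "regressors", "pve", "xcorr", "group")
_DEPS = {
    "physio": (),
    "regressors": ("physio",),
    "pve": ("physio",),
    "xcorr": ("physio",),
    "group": ("pve", "xcorr"),
}


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _done(outdir: Path, stage: str) -> Path:
    return outdir / stage / ".done"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _load_timecourses(outdir: Path, subject: str, session: str, config: PipelineConfig) -> dict:
    path = outdir / "physio" / f"{subject}_{session}_timecourses.tsv"
    if not path.exists():
        raise PipelineError(f"missing physio-stage output {path}; run the physio stage first")
    df = pd.read_csv(path, sep="\t")
    return {
        kind: PhysioTimecourse(df[kind].to_numpy(), config.tr_s, kind)
        for kind in df.columns
    }


def _stage_physio(config: PipelineConfig, manifest: pd.DataFrame, root: Path, outdir: Path) -> None:
    d = _stage_dir(outdir, "physio")
    summaries = []
    for _, row in manifest.iterrows():
        bold, recs = load_subject(row, root, config.tr_s)
        n_vols = bold.n_vols
        beats = clean_ibi(detect_beats(recs["ppg"]))
        tcs = {"hr_bpm": hr_timecourse(beats, config.tr_s, n_vols)}
        resp = recs.get("respiration")
        co2_tc = None
        if config.respiratory_measure == "petco2" and "capnograph" in recs:
            shift = align_capnograph(recs["capnograph"], resp, config.co2_max_shift_s)
            co2_tc = petco2_timecourse(recs["capnograph"], shift, config.tr_s, n_vols)
            tcs["petco2_mmHg"] = co2_tc
        rv_raw = rv_timecourse(resp, config.tr_s, n_vols)
        if config.respiratory_measure == "rv":
            tcs["rv_norm"] = normalize_rv(rv_raw)
        br = breathing_rate(resp)
        try:
            hrv = hrv_metrics(beats, rv=rv_raw, co2=co2_tc, breathing_rate_bpm=br)
        except DataError as exc:  # e.g. scan too short for spectral HRV
            log.warning("HRV summary unavailable for %s/%s: %s", row.subject, row.session, exc)
            nan = float("nan")
            from .physio import HRVSummary

            hrv = HRVSummary(nan, nan, nan, float(60.0 / np.mean(beats.ibi_s)),
                             sd_rv=float(np.std(rv_raw.values)),
                             breathing_rate_bpm=br,
                             avg_co2_mmHg=float(np.mean(co2_tc.values)) if co2_tc else None)
        summaries.append(
            {
                "subject": row.subject,
                "age_group": row.age_group,
                "condition": row.condition,
                "session": row.session,
                "ln_rmssd": hrv.ln_rmssd,
                "ln_lf": hrv.ln_lf,
                "ln_hf": hrv.ln_hf,
                "avg_hr_bpm": hrv.avg_hr_bpm,
                "sd_rv": hrv.sd_rv,
                "breathing_rate_bpm": hrv.breathing_rate_bpm,
                "avg_co2_mmHg": hrv.avg_co2_mmHg,
            }
        )
        out = pd.DataFrame({k: tc.values for k, tc in tcs.items()})
        _write_tsv(out, d / f"{row.subject}_{row.session}_timecourses.tsv")
    _write_tsv(pd.DataFrame(summaries), d / "hrv_summaries.tsv")


def _stage_regressors(config: PipelineConfig, manifest: pd.DataFrame, root: Path, outdir: Path) -> None:
    d = _stage_dir(outdir, "regressors")
    for _, row in manifest.iterrows():
        tcs = _load_timecourses(outdir, row.subject, row.session, config)
        for tag in ("joint", "cardiac", "respiratory"):
            design = build_regressors(
                tcs, tag, config.tr_s, config.n_vols,
                drift_order=config.drift_order, conv_dt_s=config.conv_dt_s,
            )
            df = pd.DataFrame(design.columns, columns=design.labels)
            _write_tsv(df, d / f"{row.subject}_{row.session}_{tag}_design.tsv")


def _stage_pve(config: PipelineConfig, manifest: pd.DataFrame, root: Path, outdir: Path) -> None:
    d = _stage_dir(outdir, "pve")
    rows = []
    for _, row in manifest.iterrows():
        bold, _ = load_subject(row, root, config.tr_s)
        tcs = _load_timecourses(outdir, row.subject, row.session, config)
        maps = run_three_models(
            bold, tcs, drift_order=config.drift_order,
            denominator=config.pve_denominator,
            subject=row.subject, session=row.session,
        )
        for tag, pmap in maps.items():
            save_nifti(pmap.values, d / f"{row.subject}_{row.session}_{tag}_pve.nii.gz")
            rec = {"subject": row.subject, "session": row.session,
                   "age_group": row.age_group, "model": tag}
            for tissue in ("gray", "white", "ventricles"):
                if tissue in bold.masks:
                    rec[f"pve_{tissue}"] = pmap.mask_mean(bold.masks[tissue])
            rows.append(rec)
    _write_tsv(pd.DataFrame(rows), d / "pve_tissue_means.tsv")


def _stage_xcorr(config: PipelineConfig, manifest: pd.DataFrame, root: Path, outdir: Path) -> None:
    d = _stage_dir(outdir, "xcorr")
    grid = config.lag_grid()
    tissue_rows = []
    for _, row in manifest.iterrows():
        bold, _ = load_subject(row, root, config.tr_s)
        tcs = _load_timecourses(outdir, row.subject, row.session, config)
        for kind, tc in tcs.items():
            lmap = voxelwise_xcorr(bold, tc, grid)
            save_nifti(lmap.values, d / f"{row.subject}_{row.session}_{kind}_xcorr.nii.gz")
            (d / f"{row.subject}_{row.session}_{kind}_lags.json").write_text(
                json.dumps({"lags_s": grid.lags_s.tolist()}, sort_keys=True) + "\n"
            )
            txc = tissue_xcorr(bold, tc, grid, upsample_dt_s=config.upsample_dt_s)
            for tissue, r in txc.r.items():
                for lag, rv in zip(txc.grid.lags_s, r):
                    tissue_rows.append(
                        {"subject": row.subject, "session": row.session,
                         "age_group": row.age_group, "physio": kind,
                         "tissue": tissue, "lag_s": lag, "r": rv}
                    )
    _write_tsv(pd.DataFrame(tissue_rows), d / "tissue_xcorr.tsv")


def _stage_group(config: PipelineConfig, manifest: pd.DataFrame, root: Path, outdir: Path) -> None:
    from .io import load_nifti
    from .xcorr import LagGrid, TissueXCorr

    d = _stage_dir(outdir, "group")
    pre = manifest[manifest.session == "pre"] if "pre" in set(manifest.session) else manifest
    groups = sorted(pre.age_group.unique())
    if len(groups) != 2:
        raise PipelineError(f"group stage needs exactly two age groups, got {groups}")
    maps, labels = [], []
    for _, row in pre.iterrows():
        v, _ = load_nifti(outdir / "pve" / f"{row.subject}_{row.session}_joint_pve.nii.gz")
        maps.append(v)
        labels.append(row.age_group)
    res = permutation_test(maps, labels, n_perm=config.n_perm, seed=config.seed)
    save_nifti(np.nan_to_num(res.t_map), d / "pve_joint_tmap.nii.gz")
    save_nifti(np.nan_to_num(res.p_corr_pos, nan=1.0), d / "pve_joint_pcorr_pos.nii.gz")
    save_nifti(np.nan_to_num(res.p_corr_neg, nan=1.0), d / "pve_joint_pcorr_neg.nii.gz")

    tx = pd.read_csv(outdir / "xcorr" / "tissue_xcorr.tsv", sep="\t")
    tx = tx[tx.session.isin(pre.session.unique())]
    kinds = sorted(tx.physio.unique())
    lag_rows = []
    for kind in kinds:
        sub = tx[tx.physio == kind]
        stacks = {g: [] for g in groups}
        for (subject, g), block in sub.groupby(["subject", "age_group"]):
            piv = block.pivot_table(index="lag_s", columns="tissue", values="r").sort_index()
            grid = LagGrid(piv.index.to_numpy())
            stacks[g].append(
                TissueXCorr(r={t: piv[t].to_numpy() for t in piv.columns},
                            grid=grid, physio_kind=kind)
            )
        test = lagwise_tissue_test(stacks[groups[0]], stacks[groups[1]], alpha=config.alpha)
        for tissue in test.t:
            for i, lag in enumerate(test.lags_s):
                lag_rows.append(
                    {"physio": kind, "tissue": tissue, "lag_s": lag,
                     "t": test.t[tissue][i], "p": test.p[tissue][i],
                     "sig_bonferroni": bool(test.sig_corrected[tissue][i]),
                     "sig_uncorrected": bool(test.sig_uncorrected[tissue][i])}
                )
    _write_tsv(pd.DataFrame(lag_rows), d / "tissue_lag_tests.tsv")
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_perm": res.n_perm,
        "exact": res.exact,
        "contrast": f"{groups[0]} vs {groups[1]} (pre)",
        "version": __version__,
    }
    (d / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")


_RUNNERS = {
    "physio": _stage_physio,
    "regressors": _stage_regressors,
    "pve": _stage_pve,
    "xcorr": _stage_xcorr,
    "group": _stage_group,
}


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    outdir: str | Path,
    stages: Optional[Sequence[str]] = None,
    force: bool = False,
) -> Path:
    """Run the requested stages over a cohort manifest; returns the run directory.

    Stage dependencies must already be satisfied (each stage checks for its
    upstream outputs).  A completed stage is a no-op unless ``force``.
    """
    config.validate()
    manifest_path = Path(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(manifest_path)
    root = manifest_path.parent
    wanted = list(stages) if stages else list(STAGES)
    for s in wanted:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; stages are {STAGES}")
    for stage in STAGES:
        if stage not in wanted:
            continue
        for dep in _DEPS[stage]:
            if not _done(outdir, dep).exists():
                raise PipelineError(f"stage {stage!r} requires completed stage {dep!r}")
        if _done(outdir, stage).exists() and not force:
            log.info("stage %s up to date, skipping", stage)
            continue
        log.info("running stage %s", stage)
        _RUNNERS[stage](config, manifest, root, outdir)
        _done(outdir, stage).write_text("")
    (outdir / "provenance.json").write_text(
        json.dumps(
            {"config_hash": _config_hash(config), "seed": config.seed,
             "version": __version__},
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return outdir
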