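"""File I/O: NIfTI volumes, BIDS-style physio TSV + JSON sidecars, cohort manifests.

NIfTI-1 gzipped volumes are written through a deterministic gzip wrapper
(mtime 0, no embedded filename) so that identical data always produces
byte-identical files — a requirement for reproducible pipeline runs.
Physiological recordings follow the BIDS physio convention: a tab-separated
table of columns plus a JSON sidecar with ``SamplingFrequency``,
``StartTime`` and ``Columns``.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError
from .glm import BOLDVolume
from .physio import PhysioRecording

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_physio",
    "read_physio",
    "load_manifest",
    "load_subject",
]

_MODALITY_COLUMNS = {"ppg": "ppg", "respiration": "respiration", "capnograph": "co2"}
_COLUMN_MODALITY = {v: k for k, v in _MODALITY_COLUMNS.items()}


def save_nifti(
    data: np.ndarray, path: str | Path, affine: Optional[np.ndarray] = None
) -> Path:
    """Write an array as (optionally gzipped) NIfTI-1, byte-stable across runs."""
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), affine)
    raw = img.to_bytes()
    if path.suffix == ".gz":
        payload = gzip.compress(raw, mtime=0)
    else:
        payload = raw
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(payload)
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_physio(
    recordings: Mapping[str, PhysioRecording], prefix: str | Path
) -> tuple[Path, Path]:
    """Write recordings as ``<prefix>.tsv`` + ``<prefix>.json`` (BIDS physio style).

    All recordings must share sampling rate and start time; columns are named
    ppg / respiration / co2 according to modality.
    """
    recs = list(recordings.values())
    fs = recs[0].fs
    t0 = recs[0].start_time_s
    for r in recs:
        if abs(r.fs - fs) > 1e-9 or abs(r.start_time_s - t0) > 1e-9:
            raise DataError("all physio recordings must share fs and start time")
    n = min(len(r.samples) for r in recs)
    cols = {_MODALITY_COLUMNS[r.modality]: r.samples[:n] for r in recs}
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    df = pd.DataFrame(cols)
    df.to_csv(tsv, sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "SamplingFrequency": fs,
        "StartTime": t0,
        "Columns": list(cols.keys()),
    }
    js = prefix.with_suffix(".json")
    js.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return tsv, js


def read_physio(prefix: str | Path) -> dict:
    """Read a BIDS-style physio TSV + sidecar into recordings keyed by modality."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    js = prefix.with_suffix(".json")
    if not tsv.exists() or not js.exists():
        raise DataError(f"missing physio files {tsv} / {js}")
    meta = json.loads(js.read_text())
    for key in ("SamplingFrequency", "StartTime", "Columns"):
        if key not in meta:
            raise DataError(f"physio sidecar {js} missing {key}")
    df = pd.read_csv(tsv, sep="\t")
    out = {}
    for col in meta["Columns"]:
        if col not in df.columns:
            raise DataError(f"physio TSV {tsv} missing declared column {col}")
        modality = _COLUMN_MODALITY.get(col)
        if modality is None:
            continue
        out[modality] = PhysioRecording(
            samples=df[col].to_numpy(dtype=float),
            fs=float(meta["SamplingFrequency"]),
            modality=modality,
            start_time_s=float(meta["StartTime"]),
        )
    return out


MANIFEST_COLUMNS = ["subject", "age_group", "condition", "session", "bold", "physio",
                    "mask_brain", "mask_gray", "mask_white", "mask_ventricles",
                    "true_pve"]


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise DataError(f"manifest missing columns: {missing}")
    dup = df.duplicated(subset=["subject", "session"])
    if dup.any():
        raise DataError(f"duplicate subject/session rows: {df.loc[dup, 'subject'].tolist()}")
    if check_paths:
        root = path.parent
        for col in df.columns:
            if col in ("subject", "age_group", "condition", "session"):
                continue
            for p in df[col].dropna():
                if not (root / p).exists():
                    raise DataError(f"manifest references missing file: {p}")
    return df


def load_subject(row: Mapping, root: str | Path, tr_s: float) -> tuple[BOLDVolume, dict]:
    """Load one manifest row into a BOLDVolume plus physiological recordings.

    Validates that every mask shares the BOLD spatial grid and that the physio
    recording covers the scan duration (within one TR).
    """
    root = Path(root)
    data, affine = load_nifti(root / row["bold"])
    if data.ndim != 4:
        raise DataError(f"BOLD file {row['bold']} is not 4D (shape {data.shape})")
    masks = {}
    for name in ("brain", "gray", "white", "ventricles"):
        key = f"mask_{name}"
        if key in row and isinstance(row[key], str):
            m, _ = load_nifti(root / row[key])
            if m.shape != data.shape[:3]:
                raise DataError(
                    f"mask {name} grid {m.shape} != BOLD grid {data.shape[:3]}"
                )
            masks[name] = m > 0.5
    bold = BOLDVolume(data=data, tr_s=tr_s, masks=masks, affine=affine)
    physio_prefix = root / str(row["physio"])
    if physio_prefix.suffix == ".tsv":
        physio_prefix = physio_prefix.with_suffix("")
    recordings = read_physio(physio_prefix)
    scan_dur = data.shape[3] * tr_s
    for modality, rec in recordings.items():
        if rec.duration_s < scan_dur - tr_s:
            raise DataError(
                f"{modality} recording ({rec.duration_s:.1f} s) shorter than scan "
                f"({scan_dur:.1f} s)"
            )
    return bold, recordings
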