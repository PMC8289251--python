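"""Disk formats: NIfTI-1 volumes/masks, CSV subject and feature tables,
JSON manifests.

Masks use the nonzero-equals-in-ROI dialect. A mask on a different lattice
than its volume is rejected outright — it is never resampled silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ThalradError
from .features import FeatureConfig, RoiMask, VoxelGrid, extract_all, run_manifest
from .outcomes import SubjectRecord

__all__ = [
    "save_nifti", "load_nifti_grid", "load_nifti_mask",
    "save_cohort", "load_cohort",
    "records_to_frame", "frame_to_records",
    "extract_table", "save_manifest", "sha256_of_file",
]

TABLE_COLUMNS = (
    "subject_id", "class_label", "dataset_id", "panss_baseline",
    "panss_discharge",
)


def save_nifti(path, values: np.ndarray, spacing_mm) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_nifti_grid(path) -> VoxelGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(np.asarray(img.dataobj, dtype=float), spacing)


def load_nifti_mask(path, grid: Optional[VoxelGrid] = None) -> RoiMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if grid is not None and data.shape != grid.values.shape:
        raise ThalradError(
            f"mask shape {data.shape} does not match volume "
            f"{grid.values.shape}; refusing to resample silently"
        )
    return RoiMask(data != 0)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "class_label": r.class_label,
            "dataset_id": r.dataset_id,
            "panss_baseline": r.panss_baseline_total,
            "panss_discharge": r.panss_discharge_total,
        })
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    recs = []
    for _, row in df.iterrows():
        def as_int(v):
            return None if pd.isna(v) else int(v)
        recs.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            class_label=str(row["class_label"]),
            dataset_id=int(row["dataset_id"]),
            panss_baseline_total=as_int(row.get("panss_baseline")),
            panss_discharge_total=as_int(row.get("panss_discharge")),
        ))
    return recs


def save_cohort(
    out_dir,
    images: Sequence[tuple[VoxelGrid, RoiMask]],
    records: Sequence[SubjectRecord],
) -> Path:
    """Write per-subject volume/mask NIfTI pairs and the subject CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (grid, mask), rec in zip(images, records):
        save_nifti(out / f"{rec.subject_id}_vol.nii.gz", grid.values,
                   grid.spacing_mm)
        save_nifti(out / f"{rec.subject_id}_mask.nii.gz",
                   mask.membership.astype(np.uint8), grid.spacing_mm)
    records_to_frame(records).to_csv(out / "subjects.csv", index=False)
    return out


def load_cohort(cohort_dir) -> tuple[list[tuple[VoxelGrid, RoiMask]],
                                     list[SubjectRecord]]:
    d = Path(cohort_dir)
    records = frame_to_records(pd.read_csv(d / "subjects.csv"))
    images = []
    for rec in records:
        grid = load_nifti_grid(d / f"{rec.subject_id}_vol.nii.gz")
        mask = load_nifti_mask(d / f"{rec.subject_id}_mask.nii.gz", grid)
        images.append((grid, mask))
    return images, records


def extract_table(
    images: Sequence[tuple[VoxelGrid, RoiMask]],
    subject_ids: Sequence[str],
    config: FeatureConfig = FeatureConfig(),
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Feature table (rows = subjects, columns = canonical names).

    ``on_error='skip'`` drops failing subjects and returns them with their
    error messages; ``'raise'`` propagates the first failure.
    """
    rows: list[OrderedDict] = []
    kept_ids: list[str] = []
    failures: list[tuple[str, str]] = []
    for sid, (grid, mask) in zip(subject_ids, images):
        try:
            rows.append(extract_all(grid, mask, config))
            kept_ids.append(sid)
        except Exception as exc:            # noqa: BLE001 - per-subject policy
            if on_error == "raise":
                raise
            failures.append((sid, f"{type(exc).__name__}: {exc}"))
    table = pd.DataFrame(rows, index=pd.Index(kept_ids, name="subject_id"))
    return table, failures


def save_manifest(path, config: FeatureConfig, extra: Optional[dict] = None
                  ) -> None:
    manifest = run_manifest(config)
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def sha256_of_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
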