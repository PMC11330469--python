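"""Cohort serialization: NIfTI volumes plus a CSV manifest.

One NIfTI file per channel per subject and one mask NIfTI, with the voxel
spacing stored in the affine; subject labels and channel-presence flags live
in ``manifest.csv``.  ``read_cohort(write_cohort(x))`` reproduces arrays
bit-exactly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import CLASS_NAMES, SubjectVolume

MANIFEST_NAME = "manifest.csv"


class CohortIOError(RuntimeError):
    """Malformed manifest or inconsistent volume files."""


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    return aff


def write_cohort(cohort: Sequence[SubjectVolume], directory: str | os.PathLike) -> Path:
    """Write a cohort to ``directory``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        aff = _affine(s.spacing)
        row: dict[str, object] = {"subject_id": s.subject_id, "label": s.label}
        for c in range(s.images.shape[0]):
            fname = f"{s.subject_id}_ch{c + 1}.nii.gz"
            nib.save(nib.Nifti1Image(s.images[c], aff), directory / fname)
            row[f"channel_{c + 1}"] = fname
            row[f"present_{c + 1}"] = int(s.present_channels[c])
        mname = f"{s.subject_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(s.mask.astype(np.uint8), aff), directory / mname)
        row["mask"] = mname
        rows.append(row)
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(directory: str | os.PathLike) -> list[SubjectVolume]:
    """Read a cohort written by :func:`write_cohort`, validating as it goes."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise CohortIOError(f"missing manifest: {manifest}")
    df = pd.read_csv(manifest)
    channel_cols = sorted(
        (c for c in df.columns if c.startswith("channel_")),
        key=lambda c: int(c.split("_")[1]),
    )
    cohort: list[SubjectVolume] = []
    for idx, row in df.iterrows():
        label = str(row["label"])
        if label not in CLASS_NAMES:
            raise CohortIOError(
                f"manifest row {idx}: unknown class label {label!r} "
                f"(expected one of {CLASS_NAMES})"
            )
        mask_img = nib.load(directory / str(row["mask"]))
        mask = np.asarray(mask_img.dataobj).astype(bool)
        spacing = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
        images = []
        present = []
        for c, col in enumerate(channel_cols, start=1):
            fname = directory / str(row[col])
            arr = np.asarray(nib.load(fname).dataobj, dtype=np.float32)
            if arr.shape != mask.shape:
                raise CohortIOError(
                    f"{fname.name}: image shape {arr.shape} does not match "
                    f"mask shape {mask.shape}"
                )
            images.append(arr)
            present.append(bool(int(row[f"present_{c}"])))
        cohort.append(
            SubjectVolume(
                subject_id=str(row["subject_id"]),
                images=np.stack(images),
                present_channels=np.asarray(present, dtype=bool),
                mask=mask,
                spacing=spacing,
                label=label,
            )
        )
    return cohort
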