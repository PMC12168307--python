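"""NIfTI subject ingestion and table writing."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .cohort import SubjectVolumes
from .errors import GeometryMismatchError


def _load(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise GeometryMismatchError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_subject(paths: dict[str, str | Path], subject_id: str | None = None) -> SubjectVolumes:
    """Load one subject's four volumes (t2w, adc, mask_left, mask_right).

    Shapes and header spacings must agree across the four files; masks are
    binarized at > 0 (with a warning if they were not already 0/1).
    """
    arrays = {}
    zooms = {}
    for key in ("t2w", "adc", "mask_left", "mask_right"):
        if key not in paths:
            raise GeometryMismatchError(f"missing path for {key!r}")
        arrays[key], zooms[key] = _load(paths[key])
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise GeometryMismatchError(f"inconsistent shapes: {sorted(shapes)}")
    if len({tuple(np.round(z, 6)) for z in zooms.values()}) != 1:
        raise GeometryMismatchError(f"inconsistent spacings: {zooms}")
    masks = {}
    for key in ("mask_left", "mask_right"):
        m = arrays[key]
        uniq = np.unique(m)
        if not np.all(np.isin(uniq, (0, 1))):
            warnings.warn(f"{key} has non-binary values {uniq[:5]}; binarizing at > 0")
        masks[key] = (m > 0).astype(np.uint8)
    return SubjectVolumes(
        subject_id=subject_id or Path(paths["t2w"]).stem.split("_")[0],
        t2w=arrays["t2w"],
        adc=arrays["adc"],
        mask_left=masks["mask_left"],
        mask_right=masks["mask_right"],
        spacing=zooms["t2w"],
    )


def read_cohort_dir(cohort_dir: str | Path):
    """Load every subject written by ``write_cohort`` plus the clinical CSV."""
    import pandas as pd

    d = Path(cohort_dir)
    clinical = pd.read_csv(d / "clinical.csv")
    subjects = []
    for sid in clinical["subject_id"]:
        subjects.append(
            read_subject(
                {k: d / f"{sid}_{k}.nii.gz" for k in ("t2w", "adc", "mask_left", "mask_right")},
                subject_id=sid,
            )
        )
    return subjects, clinical
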