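"""NIfTI volume and CSV table I/O."""

from __future__ import annotations

from pathlib import Path
from typing import List, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import Subject


def save_volume(volume: np.ndarray, path: Union[str, Path], voxel_size: float = 1.0) -> None:
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_volume(path: Union[str, Path]) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_mask(mask: np.ndarray, path: Union[str, Path], voxel_size: float = 1.0) -> None:
    save_volume(np.asarray(mask, dtype=np.uint8), path, voxel_size)


def load_mask(path: Union[str, Path]) -> np.ndarray:
    return load_volume(path) > 0.5


def cohort_table(subjects: List[Subject]) -> pd.DataFrame:
    """One row per subject: readings, resting values, MAP, rule labels."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        for i, (sbp, dbp) in enumerate(s.bp_readings, start=1):
            row[f"sbp_{i}"] = sbp
            row[f"dbp_{i}"] = dbp
        row.update(
            resting_sbp=s.resting_sbp,
            resting_dbp=s.resting_dbp,
            map_value=s.map_value,
            label_systolic=s.labels["systolic"],
            label_diastolic=s.labels["diastolic"],
            label_map=s.labels["map"],
            source=s.source,
            true_class=s.true_class,
        )
        rows.append(row)
    return pd.DataFrame(rows)
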