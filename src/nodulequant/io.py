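"""File formats: NIfTI volumes/masks, cohort CSVs, YAML configs.

Volumes are written as signed 16-bit NIfTI with the voxel spacing in the
affine; masks as uint8 NIfTI on the same grid. Cohort tables are UTF-8
comma-separated CSV with a header row and '.' decimal. Nodule/cohort configs
are flat YAML mappings whose keys are the dataclass fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .ctnumber import CTVolume, NoduleMask
from .phantom import CohortConfig, NoduleSpec, TumorRecord

__all__ = [
    "save_volume", "load_volume", "save_mask", "load_mask",
    "save_cohort", "load_cohort", "load_nodule_spec", "load_config",
]

#: Columns of the cohort CSV schema, in order.
COHORT_COLUMNS = [
    "tumor_id", "group", "invasive", "size_cm", "location", "contour",
    "necrosis", "vacuole_cyst", "mean_hu", "ggoc_pct", "sc_pct", "suv_max",
    "lepidic_pct", "appearance",
]


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.voxels.astype(np.int16),
        _affine(volume.spacing_mm, volume.origin),
    )
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(voxels=data, spacing_mm=spacing, origin=origin)


def save_mask(mask: NoduleMask, path: str | Path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(
        mask.support.astype(np.uint8), _affine(spacing_mm, (0.0, 0.0, 0.0))
    )
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def load_mask(path: str | Path, connectivity: int = 3) -> NoduleMask:
    img = nib.load(str(path))
    return NoduleMask(
        support=np.asarray(img.dataobj) > 0, connectivity=connectivity
    )


def save_cohort(records_or_frame, path: str | Path) -> None:
    """Write a cohort (records or DataFrame) to CSV in the documented schema."""
    if isinstance(records_or_frame, pd.DataFrame):
        frame = records_or_frame
    else:
        frame = pd.DataFrame([r.__dict__ for r in records_or_frame])
    frame = frame[[c for c in COHORT_COLUMNS if c in frame.columns]
                  + [c for c in frame.columns if c not in COHORT_COLUMNS]]
    frame.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"invasive", "size_cm", "sc_pct"} - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {sorted(missing)}")
    return frame


def load_config(path: str | Path) -> dict[str, Any]:
    """Flat YAML mapping; every scalar key addresses a dataclass field."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def load_nodule_spec(path: str | Path) -> NoduleSpec:
    return NoduleSpec(**load_config(path))
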