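"""Intensity standardization and cohort loading for aligned NIfTI volumes.

Volumes are assumed already spatially registered to a common template, so
that a given voxel (and hence a given descriptor cell) corresponds to the
same anatomical location in every subject. This module only standardizes
intensities: whole-volume z-scoring, clipping to [-4, 4] and linear rescale
to [0, 1]. No registration, skull-stripping, bias-field correction or
resampling is performed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class Volume:
    """One subject's 3D intensity array plus grid metadata and label."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(
                f"{self.subject_id}: volume must have exactly 3 axes, "
                f"got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: volume contains non-finite values")


@dataclasses.dataclass(frozen=True)
class NormalizedVolume:
    """A volume rescaled to [0, 1], with the removed statistics recorded."""

    data: np.ndarray
    subject_id: str
    mean_removed: float
    sd_removed: float

    def __post_init__(self) -> None:
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError(f"{self.subject_id}: normalized data outside [0, 1]")


#: z-scores are clipped to this symmetric range before rescaling to [0, 1]
CLIP_RANGE = 4.0


def zscore_normalize(vol: Volume, mask_nonzero: bool = False) -> NormalizedVolume:
    """Standardize intensities: z-score, clip to [-4, 4], rescale to [0, 1].

    Statistics use every voxel by default; ``mask_nonzero=True`` restricts the
    mean/sd to nonzero voxels (an approximation of brain-only statistics when
    background air is exactly zero). The standard deviation is the population
    (divide-by-N) form, fixed for bit-reproducibility.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    stat_values = data[data != 0] if mask_nonzero else data
    mean = float(stat_values.mean())
    sd = float(stat_values.std())  # population sd
    if sd == 0.0:
        raise ValueError(
            f"{vol.subject_id}: constant intensity (sd = 0); cannot z-score"
        )
    z = np.clip((data - mean) / sd, -CLIP_RANGE, CLIP_RANGE)
    rescaled = (z + CLIP_RANGE) / (2.0 * CLIP_RANGE)
    return NormalizedVolume(
        data=rescaled, subject_id=vol.subject_id, mean_removed=mean, sd_removed=sd
    )


def _find_nifti(nifti_dir: Path, subject_id: str) -> Path:
    candidates = [nifti_dir / f"{subject_id}{ext}" for ext in (".nii.gz", ".nii")]
    hits = [c for c in candidates if c.exists()]
    if len(hits) != 1:
        raise FileNotFoundError(
            f"subject {subject_id!r}: expected exactly one NIfTI file in "
            f"{nifti_dir}, found {len(hits)}"
        )
    return hits[0]


def load_cohort(nifti_dir: str | Path, labels_csv: str | Path) -> list[Volume]:
    """Load a labeled cohort: one NIfTI per CSV row, in CSV row order.

    The labels CSV must have a header with columns ``subject_id,label`` and
    binary labels. All volumes must share the same shape and affine (the
    alignment contract); violations raise an error naming the subject.
    """
    nifti_dir = Path(nifti_dir)
    table = pd.read_csv(labels_csv, dtype={"subject_id": str})
    missing = {"subject_id", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns: {sorted(missing)}")

    volumes: list[Volume] = []
    ref_shape: tuple[int, ...] | None = None
    ref_affine: np.ndarray | None = None
    for row in table.itertuples(index=False):
        sid = str(row.subject_id)
        label = row.label
        if label not in (0, 1):
            raise ValueError(f"subject {sid!r}: non-binary label {label!r}")
        img = nib.load(_find_nifti(nifti_dir, sid))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, img.affine
        else:
            if data.shape != ref_shape:
                raise ValueError(
                    f"subject {sid!r}: shape {data.shape} does not match "
                    f"cohort shape {ref_shape}"
                )
            if not np.allclose(img.affine, ref_affine):
                raise ValueError(
                    f"subject {sid!r}: affine does not match the cohort affine"
                )
        volumes.append(
            Volume(data=data, affine=np.asarray(img.affine), subject_id=sid,
                   label=int(label))
        )
    return volumes
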