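"""Volume/mask I/O, manifest handling, two-reader ROI superposition, geometry checks.

Volumes and masks travel as NIfTI-1 files; a cohort manifest is a CSV with
columns ``subject_id,group,phase,volume,mask`` whose paths are resolved
relative to the manifest's own directory.  Masks are binary and must be
congruent (shape and voxel spacing) with their paired volume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

PHASES = ("corticomedullary", "nephrographic")
GROUPS = ("low", "high")

#: inclusion rule: a lesion must appear on at least this many axial slices
MIN_LESION_SLICES = 7

MANIFEST_COLUMNS = ["subject_id", "group", "phase", "volume", "mask"]


class GeometryError(ValueError):
    """Shape/spacing disagreement between a volume and a mask, or wrong rank."""


@dataclass
class ImageVolume:
    """A 3D scalar field on a regular grid (HU-scale intensities).

    ``affine`` is the NIfTI voxel-to-world map and is carried opaquely;
    ``spacing`` (mm per voxel along each axis) is derived from it.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(
                f"expected a 3D volume, got {self.data.ndim}D data of shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(s) for s in nib.affines.voxel_sizes(self.affine))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ROIMask:
    """Binary lesion mask congruent with its paired :class:`ImageVolume`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(
                f"expected a 3D mask, got {self.data.ndim}D data of shape {self.data.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(s) for s in nib.affines.voxel_sizes(self.affine))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def n_slices(self, axis: int = 2) -> int:
        """Number of axial slices on which the mask has any foreground."""
        other = tuple(i for i in range(3) if i != axis)
        return int(np.any(self.data, axis=other).sum())


def load_volume(path: str | os.PathLike) -> ImageVolume:
    """Load a NIfTI volume; spacing comes from the header, no resampling."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, file is {img.ndim}D")
    # keep the on-disk precision (phantom volumes are float32)
    return ImageVolume(np.asanyarray(img.dataobj), img.affine)


def load_mask(path: str | os.PathLike) -> ROIMask:
    """Load a NIfTI binary mask (any voxel > 0.5 counts as foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D mask, file is {img.ndim}D")
    return ROIMask(np.asanyarray(img.dataobj) > 0.5, img.affine)


def save_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine),
        str(path),
    )


def save_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path)
    )


def _check_congruent(a, b, what: str = "mask") -> None:
    if a.shape != b.shape:
        raise GeometryError(f"{what} shape {b.shape} does not match {a.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-4):
        raise GeometryError(f"{what} spacing {b.spacing} does not match {a.spacing}")


def superimpose_rois(mask_a: ROIMask, mask_b: ROIMask, rule: str = "union") -> ROIMask:
    """Combine two readers' ROI tracings into the final analysis ROI.

    The study protocol has two readers delineate the lesion independently and
    superimposes the results.  ``rule='union'`` (default) keeps every voxel
    either reader included, maximizing captured tumor including its
    heterogeneous periphery; ``rule='intersection'`` keeps only consensus
    voxels.  The operation is commutative and idempotent.
    """
    _check_congruent(mask_a, mask_b)
    if rule == "union":
        combined = mask_a.data | mask_b.data
    elif rule == "intersection":
        combined = mask_a.data & mask_b.data
    else:
        raise ValueError(f"rule must be 'union' or 'intersection', got {rule!r}")
    return ROIMask(combined, mask_a.affine.copy())


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV; relative paths are resolved against it."""
    path = Path(path)
    manifest = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError(f"manifest {path} has no rows")
    base = path.parent
    for col in ("volume", "mask"):
        manifest[col] = [
            str(p) if os.path.isabs(p) else str(base / p) for p in manifest[col]
        ]
    return manifest


def validate_cohort(
    manifest: pd.DataFrame, min_slices: int = MIN_LESION_SLICES
) -> pd.DataFrame:
    """Per-subject conformance report against the study inclusion rules.

    Checks, per subject: both contrast phases present exactly once, all files
    readable, volume/mask geometry congruent, mask non-empty and spanning at
    least ``min_slices`` axial slices.  Returns a data frame with columns
    ``subject_id, passed, reasons``.
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    rows = []
    for subject_id, sub in manifest.groupby("subject_id", sort=True):
        reasons = []
        for phase in PHASES:
            phase_rows = sub[sub["phase"] == phase]
            if len(phase_rows) == 0:
                reasons.append(f"missing phase: {phase}")
                continue
            if len(phase_rows) > 1:
                reasons.append(f"duplicate phase: {phase}")
                continue
            row = phase_rows.iloc[0]
            try:
                vol = load_volume(row["volume"])
                mask = load_mask(row["mask"])
            except (OSError, GeometryError) as exc:
                reasons.append(f"{phase}: unreadable input ({exc})")
                continue
            try:
                _check_congruent(vol, mask)
            except GeometryError as exc:
                reasons.append(f"{phase}: geometry mismatch ({exc})")
                continue
            if mask.n_voxels == 0:
                reasons.append(f"{phase}: empty mask")
            elif mask.n_slices() < min_slices:
                reasons.append(
                    f"{phase}: slice count {mask.n_slices()} < {min_slices}"
                )
        rows.append(
            {
                "subject_id": subject_id,
                "passed": not reasons,
                "reasons": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "passed", "reasons"])
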