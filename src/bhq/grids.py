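"""Volume containers and NIfTI-1 I/O.

All maps in a cohort live on a common, already spatially normalized grid, so a
volume is just a 3-D scalar lattice plus its voxel spacing and a modality tag.
World coordinates are never needed; the affine written to disk is diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "AtlasVolume",
    "ReferenceField",
    "save_nifti",
    "load_nifti",
    "save_atlas",
    "load_atlas",
]

#: modalities a VolumeGrid may carry
MODALITIES = frozenset({"fa", "gm", "wm", "csf", "quotient", "mean", "sd"})


def _as_triple(x) -> tuple[float, float, float]:
    if np.isscalar(x):
        return (float(x),) * 3
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 voxel sizes, got {len(t)}")
    return t


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with isotropic-or-not voxel spacing in mm.

    Quotient volumes may contain NaN at out-of-mask voxels; every other
    modality must be finite everywhere.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    modality: str = "fa"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.values.shape}")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive: {self.voxel_size_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality != "quotient" and not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.modality} volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other: "VolumeGrid | AtlasVolume") -> bool:
        oshape = other.labels.shape if isinstance(other, AtlasVolume) else other.shape
        osize = other.voxel_size_mm
        return self.shape == tuple(oshape) and np.allclose(self.voxel_size_mm, osize)

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "VolumeGrid":
        return VolumeGrid(values, self.voxel_size_mm, modality or self.modality)


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation on the same grid as the scalar maps.

    Label 0 is background; ``names`` maps every positive label to a region
    name.  Every named label must occupy at least one voxel.
    """

    labels: np.ndarray
    names: Mapping[int, str] = field(default_factory=dict)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("atlas labels must be integers")
            self.labels = lab.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        present = set(np.unique(self.labels).tolist()) - {0}
        if not self.names:
            self.names = {int(k): f"region_{int(k):02d}" for k in sorted(present)}
        else:
            self.names = {int(k): str(v) for k, v in self.names.items()}
            missing = set(self.names) - present
            if missing:
                raise ValueError(f"named labels absent from lattice: {sorted(missing)}")

    @property
    def region_labels(self) -> list[int]:
        return sorted(int(k) for k in self.names)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ReferenceField:
    """Voxelwise mean/SD images defining the quotient's population norm."""

    mean: VolumeGrid
    sd: VolumeGrid
    mask: np.ndarray
    n_source_maps: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.mean.shape:
            raise ValueError("mask/mean shape mismatch")
        if self.sd.shape != self.mean.shape:
            raise ValueError("sd/mean shape mismatch")
        if self.mask.any() and not np.all(self.sd.values[self.mask] > 0):
            raise ValueError("reference SD must be positive on every masked voxel")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# NIfTI-1 round trips


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(volume: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path, modality: str = "fa") -> VolumeGrid:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), zooms, modality)


def save_atlas(atlas: AtlasVolume, path: str | Path) -> Path:
    """Write the label volume; region names go to a ``.names.json`` sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size_mm))
    img.header.set_zooms(atlas.voxel_size_mm)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
    sidecar = Path(str(sidecar) + ".names.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in atlas.names.items()}, indent=1))
    return path


def load_atlas(path: str | Path) -> AtlasVolume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asarray(img.dataobj).astype(np.int32)
    sidecar = Path(str(Path(path)).replace(".nii.gz", "").replace(".nii", "") + ".names.json")
    names: dict[int, str] = {}
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return AtlasVolume(labels, names, zooms)
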