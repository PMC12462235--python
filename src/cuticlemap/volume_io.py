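"""Volumetric containers and file I/O.

The package works on three kinds of 3D grids: grayscale volumes (the
tomographic reconstruction), binary segmentation masks (the cuticle
segmentation) and integer thickness fields (the encoded relative-thickness
"second data set").  All grids use 0-based voxel indices in ``(z, y, x)``
order with voxel-centre geometry; voxel spacing is carried as metadata only
— thickness values are run *counts* in voxels, never micrometres, because
the method is explicitly relative.

Supported formats: NIfTI-1 (``.nii``/``.nii.gz``) and numbered TIFF stacks
(``slice_0000.tif`` ...).  Thickness fields store their search radius in a
JSON sidecar (``<file>.json``).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "GrayscaleVolume",
    "SegmentationMask",
    "ThicknessField",
    "RegionLabelMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_thickness_field",
    "write_thickness_field",
    "write_labels",
    "read_labels",
    "binarize",
]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in np.atleast_1d(spacing).ravel())
    if len(spacing) == 1:
        spacing = spacing * 3
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be 3 positive finite scalars, got {spacing}")
    return spacing


@dataclass
class GrayscaleVolume:
    """3D scalar grid with isotropic-or-not voxel spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Binary foreground mask congruent with its companion volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class ThicknessField:
    """Per-voxel encoded run counts, 0 on background, capped at ``rmax``."""

    data: np.ndarray
    rmax: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"thickness field must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("thickness field must be an integer grid")
        self.rmax = int(self.rmax)
        if self.rmax < 1:
            raise ValueError("rmax must be a positive integer")
        self.validate()
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def validate(self) -> None:
        if self.data.size and self.data.min() < 0:
            raise ValueError("thickness field has negative values")
        if self.data.size and self.data.max() > self.rmax:
            raise ValueError(
                f"thickness field max {int(self.data.max())} exceeds rmax {self.rmax}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RegionLabelMap:
    """Small-integer region labels with a legend mapping label -> name."""

    data: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be an integer grid")
        self.legend = {int(k): str(v) for k, v in dict(self.legend).items()}
        present = set(int(v) for v in np.unique(self.data))
        missing = present - set(self.legend) - {0}
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in data but absent from legend")


# ---------------------------------------------------------------------------
# NIfTI / TIFF-stack readers and writers
# ---------------------------------------------------------------------------

_SLICE_RE = re.compile(r"slice_(\d+)\.tiff?$")


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tiff_stack"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from {path}")


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        logger.warning("%s: missing/invalid voxel size in header, assuming 1.0", path)
        zooms = (1.0, 1.0, 1.0)
    return data, tuple(float(z) for z in zooms)


def _read_tiff_stack(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(path.glob("slice_*.tif")) + sorted(path.glob("slice_*.tiff"))
        if not files:
            raise FileNotFoundError(f"no slice_*.tif files in {path}")
        slices = []
        shape0 = None
        for f in files:
            sl = tifffile.imread(str(f))
            if sl.ndim != 2:
                raise ValueError(f"{f}: expected a 2D slice, got shape {sl.shape}")
            if shape0 is None:
                shape0 = sl.shape
            elif sl.shape != shape0:
                raise ValueError(
                    f"{f}: slice shape {sl.shape} differs from first slice {shape0}"
                )
            slices.append(sl)
        return np.stack(slices, axis=0)
    data = tifffile.imread(str(path))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D TIFF, got shape {data.shape}")
    return data


def read_volume(path, format: str | None = None) -> GrayscaleVolume:
    """Read a grayscale volume from NIfTI or a numbered TIFF stack.

    Spacing is taken from the NIfTI header when present; TIFF stacks are
    assumed isotropic 1.0 µm (a warning is logged), matching the convention
    that thickness is measured in voxels regardless of scanner resolution.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        data, spacing = _read_nifti(path)
        return GrayscaleVolume(data=data, spacing=spacing)
    if fmt == "tiff_stack":
        data = _read_tiff_stack(path)
        logger.warning("%s: TIFF carries no voxel size, assuming isotropic 1.0", path)
        return GrayscaleVolume(data=data, spacing=(1.0, 1.0, 1.0))
    raise ValueError(f"unknown volume format {fmt!r}")


def _write_nifti(data: np.ndarray, spacing, path: Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def write_volume(volume: GrayscaleVolume, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        _write_nifti(volume.data, volume.spacing, path)
    elif fmt == "tiff_stack":
        path.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(volume.data):
            tifffile.imwrite(str(path / f"slice_{i:04d}.tif"), np.asarray(sl))
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


def write_mask(mask: SegmentationMask, path) -> None:
    _write_nifti(mask.data.astype(np.uint8), mask.spacing, Path(path))


def read_mask(path) -> SegmentationMask:
    vol = read_volume(path, format="nifti")
    return SegmentationMask(data=vol.data > 0, spacing=vol.spacing)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_thickness_field(field: ThicknessField, path) -> None:
    """Write the encoded thickness field as NIfTI plus an rmax sidecar.

    Refuses to write a field violating its own invariants (any value above
    rmax) so files on disk are always self-consistent.
    """
    field.validate()
    path = Path(path)
    _write_nifti(field.data.astype(np.int32), field.spacing, path)
    _sidecar(path).write_text(json.dumps({"rmax": int(field.rmax)}) + "\n")


def read_thickness_field(path) -> ThicknessField:
    path = Path(path)
    vol = read_volume(path, format="nifti")
    meta = json.loads(_sidecar(path).read_text())
    return ThicknessField(
        data=np.asarray(vol.data).astype(np.int32),
        rmax=int(meta["rmax"]),
        spacing=vol.spacing,
    )


def write_labels(labels: RegionLabelMap, path, spacing=(1.0, 1.0, 1.0)) -> None:
    path = Path(path)
    _write_nifti(labels.data.astype(np.int16), _check_spacing(spacing), path)
    legend = {str(k): v for k, v in labels.legend.items()}
    _sidecar(path).write_text(json.dumps({"legend": legend}) + "\n")


def read_labels(path) -> RegionLabelMap:
    path = Path(path)
    vol = read_volume(path, format="nifti")
    meta = json.loads(_sidecar(path).read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    return RegionLabelMap(data=np.asarray(vol.data).astype(np.int16), legend=legend)


def binarize(volume: GrayscaleVolume, threshold: float) -> SegmentationMask:
    """Threshold a grayscale volume into a segmentation mask (data >= threshold)."""
    threshold = float(threshold)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return SegmentationMask(
        data=volume.data >= threshold, spacing=volume.spacing, origin=volume.origin
    )
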