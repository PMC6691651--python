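"""Scan-geometry arithmetic and NIfTI-1 volume I/O.

The study geometry is a 128x128 in-plane matrix over a 15x15 mm field of
view with 21 slices of 0.5 mm thickness, giving an in-plane resolution of
about 0.117 mm and a voxel volume of about 0.007 mm^3.  Arrays are ordered
(slice, row, col), 0-based; slice 0 is the most anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ScanGeometry",
    "ImageVolume",
    "STUDY_GEOMETRY",
    "inplane_resolution",
    "voxel_volume",
    "load_volume",
    "save_volume",
    "GeometryMismatchError",
]

MODALITIES = ("T1post", "T2")


class GeometryMismatchError(ValueError):
    """Raised when a file's header geometry differs from the expected one."""


@dataclass(frozen=True)
class ScanGeometry:
    matrix_rows: int = 128
    matrix_cols: int = 128
    fov_mm: tuple[float, float] = (15.0, 15.0)
    n_slices: int = 21
    slice_thickness_mm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("matrix_rows", "matrix_cols", "n_slices"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if len(self.fov_mm) != 2 or any(not f > 0 for f in self.fov_mm):
            raise ValueError(f"fov_mm must be two positive reals, got {self.fov_mm!r}")
        if not self.slice_thickness_mm > 0:
            raise ValueError(
                f"slice_thickness_mm must be > 0, got {self.slice_thickness_mm!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_slices, matrix_rows, matrix_cols)."""
        return (self.n_slices, self.matrix_rows, self.matrix_cols)

    def inplane_resolution(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix_rows, self.fov_mm[1] / self.matrix_cols)

    @property
    def voxel_volume_mm3(self) -> float:
        r, c = self.inplane_resolution()
        return r * c * self.slice_thickness_mm


#: Geometry of the study's scans.
STUDY_GEOMETRY = ScanGeometry()


def inplane_resolution(geometry: ScanGeometry) -> tuple[float, float]:
    """In-plane (row, col) voxel size in mm: FOV divided by matrix size."""
    return geometry.inplane_resolution()


def voxel_volume(geometry: ScanGeometry) -> float:
    """Voxel unit volume in mm^3 (pixel area times slice thickness)."""
    return geometry.voxel_volume_mm3


@dataclass
class ImageVolume:
    """A 3-D intensity volume with mm-scale geometry and scan metadata."""

    data: np.ndarray
    geometry: ScanGeometry
    modality: str = "T2"
    subject_id: str = ""
    week: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"grid shape {self.data.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must all be finite")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.week < 0:
            raise ValueError(f"week must be non-negative, got {self.week}")


def _affine(geometry: ScanGeometry) -> np.ndarray:
    res_r, res_c = geometry.inplane_resolution()
    return np.diag([geometry.slice_thickness_mm, res_r, res_c, 1.0])


def save_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz) with mm voxel sizes."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32), _affine(volume.geometry)
    )
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def load_volume(
    path: str | Path,
    expected_geometry: ScanGeometry | None = None,
    *,
    modality: str = "T2",
    subject_id: str = "",
    week: float = 0.0,
) -> ImageVolume:
    """Load a NIfTI-1 volume, reconstructing geometry from header zooms.

    If ``expected_geometry`` is given, shape and voxel sizes must match the
    header to within 1e-3 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    n_slices, rows, cols = data.shape
    geom = ScanGeometry(
        matrix_rows=int(rows),
        matrix_cols=int(cols),
        fov_mm=(float(zooms[1]) * rows, float(zooms[2]) * cols),
        n_slices=int(n_slices),
        slice_thickness_mm=float(zooms[0]),
    )
    if expected_geometry is not None:
        if geom.shape != expected_geometry.shape:
            raise GeometryMismatchError(
                f"{path}: expected grid shape {expected_geometry.shape}, "
                f"found {geom.shape}"
            )
        exp = (
            expected_geometry.slice_thickness_mm,
            *expected_geometry.inplane_resolution(),
        )
        got = (geom.slice_thickness_mm, *geom.inplane_resolution())
        if any(abs(a - b) > 1e-3 for a, b in zip(exp, got)):
            raise GeometryMismatchError(
                f"{path}: expected voxel sizes {exp} mm, found {got} mm"
            )
        geom = expected_geometry
    return ImageVolume(
        data=data, geometry=geom, modality=modality, subject_id=subject_id, week=week
    )
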