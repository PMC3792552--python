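"""Shared containers, error types and NIfTI helpers.

The pipeline operates on plain numpy arrays wherever possible; the only
heavyweight container is :class:`Bold4D`, a 4D BOLD volume carrying its
grid-to-world affine and repetition time.  Masks are boolean 3D arrays,
motion traces are ``(n_frames, 6)`` float arrays (tx ty tz in mm, rx ry rz
in degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "Bold4D",
    "ConfigError",
    "DataError",
    "load_mask",
    "save_mask",
    "load_motion",
    "save_motion",
]


class ConfigError(ValueError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class Bold4D:
    """A 4D BOLD time series on a regular voxel grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities; time is the last axis.
    affine : ndarray, shape (4, 4)
        Grid-to-world affine (NIfTI convention, mm).
    tr_s : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")
        if self.tr_s <= 0:
            raise DataError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_size_mm(self) -> float:
        """Scalar voxel size; geometric mean over axes (grids are isotropic
        in this pipeline, so this equals the common edge length)."""
        return float(np.exp(np.log(self.voxel_sizes_mm).mean()))

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in microliters (1 mm^3 == 1 ul)."""
        return float(np.prod(self.voxel_sizes_mm))

    def discard_initial(self, n: int) -> "Bold4D":
        """Drop the first *n* frames (dummy-scan / T1-equilibration discard)."""
        if not 0 <= n < self.n_frames:
            raise DataError(f"cannot discard {n} of {self.n_frames} frames")
        return Bold4D(self.data[..., n:], self.affine, self.tr_s)

    def copy_with(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(data, self.affine, self.tr_s)

    # ---- I/O -----------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        zooms = tuple(self.voxel_sizes_mm) + (self.tr_s,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, tr_s: float | None = None) -> "Bold4D":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(data, img.affine, tr_s)


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a boolean 3D mask as uint8 NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D mask; returns ``(bool array, affine)``."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0, img.affine


def save_motion(trace: np.ndarray, path) -> None:
    """Write a motion trace as 6-column whitespace text, one row per frame."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise DataError("motion trace must have shape (n_frames, 6)")
    np.savetxt(str(path), trace, fmt="%.6f")


def load_motion(path) -> np.ndarray:
    """Read a 6-column motion trace (tx ty tz mm, rx ry rz degrees)."""
    trace = np.loadtxt(str(path), ndmin=2)
    if trace.shape[1] != 6:
        raise DataError(f"motion trace must have 6 columns, got {trace.shape[1]}")
    if not np.all(np.isfinite(trace)):
        raise DataError("motion trace contains non-finite values")
    return trace
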