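"""CT volume / ROI mask containers, NIfTI round-trip, HU admissibility filter.

Volumes are plain 3D grids of Hounsfield units with the slice axis first
(index 0), so every per-slice operation downstream indexes ``voxels[k]``.
NIfTI stores grids (x, y, z); the reader transposes to (z, y, x) and the
writer transposes back, so files written here are readable by any NIfTI
viewer with the conventional axis order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import AlignmentError, EmptyROIError, FormatError

__all__ = [
    "CTVolume",
    "ROIMask",
    "HUFilter",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "apply_hu_filter",
    "largest_cross_section",
]


@dataclasses.dataclass(frozen=True)
class HUFilter:
    """Inclusive admissibility band on Hounsfield units.

    Voxels strictly below ``lo`` or strictly above ``hi`` are removed from
    analysis; the bounds themselves survive. The defaults drop peri- and
    intra-pancreatic fat (HU < -10) and metallic/stent voxels (HU > 500).
    """

    lo: float = -10.0
    hi: float = 500.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"HUFilter requires lo < hi, got ({self.lo}, {self.hi})")

    def admissible(self, hu: np.ndarray) -> np.ndarray:
        """Boolean grid: True where HU lies inside [lo, hi]."""
        return (hu >= self.lo) & (hu <= self.hi)


@dataclasses.dataclass(frozen=True)
class CTVolume:
    """3D grid of Hounsfield units with voxel spacing.

    voxels : float array, shape (n_slices, ny, nx)
    spacing : (dz, dy, dx) in millimetres, all positive
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or vox.size == 0:
            raise FormatError(f"volume must be a non-empty 3D grid, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise FormatError("volume contains non-finite HU values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing components must be positive, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        """In-plane spacing (dy, dx) in mm."""
        return self.spacing[1], self.spacing[2]


@dataclasses.dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest grid congruent with a :class:`CTVolume`."""

    mask: np.ndarray
    role: str = "tumor"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise FormatError(f"mask must be 3D, got shape {m.shape}")
        if self.role not in ("tumor", "normal"):
            raise ValueError(f"role must be 'tumor' or 'normal', got {self.role!r}")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, volume: CTVolume) -> None:
        if self.mask.shape != volume.voxels.shape:
            raise AlignmentError(
                f"mask shape {self.mask.shape} != volume shape {volume.voxels.shape}"
            )


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D payload, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) in grid order
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    # NIfTI grid order is (x, y, z); slice axis goes first.
    grid = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    return grid, spacing


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI volume; returns HU grid with slice axis first."""
    grid, spacing = _load_nifti(path)
    return CTVolume(voxels=grid.astype(float), spacing=spacing)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing recorded in the header."""
    dz, dy, dx = volume.spacing
    data = np.transpose(volume.voxels, (2, 1, 0))
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def read_mask(path: str | Path, role: str = "tumor") -> ROIMask:
    """Read a NIfTI mask; any nonzero voxel counts as in-ROI."""
    grid, _ = _load_nifti(path)
    return ROIMask(mask=grid != 0, role=role)


def write_mask(mask: ROIMask, volume: CTVolume, path: str | Path) -> None:
    dz, dy, dx = volume.spacing
    data = np.transpose(mask.mask.astype(np.uint8), (2, 1, 0))
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def apply_hu_filter(volume: CTVolume, mask: ROIMask, hu_filter: HUFilter = HUFilter()) -> ROIMask:
    """Restrict a mask to voxels whose HU lies inside the admissible band.

    Idempotent; the input mask is never modified, and the result is always
    a subset of it. An all-filtered (empty) mask is returned as-is —
    downstream operations are responsible for rejecting it.
    """
    mask.check_congruent(volume)
    filtered = mask.mask & hu_filter.admissible(volume.voxels)
    return ROIMask(mask=filtered, role=mask.role)


def largest_cross_section(
    mask: ROIMask, pixel_spacing: tuple[float, float]
) -> tuple[int, float]:
    """Slice index with the most in-mask pixels, and its area in mm².

    Ties go to the lowest slice index. ``pixel_spacing`` is (dy, dx) in mm.
    """
    counts = mask.mask.sum(axis=(1, 2))
    if counts.sum() == 0:
        raise EmptyROIError(f"{mask.role} mask is empty")
    idx = int(np.argmax(counts))  # argmax returns the first maximizer
    dy, dx = pixel_spacing
    area = float(counts[idx]) * float(dy) * float(dx)
    return idx, area
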