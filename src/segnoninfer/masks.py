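"""Binary 3D masks with physical voxel geometry.

The unit of comparison throughout the package is a co-registered 3D binary
mask with a known voxel spacing in millimetres.  Masks are read and written
as NIfTI-1 volumes (``.nii`` / ``.nii.gz``) via nibabel; any voxel value
above 0.5 is treated as foreground.  No resampling or registration is
performed — all masks of a case must already live on the same grid, and a
shape or spacing mismatch is a hard error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, GeometryError, GridCompatibilityError

__all__ = [
    "BinaryMask3D",
    "SegmentationCase",
    "load_mask",
    "save_mask",
    "volume_ml",
    "assert_compatible",
]

#: relative tolerance for declaring two spacings equal
SPACING_RTOL = 1e-4


@dataclass
class BinaryMask3D:
    """A 3D boolean voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        3D array; any value > 0.5 is coerced to foreground (True).
    spacing_mm
        Physical edge length of a voxel along each array axis, in mm.
    affine
        Optional 4x4 affine carried through I/O for provenance.  Only the
        spacing enters any computation; orientation differences are warned
        about, never acted on.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {arr.ndim}D shape {arr.shape}")
        if arr.dtype != bool:
            arr = arr > 0.5
        self.voxels = arr
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3:
            raise GeometryError(f"spacing must have 3 components, got {sp}")
        if any(not np.isfinite(s) or s <= 0 for s in sp):
            raise GeometryError(f"spacing components must be positive and finite, got {sp}")
        self.spacing_mm = sp

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def is_empty(self) -> bool:
        return self.foreground_count == 0

    def volume_ml(self) -> float:
        return volume_ml(self)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(
            self.voxels.copy(),
            self.spacing_mm,
            None if self.affine is None else self.affine.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask3D):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, rtol=SPACING_RTOL)
            and bool(np.array_equal(self.voxels, other.voxels))
        )


@dataclass
class SegmentationCase:
    """All masks annotated for one patient/case on a common grid.

    ``masks`` maps role names (e.g. ``"truth"``, ``"raterA"``, ``"model"``)
    to masks.  At least two masks are required and all must share shape and
    spacing exactly (within :data:`SPACING_RTOL`).
    """

    case_id: str
    masks: dict[str, BinaryMask3D]

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise ValueError(f"case {self.case_id!r} needs >= 2 masks, got {len(self.masks)}")
        roles = list(self.masks)
        first = self.masks[roles[0]]
        for role in roles[1:]:
            try:
                assert_compatible(first, self.masks[role])
            except GridCompatibilityError as exc:
                raise GridCompatibilityError(
                    f"case {self.case_id!r}: mask {role!r} incompatible with {roles[0]!r}: {exc}"
                ) from exc

    def __getitem__(self, role: str) -> BinaryMask3D:
        return self.masks[role]


def load_mask(path: str | Path) -> BinaryMask3D:
    """Read a NIfTI volume as a binary mask.

    Values are binarised at 0.5.  A 4D volume whose trailing dimensions are
    singletons is squeezed to 3D; anything else non-3D is rejected.  Spacing
    is taken from the header voxel-dimension fields and must be positive.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise GeometryError(f"{path}: non-positive voxel spacing {zooms}")
    return BinaryMask3D(data, zooms, affine=np.asarray(img.affine, dtype=float))


def save_mask(mask: BinaryMask3D, path: str | Path) -> None:
    """Write a mask as NIfTI with foreground 1, background 0, spacing in header."""
    path = Path(path)
    affine = mask.affine
    if affine is None:
        affine = np.diag([*mask.spacing_mm, 1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write NIfTI file {path}: {exc}") from exc


def volume_ml(mask: BinaryMask3D) -> float:
    """Foreground volume in millilitres (1 ml = 1000 mm^3)."""
    return mask.foreground_count * mask.voxel_volume_mm3() / 1000.0


def assert_compatible(a: BinaryMask3D, b: BinaryMask3D) -> None:
    """Require two masks to share the same voxel grid.

    Shapes must match exactly; spacings within relative tolerance 1e-4.
    Affine differences beyond spacing only trigger a warning because
    volumes and distances depend on spacing alone.
    """
    if a.shape != b.shape:
        raise GridCompatibilityError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm, rtol=SPACING_RTOL, atol=0.0):
        raise GridCompatibilityError(f"spacing mismatch: {a.spacing_mm} vs {b.spacing_mm}")
    if a.affine is not None and b.affine is not None and not np.allclose(a.affine, b.affine, atol=1e-3):
        warnings.warn(
            "mask affines differ beyond spacing; only spacing is used for metrics",
            stacklevel=2,
        )


def save_case(case: SegmentationCase, case_dir: str | Path) -> None:
    """Write every mask of a case as ``<role>.nii.gz`` under ``case_dir``."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    for role, mask in case.masks.items():
        save_mask(mask, case_dir / f"{role}.nii.gz")


def load_case(case_dir: str | Path, roles: list[str] | None = None) -> SegmentationCase:
    """Read a case directory written by :func:`save_case`.

    If ``roles`` is None, every ``*.nii``/``*.nii.gz`` file in the directory
    becomes a mask named after its stem.
    """
    case_dir = Path(case_dir)
    if roles is None:
        paths = sorted(case_dir.glob("*.nii*"))
    else:
        paths = []
        for role in roles:
            for ext in (".nii.gz", ".nii"):
                p = case_dir / f"{role}{ext}"
                if p.exists():
                    paths.append(p)
                    break
            else:
                raise FileNotFoundError(f"case {case_dir.name}: missing mask for role {role!r}")
    masks = {p.name.removesuffix(".gz").removesuffix(".nii"): load_mask(p) for p in paths}
    return SegmentationCase(case_dir.name, masks)


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
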