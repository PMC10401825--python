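"""Domain types, geometry conventions, and NIfTI I/O.

Internal axis convention (fixed for the whole package, supine subject):

* axis 0 (``x``): right -> left
* axis 1 (``y``): ventral -> dorsal (gravity points along +y)
* axis 2 (``z``): caudal -> cranial

which is the LPS orientation. Files whose header orientation differs are
reoriented on read. All arrays are indexed ``data[x, y, z]`` and spacings
are millimetres per axis. Displacement fields are stored in millimetres
(world units) so Jacobians are spacing-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "LungMask",
    "AerationMap",
    "StrainMap",
    "DisplacementField",
    "read_volume",
    "read_mask",
    "read_field",
    "write_volume",
    "check_geometry",
    "require_same_geometry",
    "GeometryError",
]

#: semantic axis codes of the internal orientation (nibabel letters)
AXIS_CODES = ("L", "P", "S")

SPACING_ATOL_MM = 1e-6


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _validate_grid(data: np.ndarray, spacing) -> tuple[float, float, float]:
    if data.ndim != 3:
        raise ValueError(f"expected 3 spatial dimensions, got {data.ndim}")
    if any(s < 2 for s in data.shape):
        raise ValueError(f"grid must have >= 2 voxels per axis, got {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths (mm), got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """3-D scalar grid of Hounsfield units with voxel spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = _validate_grid(self.data, self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class LungMask:
    """Binary parenchymal mask on the same geometry as its CT volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        self.spacing = _validate_grid(self.data, self.spacing)
        if not self.data.any():
            raise ValueError("lung mask is empty")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class AerationMap:
    """Voxelwise gas fraction F_gas in [0, 1]; defined inside ``mask`` only."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _validate_grid(self.data, self.spacing)
        self.mask = np.asarray(self.mask) > 0
        if self.mask.shape != self.data.shape:
            raise GeometryError("mask shape differs from map shape")
        inside = self.data[self.mask]
        if inside.size and (inside.min() < -1e-9 or inside.max() > 1 + 1e-9):
            raise ValueError("in-mask gas fractions must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class StrainMap:
    """Voxelwise volumetric strain (Jacobian - 1) on the end-expiratory grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _validate_grid(self.data, self.spacing)
        self.mask = np.asarray(self.mask) > 0
        if self.mask.shape != self.data.shape:
            raise GeometryError("mask shape differs from map shape")
        inside = self.data[self.mask]
        if inside.size and inside.min() <= -1.0:
            raise ValueError("in-mask strain must exceed -1 (Jacobian > 0)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class DisplacementField:
    """Dense EE->EI displacement u (mm) on the EE grid; T(x) = x + u(x)."""

    data: np.ndarray  # shape (nx, ny, nz, 3), mm
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"displacement field must be (nx, ny, nz, 3), got {self.data.shape}"
            )
        self.spacing = _validate_grid(self.data[..., 0], self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]


VolumeLike = CTVolume | LungMask | AerationMap | StrainMap | DisplacementField


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # internal LPS axes expressed in nibabel's RAS world: x and y flip sign
    return np.diag([-spacing[0], -spacing[1], spacing[2], 1.0])


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    vector_last = data.ndim == 4 and data.shape[-1] == 3
    if data.ndim != 3 and not vector_last:
        raise ValueError(
            f"expected 3 spatial dimensions, got shape {data.shape} in {path.name}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"zero/negative voxel spacing in header of {path.name}")
    ornt = nib.orientations.io_orientation(img.affine)
    target = nib.orientations.axcodes2ornt(AXIS_CODES)
    xform = nib.orientations.ornt_transform(ornt, target)
    if data.ndim == 4:
        # reorient each component volume, then remap/flip the vector
        # components to the new axis order
        comp0 = nib.orientations.apply_orientation(data[..., 0], xform)
        out = np.empty(comp0.shape + (3,), dtype=np.float64)
        for src_axis, (dst_axis, flip) in enumerate(xform):
            comp = nib.orientations.apply_orientation(data[..., src_axis], xform)
            out[..., int(dst_axis)] = float(flip) * comp
        data = out
    else:
        data = nib.orientations.apply_orientation(data, xform)
    out_spacing = [0.0, 0.0, 0.0]
    for src_axis, (dst_axis, _flip) in enumerate(xform):
        out_spacing[int(dst_axis)] = float(zooms[src_axis])
    return data, tuple(out_spacing)


def read_volume(path) -> CTVolume:
    """Read a 3-D NIfTI scalar volume, reorienting to the package convention."""
    data, spacing = _load_canonical(path)
    if data.ndim != 3:
        raise ValueError("expected 3 spatial dimensions (scalar volume)")
    return CTVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing)


def read_mask(path) -> LungMask:
    data, spacing = _load_canonical(path)
    if data.ndim != 3:
        raise ValueError("expected 3 spatial dimensions (mask volume)")
    return LungMask(data=data, spacing=spacing)


def read_field(path) -> DisplacementField:
    data, spacing = _load_canonical(path)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI with size-3 last axis (vector field)")
    return DisplacementField(data=np.asarray(data, dtype=np.float64), spacing=spacing)


def write_volume(vol: VolumeLike, path) -> None:
    """Write a volume-like object as NIfTI.

    Masks are stored as 8-bit integers, scalar maps as 32-bit floats, and
    displacement fields as 4-D images with the vector component last.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LungMask):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, DisplacementField):
        data = vol.data.astype(np.float32)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing))
    img.header.set_zooms(vol.spacing + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def check_geometry(a: VolumeLike, b: VolumeLike) -> bool:
    """True iff the two objects share grid shape and spacing (1e-6 mm)."""
    if a is None or b is None:
        return False
    sa = a.shape if not isinstance(a, DisplacementField) else a.shape
    if sa != b.shape:
        return False
    return all(
        abs(x - y) <= SPACING_ATOL_MM for x, y in zip(a.spacing, b.spacing)
    )


def require_same_geometry(a: VolumeLike, b: VolumeLike, what: str = "inputs") -> None:
    if not check_geometry(a, b):
        raise GeometryError(
            f"{what} are on different grids: "
            f"{a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )
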