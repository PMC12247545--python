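"""Shared spatial data model: voxel grids, brain masks, volume I/O and
searchlight sphere geometry.

All maps handled by the pipeline live on a common :class:`VolumeGrid` — a 3D
voxel lattice with a boolean brain mask. Searchlight neighbourhoods are
spheres of integer voxel offsets (:class:`SphereSpec`); sphere membership uses
center-to-center Euclidean distance in voxel units with an inclusive radius.
Spheres that poke out of the grid or the mask are *clipped*: out-of-mask
voxels are dropped rather than the whole sphere discarded, so every mask
voxel receives a value.

Volumes are stored and exchanged as single-volume NIfTI images (.nii or
.nii.gz) via nibabel. Voxel indices are 0-based in on-disk array order
(x, y, z).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    GridMismatchError,
    InvalidCenterError,
    InvalidParameterError,
)

CONDITIONS = ("pain", "touch", "control")

__all__ = [
    "CONDITIONS",
    "VolumeGrid",
    "ConditionMap",
    "SphereSpec",
    "sphere_offsets",
    "extract_pattern",
    "sphere_index_table",
    "read_volume",
    "read_mask",
    "write_volume",
    "ellipsoid_mask_grid",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice plus brain mask that all maps share.

    Parameters
    ----------
    shape : tuple of 3 positive ints
        Voxels per axis. The conventional full-resolution standard-space
        grid is (91, 109, 91) at 2 mm.
    voxel_size_mm : tuple of 3 positive floats
        Voxel edge lengths in millimetres.
    mask : boolean ndarray of ``shape``
        True inside the brain. Must contain at least one voxel.
    affine : (4, 4) ndarray, optional
        Voxel-to-world affine used when writing NIfTI; defaults to a
        scaled identity from ``voxel_size_mm``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mask: np.ndarray = None  # type: ignore[assignment]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise InvalidParameterError(f"grid shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise InvalidParameterError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "voxel_size_mm", vs)
        mask = self.mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise GridMismatchError(f"mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise InvalidParameterError("mask must contain at least one true voxel")
        object.__setattr__(self, "mask", mask)
        affine = self.affine
        if affine is None:
            affine = np.diag((*vs, 1.0))
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidParameterError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def check_volume(self, values: np.ndarray) -> np.ndarray:
        """Validate that ``values`` lives on this grid and return it as float64."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise GridMismatchError(
                f"volume shape {values.shape} does not match grid {self.shape}"
            )
        return values

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        """Map a 0-based voxel index triple to world (scanner/template) mm."""
        ijk1 = np.append(np.asarray(ijk, dtype=float), 1.0)
        return (self.affine @ ijk1)[:3]


@dataclass(frozen=True)
class ConditionMap:
    """One subject's statistic volume for one experimental condition.

    ``values`` holds z-statistic units on a :class:`VolumeGrid`; values inside
    the mask must be finite.
    """

    subject_id: str
    condition: str
    values: np.ndarray
    grid: VolumeGrid

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        values = self.grid.check_volume(self.values)
        if not np.isfinite(values[self.grid.mask]).all():
            raise InvalidParameterError(
                f"non-finite values inside mask for {self.subject_id}/{self.condition}"
            )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SphereSpec:
    """Integer voxel offsets forming an approximately spherical neighbourhood.

    ``offsets`` is exactly the set of integer triples within Euclidean
    distance ``radius_voxels`` of the origin (inclusive), in lexicographic
    order. Contains (0,0,0) and is symmetric under negation.
    """

    radius_voxels: float
    offsets: tuple[tuple[int, int, int], ...]

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)

    def offsets_array(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=np.int64)


def sphere_offsets(radius_voxels: float) -> SphereSpec:
    """Enumerate all integer offsets within ``radius_voxels`` of the origin.

    Membership is inclusive (dx²+dy²+dz² ≤ r²); ordering is lexicographic,
    which makes pattern extraction deterministic.

    >>> sphere_offsets(0).n_offsets
    1
    >>> sphere_offsets(3).n_offsets
    123
    """
    r = float(radius_voxels)
    if not np.isfinite(r) or r < 0:
        raise InvalidParameterError(f"radius must be a non-negative real, got {radius_voxels}")
    rmax = int(np.floor(r))
    r2 = r * r
    offs = [
        (dx, dy, dz)
        for dx, dy, dz in itertools.product(range(-rmax, rmax + 1), repeat=3)
        if dx * dx + dy * dy + dz * dz <= r2
    ]
    offs.sort()
    return SphereSpec(radius_voxels=r, offsets=tuple(offs))


def extract_pattern(
    values: np.ndarray,
    center: Sequence[int],
    sphere: SphereSpec,
    grid: VolumeGrid,
) -> np.ndarray:
    """Extract the in-sphere, in-mask feature vector around ``center``.

    Returns the values at ``center + offset`` for every sphere offset that
    falls inside the grid bounds *and* inside the mask, in the sphere's
    offset order. For a fixed center the selected voxels are identical for
    every volume on the same grid, so patterns from different maps are
    element-wise comparable.
    """
    values = values.values if isinstance(values, ConditionMap) else np.asarray(values)
    if values.shape != grid.shape:
        raise GridMismatchError(f"volume shape {values.shape} != grid {grid.shape}")
    c = np.asarray(center, dtype=np.int64)
    if c.shape != (3,):
        raise InvalidParameterError(f"center must be a voxel index triple, got {center}")
    if (c < 0).any() or (c >= np.asarray(grid.shape)).any() or not grid.mask[tuple(c)]:
        raise InvalidCenterError(f"center {tuple(int(x) for x in c)} is outside the mask")
    coords = c[None, :] + sphere.offsets_array()
    inb = ((coords >= 0) & (coords < np.asarray(grid.shape)[None, :])).all(axis=1)
    coords = coords[inb]
    keep = grid.mask[coords[:, 0], coords[:, 1], coords[:, 2]]
    coords = coords[keep]
    return values[coords[:, 0], coords[:, 1], coords[:, 2]]


def sphere_index_table(grid: VolumeGrid, sphere: SphereSpec):
    """Precompute sphere membership for every mask voxel.

    Returns
    -------
    centers : (M, 3) int array
        Mask voxel coordinates in C order.
    indices : (M, K) int array
        Flat voxel indices of each center's in-bounds, in-mask sphere
        members (K = number of sphere offsets); -1 marks a clipped slot.

    This is the vectorised equivalent of calling :func:`extract_pattern` at
    every mask voxel, used by the searchlight engine.
    """
    centers = np.argwhere(grid.mask)
    offs = sphere.offsets_array()
    shape = np.asarray(grid.shape)
    M, K = len(centers), len(offs)
    indices = np.full((M, K), -1, dtype=np.int64)
    mask_flat = grid.mask.ravel()
    # loop over offsets (K small) rather than centers (M large)
    for j, off in enumerate(offs):
        coords = centers + off[None, :]
        ok = ((coords >= 0) & (coords < shape[None, :])).all(axis=1)
        flat = np.ravel_multi_index(coords[ok].T, grid.shape)
        good = mask_flat[flat]
        col = np.full(M, -1, dtype=np.int64)
        sel = np.flatnonzero(ok)
        col[sel[good]] = flat[good]
        indices[:, j] = col
    return centers, indices


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, grid: VolumeGrid | None = None):
    """Read a single-volume NIfTI file.

    Returns ``(values, grid)`` where ``grid`` carries the image's shape,
    voxel sizes and affine (with an all-true mask unless ``grid`` was
    supplied). If ``grid`` is given, the image shape must match it.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GridMismatchError(f"{path}: expected a single 3D volume, got shape {data.shape}")
    data = data.astype(np.float64)
    if grid is not None:
        if data.shape != grid.shape:
            raise GridMismatchError(
                f"{path}: shape {data.shape} does not match bound grid {grid.shape}"
            )
        return data, grid
    zooms = img.header.get_zooms()[:3]
    out_grid = VolumeGrid(
        shape=data.shape,
        voxel_size_mm=tuple(float(z) for z in zooms),
        mask=np.ones(data.shape, dtype=bool),
        affine=np.asarray(img.affine, dtype=float),
    )
    return data, out_grid


def read_mask(path) -> VolumeGrid:
    """Read a binary mask volume into a :class:`VolumeGrid` (nonzero = inside)."""
    data, grid = read_volume(path)
    return VolumeGrid(
        shape=grid.shape,
        voxel_size_mm=grid.voxel_size_mm,
        mask=data != 0,
        affine=grid.affine,
    )


def write_volume(values: np.ndarray, path, grid: VolumeGrid) -> None:
    """Write a volume to NIfTI-1 (.nii/.nii.gz), preserving grid metadata."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise GridMismatchError(f"volume shape {values.shape} != grid {grid.shape}")
    img = nib.Nifti1Image(values, grid.affine)
    img.header.set_zooms(grid.voxel_size_mm)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def ellipsoid_mask_grid(
    shape: Sequence[int] = (24, 24, 24),
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    semiaxes_frac: Sequence[float] = (0.42, 0.42, 0.42),
) -> VolumeGrid:
    """Build a grid with a centred ellipsoid "brain" mask.

    The default 24³ grid with ~0.42·shape semiaxes gives a compact
    brain-like blob used throughout the synthetic cohorts; no atlas is
    required.
    """
    shape = tuple(int(s) for s in shape)
    ax = np.asarray(semiaxes_frac, dtype=float) * np.asarray(shape)
    center = (np.asarray(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = (
        ((ii - center[0]) / ax[0]) ** 2
        + ((jj - center[1]) / ax[1]) ** 2
        + ((kk - center[2]) / ax[2]) ** 2
    )
    return VolumeGrid(shape=shape, voxel_size_mm=tuple(voxel_size_mm), mask=d2 <= 1.0)
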