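"""Core in-memory containers.

All grids are 3D numpy arrays in z,y,x axis order, 0-based. Bounding boxes are
inclusive on both ends: ``(zmin, zmax, ymin, ymax, xmin, xmax)``. Voxel sizes
are nanometres per axis in z,y,x order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume", "BinaryMask", "LabelVolume", "SynapseSite", "Connection", "BBox"]

#: Inclusive voxel bounding box (zmin, zmax, ymin, ymax, xmin, xmax).
BBox = tuple[int, int, int, int, int, int]


def _check_grid(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")


def _check_meta(voxel_size_nm, origin_voxel) -> None:
    if len(voxel_size_nm) != 3 or any(s <= 0 for s in voxel_size_nm):
        raise ValueError(f"voxel_size_nm must be three positive reals, got {voxel_size_nm}")
    if len(origin_voxel) != 3 or any(o < 0 for o in origin_voxel):
        raise ValueError(f"origin_voxel must be three non-negative ints, got {origin_voxel}")


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical voxel size.

    ``data`` is either an unsigned-integer grid (raw intensities, with the
    dtype declaring the bit depth) or a floating grid with all values in
    [0, 1] (a probability map). ``origin_voxel`` locates this (sub)volume in
    a parent grid so crops stay addressable in global coordinates.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data)
        _check_meta(self.voxel_size_nm, self.origin_voxel)
        self.voxel_size_nm = tuple(float(s) for s in self.voxel_size_nm)
        self.origin_voxel = tuple(int(o) for o in self.origin_voxel)
        if np.issubdtype(self.data.dtype, np.floating):
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"floating volumes are probability maps and must lie in [0,1]; got [{lo}, {hi}]"
                )
        elif not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"unsupported dtype {self.data.dtype}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """A 3D boolean foreground mask sharing Volume's metadata conventions."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data)
        _check_meta(self.voxel_size_nm, self.origin_voxel)
        if self.data.dtype != bool:
            self.data = self.data != 0
        self.voxel_size_nm = tuple(float(s) for s in self.voxel_size_nm)
        self.origin_voxel = tuple(int(o) for o in self.origin_voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """A 3D grid of instance identifiers; 0 is background, labels 1..K."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data)
        _check_meta(self.voxel_size_nm, self.origin_voxel)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label grids must be integer, got {self.data.dtype}")
        if self.data.size and int(self.data.min()) < 0:
            raise ValueError("label grids must be non-negative")
        self.voxel_size_nm = tuple(float(s) for s in self.voxel_size_nm)
        self.origin_voxel = tuple(int(o) for o in self.origin_voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def max_label(self) -> int:
        return int(self.data.max()) if self.data.size else 0

    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present."""
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class SynapseSite:
    """One detected punctate instance (a candidate pre/postsynaptic site)."""

    id: int
    voxel_count: int
    centroid: tuple[float, float, float]  # z,y,x in voxels
    bbox: BBox
    role: str = "presynaptic"
    assigned_mask_id: int | None = None
    overlap_fraction: float | None = None  # fraction of this site inside the assigned mask

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be positive")
        z, y, x = self.centroid
        zmin, zmax, ymin, ymax, xmin, xmax = self.bbox
        if not (zmin <= z <= zmax and ymin <= y <= ymax and xmin <= x <= xmax):
            raise ValueError(f"centroid {self.centroid} outside bbox {self.bbox}")

    @property
    def extent(self) -> tuple[int, int, int]:
        zmin, zmax, ymin, ymax, xmin, xmax = self.bbox
        return (zmax - zmin + 1, ymax - ymin + 1, xmax - xmin + 1)


@dataclass
class Connection:
    """One pre-site/post-object contact.

    ``overlap_fraction`` is overlap voxels divided by the *query* object's
    voxel count (the postsynaptic site when matching post sites against
    presynaptic sites, the presynaptic site when matching against a neuron
    membrane mask).
    """

    pre_site_id: int
    post_object_id: int
    post_object_type: str  # "site" or "mask"
    overlap_voxels: int
    overlap_fraction: float
    contact_centroid: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        if self.post_object_type not in ("site", "mask"):
            raise ValueError(f"post_object_type must be 'site' or 'mask', got {self.post_object_type!r}")
        if self.overlap_voxels < 0:
            raise ValueError("overlap_voxels must be non-negative")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError(f"overlap_fraction must lie in [0,1], got {self.overlap_fraction}")
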