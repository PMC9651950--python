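"""Volume and report I/O plus whole-volume utilities.

Two on-disk layouts are supported:

* ``tiff_series`` — a directory of zero-padded grayscale slices
  ``slice_00000.tif``, ``slice_00001.tif``, ... plus a JSON sidecar
  ``attributes.json`` holding voxel size and axis order.
* ``chunked_store`` — an N5/zarr-style chunked directory store with JSON
  attributes (keys ``voxel_size_nm``, ``axis_order``, ``dtype``).

Stores written here record voxel size in z,y,x nanometres under
``voxel_size_nm``; foreign stores carrying an x,y,z-ordered ``voxel_size``
attribute are detected by key name and reversed on read.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import zarr

from .errors import VolumeFormatError
from .types import BBox, BinaryMask, Connection, LabelVolume, SynapseSite, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "crop_roi",
    "max_intensity_projection",
    "subtract_crosstalk",
    "write_site_report",
    "read_site_report",
]

SIDECAR_NAME = "attributes.json"
DEFAULT_CHUNK = 128  # divides the 512-voxel analysis blocks evenly
_SLICE_RE = re.compile(r"slice_(\d+)\.tiff?$")


def _grid_of(v) -> np.ndarray:
    """Serialized representation: masks as uint8 {0,255}, labels as smallest uint."""
    if isinstance(v, BinaryMask):
        return v.data.astype(np.uint8) * np.uint8(255)
    if isinstance(v, LabelVolume):
        m = v.max_label
        dtype = np.uint8 if m < 256 else (np.uint16 if m < 65536 else np.uint32)
        return v.data.astype(dtype)
    return v.data


def _detect_format(path: Path) -> str:
    if path.is_dir():
        if (path / "zarr.json").exists():
            return "chunked_store"
        if any(_SLICE_RE.search(p.name) for p in path.iterdir()):
            return "tiff_series"
    raise VolumeFormatError(f"cannot determine volume format of {path}")


def _voxel_size_from_attrs(attrs: dict) -> tuple[float, float, float] | None:
    if "voxel_size_nm" in attrs:  # our dialect, already z,y,x
        return tuple(float(s) for s in attrs["voxel_size_nm"])
    if "voxel_size" in attrs:  # foreign x,y,z dialect: reverse
        return tuple(float(s) for s in reversed(attrs["voxel_size"]))
    return None


def read_volume(path, format: str | None = None,
                default_voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Read a volume from a TIFF series directory or a chunked store.

    Axis order is normalized to z,y,x; voxel size comes from the sidecar or
    store attributes when present, else ``default_voxel_size_nm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no volume at {path}")
    fmt = format or _detect_format(path)
    if fmt == "tiff_series":
        files = sorted(p for p in path.iterdir() if _SLICE_RE.search(p.name))
        if not files:
            raise VolumeFormatError(f"no slice_*.tif files in {path}")
        slices = []
        shape0 = dtype0 = None
        for f in files:
            s = tifffile.imread(f)
            if s.ndim != 2:
                raise VolumeFormatError(f"slice {f.name} is not a 2D grayscale image")
            if shape0 is None:
                shape0, dtype0 = s.shape, s.dtype
            elif s.shape != shape0 or s.dtype != dtype0:
                raise VolumeFormatError(
                    f"slice {f.name} has shape {s.shape}/{s.dtype}, expected {shape0}/{dtype0}")
            slices.append(s)
        data = np.stack(slices, axis=0)
        attrs = {}
        sidecar = path / SIDECAR_NAME
        if sidecar.exists():
            attrs = json.loads(sidecar.read_text())
    elif fmt == "chunked_store":
        arr = zarr.open_array(str(path), mode="r")
        data = arr[:]
        attrs = dict(arr.attrs)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}; expected tiff_series or chunked_store")
    if not (np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.floating)):
        raise VolumeFormatError(f"unsupported dtype {data.dtype} in {path}")
    vs = _voxel_size_from_attrs(attrs) or tuple(default_voxel_size_nm)
    origin = tuple(int(o) for o in attrs.get("origin_voxel", (0, 0, 0)))
    return Volume(data=data, voxel_size_nm=vs, origin_voxel=origin)


def write_volume(v, path, format: str = "chunked_store", chunk_edge: int = DEFAULT_CHUNK) -> None:
    """Persist a Volume/BinaryMask/LabelVolume with metadata.

    ``read_volume(write_volume(v))`` is the identity on data (masks read back
    as uint8 {0,255}; compare through foreground).
    """
    path = Path(path)
    data = _grid_of(v)
    attrs = {
        "voxel_size_nm": list(v.voxel_size_nm),
        "axis_order": "zyx",
        "dtype": str(data.dtype),
        "origin_voxel": list(v.origin_voxel),
    }
    if format == "tiff_series":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(data.shape[0]):
            tifffile.imwrite(path / f"slice_{i:05d}.tif", data[i])
        (path / SIDECAR_NAME).write_text(json.dumps(attrs, sort_keys=True, indent=1))
    elif format == "chunked_store":
        path.parent.mkdir(parents=True, exist_ok=True)
        chunks = tuple(min(chunk_edge, s) for s in data.shape)
        arr = zarr.create_array(store=str(path), shape=data.shape, dtype=data.dtype,
                                chunks=chunks, attributes=attrs, overwrite=True)
        arr[:] = data
    else:
        raise VolumeFormatError(f"unknown format {format!r}; expected tiff_series or chunked_store")


def crop_roi(v: Volume, bbox: BBox) -> Volume:
    """Crop to an inclusive voxel box, advancing ``origin_voxel`` accordingly."""
    zmin, zmax, ymin, ymax, xmin, xmax = bbox
    nz, ny, nx = v.data.shape
    if not (0 <= zmin <= zmax < nz and 0 <= ymin <= ymax < ny and 0 <= xmin <= xmax < nx):
        clipped = (max(zmin, 0), min(zmax, nz - 1), max(ymin, 0), min(ymax, ny - 1),
                   max(xmin, 0), min(xmax, nx - 1))
        raise ValueError(
            f"box {bbox} exceeds volume shape {v.data.shape}; largest valid extent is {clipped}")
    oz, oy, ox = v.origin_voxel
    return Volume(
        data=v.data[zmin:zmax + 1, ymin:ymax + 1, xmin:xmax + 1].copy(),
        voxel_size_nm=v.voxel_size_nm,
        origin_voxel=(oz + zmin, oy + ymin, ox + xmin),
    )


def max_intensity_projection(v: Volume, axis: str = "z") -> np.ndarray:
    """2D image of per-pixel maxima along one axis ('z', 'y' or 'x')."""
    try:
        ax = "zyx".index(axis)
    except ValueError:
        raise ValueError(f"axis must be one of 'z','y','x', got {axis!r}") from None
    return v.data.max(axis=ax)


def subtract_crosstalk(a: Volume, b: Volume, factor: float) -> Volume:
    """``max(a - factor*b, 0)`` with a saturating cast back to a's dtype."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if factor < 0:
        raise ValueError("factor must be non-negative")
    out = a.data.astype(np.float64) - factor * b.data.astype(np.float64)
    np.clip(out, 0, None, out=out)
    if np.issubdtype(a.data.dtype, np.integer):
        info = np.iinfo(a.data.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return a.with_data(out.astype(a.data.dtype))


SITE_COLUMNS = [
    "id", "stage", "voxel_count",
    "centroid_z", "centroid_y", "centroid_x",
    "bbox_zmin", "bbox_zmax", "bbox_ymin", "bbox_ymax", "bbox_xmin", "bbox_xmax",
    "extent_z", "extent_y", "extent_x", "assigned_mask_id",
]
CONNECTION_COLUMNS = [
    "pre_site_id", "post_object_id", "post_object_type",
    "overlap_voxels", "overlap_fraction",
    "contact_centroid_z", "contact_centroid_y", "contact_centroid_x",
]


def _site_row(s: SynapseSite, stage: str) -> list[str]:
    ez, ey, ex = s.extent
    return [
        str(s.id), stage, str(s.voxel_count),
        f"{s.centroid[0]:.3f}", f"{s.centroid[1]:.3f}", f"{s.centroid[2]:.3f}",
        *(str(b) for b in s.bbox),
        str(ez), str(ey), str(ex),
        "" if s.assigned_mask_id is None else str(s.assigned_mask_id),
    ]


def _connection_row(c: Connection, stage: str) -> list[str]:
    return [
        str(c.pre_site_id), str(c.post_object_id), c.post_object_type,
        str(c.overlap_voxels), f"{c.overlap_fraction:.6f}",
        f"{c.contact_centroid[0]:.3f}", f"{c.contact_centroid[1]:.3f}", f"{c.contact_centroid[2]:.3f}",
    ]


def write_site_report(records: Sequence[SynapseSite | Connection], path, stage_tag: str) -> None:
    """Write a stage CSV of homogeneous SynapseSite or Connection records."""
    records = list(records)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(f"records must be homogeneous per file, got {sorted(k.__name__ for k in kinds)}")
    is_conn = bool(records) and isinstance(records[0], Connection)
    header = CONNECTION_COLUMNS if is_conn else SITE_COLUMNS
    rows = [_connection_row(r, stage_tag) if is_conn else _site_row(r, stage_tag) for r in records]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


def read_site_report(path):
    """Read a stage CSV back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path)
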