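"""Neuron-mask post-processing.

At 8x expansion the fluorescent signal along a neurite is not continuous:
fluorophore expression and antibody labeling leave gaps, and downsampled
semi-automatic segmentation over-masks edges. This module turns a raw or
semi-segmented neuron channel into a final binary mask:

    intensity threshold (Otsu / Li / manual)
    -> bridge labeling gaps (pairs of components closer than ``max_gap``
       voxels are joined by a rasterized 3D line, iterated)
    -> morphological closing (connect voxels separated by one voxel)
    -> connected components
    -> size filter (drop components smaller than 2000 voxels)

The foreground rule everywhere is ``value >= threshold``. Foreground
connectivity defaults to 26 (thin diagonal neurites survive).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line_nd
from skimage.filters import threshold_li

from .config import BridgeSpec, PipelineConfig, ThresholdSpec
from .errors import ConfigError, DegenerateInputError
from .types import BinaryMask, LabelVolume, Volume

__all__ = [
    "compute_threshold",
    "apply_threshold",
    "connected_components",
    "size_filter",
    "close_unit_gaps",
    "bridge_components",
    "postprocess_neuron_mask",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _otsu_ge(values: np.ndarray) -> float:
    """Otsu's threshold under the foreground = (v >= t) convention.

    Scans every occupied gray level as a candidate threshold, maximizing the
    between-class variance; ties resolve to the lowest optimal threshold.
    """
    levels, counts = np.unique(values.ravel(), return_counts=True)
    if len(levels) < 2:
        raise DegenerateInputError(
            "constant volume: Otsu/Li are undefined; use a manual threshold")
    levels = levels.astype(np.float64)
    counts = counts.astype(np.float64)
    total = counts.sum()
    csum = np.cumsum(counts)
    cmean = np.cumsum(counts * levels)
    grand = cmean[-1]
    # candidate t = levels[k] for k >= 1: background {v < t} = levels[:k]
    w0 = csum[:-1]
    w1 = total - w0
    mu0 = cmean[:-1] / w0
    mu1 = (grand - cmean[:-1]) / w1
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(var_between))  # argmax returns the first (lowest) optimum
    # lowest threshold realizing the optimal partition: one gray level above the
    # highest background level (== levels[k+1] when the levels are consecutive)
    if float(levels[k]) == int(levels[k]):
        return float(int(levels[k]) + 1)
    return float(levels[k + 1])


def compute_threshold(v: Volume, spec: ThresholdSpec) -> float:
    """Compute an intensity threshold per the spec; foreground is ``v >= t``."""
    if spec.method == "manual":
        if spec.manual_value is None:
            raise ConfigError("manual threshold requested without manual_value")
        return float(spec.manual_value)
    data = v.data
    if data.min() == data.max():
        raise DegenerateInputError(
            "constant volume: Otsu/Li are undefined; use a manual threshold")
    if spec.method == "otsu":
        return _otsu_ge(data)
    # Li's iterative minimum cross-entropy; returned value separates the modes,
    # used with the same >= rule.
    return float(threshold_li(data))


def apply_threshold(v: Volume, t: float) -> BinaryMask:
    """Binary mask of ``v >= t``; antitone in t (set inclusion)."""
    return BinaryMask(data=v.data >= t, voxel_size_nm=v.voxel_size_nm,
                      origin_voxel=v.origin_voxel)


def _relabel_raster(lab: np.ndarray) -> np.ndarray:
    """Relabel to 1..K ordered by the raster position of each component's first voxel."""
    maxl = int(lab.max()) if lab.size else 0
    if maxl == 0:
        return lab.astype(np.int32)
    flat = lab.ravel()
    nz = np.flatnonzero(flat)
    uniq, first_idx = np.unique(flat[nz], return_index=True)
    order = np.argsort(first_idx, kind="stable")  # labels by first raster occurrence
    lut = np.zeros(maxl + 1, dtype=np.int32)
    lut[uniq[order]] = np.arange(1, len(uniq) + 1, dtype=np.int32)
    return lut[lab]


def connected_components(m: BinaryMask, connectivity: int = 26) -> LabelVolume:
    """Label foreground under 6/18/26 adjacency; labels 1..K in raster order."""
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    lab, _ = ndimage.label(m.data, structure=_STRUCTS[connectivity])
    return LabelVolume(data=_relabel_raster(lab), voxel_size_nm=m.voxel_size_nm,
                       origin_voxel=m.origin_voxel)


def size_filter(l: LabelVolume, min_voxels: int) -> LabelVolume:
    """Keep components with >= min_voxels voxels (strictly smaller removed);
    survivors relabeled 1..K preserving original label order."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be positive")
    maxl = l.max_label
    if maxl == 0:
        return LabelVolume(data=l.data.astype(np.int32), voxel_size_nm=l.voxel_size_nm,
                           origin_voxel=l.origin_voxel)
    counts = np.bincount(l.data.ravel(), minlength=maxl + 1)
    keep = counts >= min_voxels
    keep[0] = False
    lut = np.zeros(maxl + 1, dtype=np.int32)
    lut[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabelVolume(data=lut[l.data], voxel_size_nm=l.voxel_size_nm,
                       origin_voxel=l.origin_voxel)


_BOX3 = np.ones((3, 3, 3), dtype=bool)


def close_unit_gaps(m: BinaryMask) -> BinaryMask:
    """Morphological closing with a 3x3x3 box: voxels separated by one voxel
    become connected. Padding by one voxel keeps the operation extensive at
    the volume border (output is a superset of the input)."""
    padded = np.pad(m.data, 1)
    closed = ndimage.binary_closing(padded, structure=_BOX3)
    out = closed[1:-1, 1:-1, 1:-1] | m.data
    return BinaryMask(data=out, voxel_size_nm=m.voxel_size_nm, origin_voxel=m.origin_voxel)


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=_BOX3, border_value=1)
    return mask & ~eroded


def _min_pair(ci: np.ndarray, cj: np.ndarray,
              tree_j: cKDTree | None = None) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum Euclidean distance between two raster-ordered coordinate sets
    and a deterministic arg-min voxel pair (first ci voxel achieving the
    minimum, then the first cj voxel nearest to it)."""
    tree = tree_j if tree_j is not None else cKDTree(cj)
    d, _ = tree.query(ci)
    i = int(np.flatnonzero(d == d.min())[0])  # first in raster order
    a = ci[i]
    dj = np.sqrt(((cj - a).astype(np.float64) ** 2).sum(axis=1))
    j = int(np.argmin(dj))  # argmin returns the first (raster-lowest) minimum
    return float(dj[j]), a, cj[j]


def bridge_components(m: BinaryMask, spec: BridgeSpec | None = None) -> BinaryMask:
    """Connect disconnected components separated by small labeling gaps.

    Each round: label at 26-connectivity; for every component pair whose
    minimum voxel-centre distance is <= ``max_gap_voxels``, rasterize the 3D
    line segment between the arg-min voxel pair and add it (dilated by
    ``bridge_radius``) to the foreground. Repeats for ``iterations`` rounds or
    until a round adds nothing. Output is a superset of the input and the
    component count never increases.
    """
    spec = spec or BridgeSpec()
    out = m.data.copy()
    for _ in range(spec.iterations):
        lab, k = ndimage.label(out, structure=_STRUCTS[26])
        if k <= 1:
            break
        surf = _surface(out)
        coords = np.argwhere(surf)  # raster order
        labs = lab[tuple(coords.T)]
        per_comp = [coords[labs == i] for i in range(1, k + 1)]
        trees = [cKDTree(c) for c in per_comp]
        bridge = np.zeros_like(out)
        added = False
        for i in range(k):
            for j in range(i + 1, k):
                d, a, b = _min_pair(per_comp[i], per_comp[j], trees[j])
                if d <= spec.max_gap_voxels:
                    line = line_nd(a, b, endpoint=True)
                    bridge[line] = True
                    added = True
        if not added:
            break
        if spec.bridge_radius > 0:
            bridge = ndimage.binary_dilation(bridge, structure=_BOX3,
                                             iterations=spec.bridge_radius)
        out |= bridge
    return BinaryMask(data=out, voxel_size_nm=m.voxel_size_nm, origin_voxel=m.origin_voxel)


def postprocess_neuron_mask(v: Volume, cfg: PipelineConfig | None = None) -> BinaryMask:
    """Full neuron-mask chain: threshold -> bridge -> close -> components ->
    2000-voxel size filter -> binary mask."""
    cfg = cfg or PipelineConfig()
    if v.data.min() == v.data.max() and cfg.neuron_threshold.method != "manual":
        # empty/constant channel: nothing to segment
        return BinaryMask(data=np.zeros(v.data.shape, dtype=bool),
                          voxel_size_nm=v.voxel_size_nm, origin_voxel=v.origin_voxel)
    t = compute_threshold(v, cfg.neuron_threshold)
    mask = apply_threshold(v, t)
    mask = bridge_components(mask, cfg.neuron_bridge)
    mask = close_unit_gaps(mask)
    labels = connected_components(mask, cfg.connectivity)
    labels = size_filter(labels, cfg.neuron_min_size_voxels)
    return BinaryMask(data=labels.data > 0, voxel_size_nm=v.voxel_size_nm,
                      origin_voxel=v.origin_voxel)
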