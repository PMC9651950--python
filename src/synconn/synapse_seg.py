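"""Punctate synaptic-site instance segmentation.

A synaptic-marker channel (BRP-like presynaptic, Drep2-like postsynaptic, or
innexin gap-junction puncta) is converted into individually labeled instances:

    probability map (pluggable voxel classifier)
    -> threshold at 0.8
    -> distance-transform watershed to split touching clusters
    -> role-specific size gate (400 voxels presynaptic, 200 otherwise)
    -> per-instance records (voxel count, centroid, bounding box)

The voxel classifier is a provider interface: ``scaled_intensity`` rescales
raw intensities into [0,1]; ``external_model`` wraps any user-supplied
callable (e.g. a trained network's inference function). No trained weights
ship with the package.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .config import SegmentationProfile
from .errors import ConfigError
from .mask_ops import _relabel_raster, _STRUCTS, apply_threshold, size_filter
from .types import BinaryMask, LabelVolume, SynapseSite, Volume

__all__ = [
    "ProbabilityProvider",
    "register_provider",
    "probability_map",
    "watershed_instances",
    "extract_sites",
    "detect_sites",
]


class ProbabilityProvider:
    """A named voxel classifier producing a probability volume in [0,1]."""

    def __init__(self, name: str, parameters: dict | None = None):
        self.name = name
        self.parameters = dict(parameters or {})

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProbabilityProvider({self.name!r}, {self.parameters!r})"


def _scaled_intensity(v: Volume, params: dict) -> np.ndarray:
    """clip((v - lo)/(hi - lo), 0, 1); lo/hi default to the 1st/99.9th percentiles."""
    data = v.data.astype(np.float64)
    lo = params.get("lo")
    hi = params.get("hi")
    if lo is None:
        lo = float(np.percentile(data, 1.0))
    if hi is None:
        hi = float(np.percentile(data, 99.9))
    if hi <= lo:  # degenerate range (e.g. constant volume): all background
        return np.zeros(v.data.shape, dtype=np.float64)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def _external_model(v: Volume, params: dict) -> np.ndarray:
    fn: Callable[[np.ndarray], np.ndarray] | None = params.get("model")
    if fn is None:
        raise ConfigError("external_model provider requires a 'model' callable parameter")
    out = np.asarray(fn(v.data), dtype=np.float64)
    if out.shape != v.data.shape:
        raise ValueError(f"model output shape {out.shape} != input shape {v.data.shape}")
    return out

_PROVIDERS: dict[str, Callable[[Volume, dict], np.ndarray]] = {
    "scaled_intensity": _scaled_intensity,
    "external_model": _external_model,
}


def register_provider(name: str, fn: Callable[[Volume, dict], np.ndarray]) -> None:
    """Register a custom probability provider under ``name``."""
    _PROVIDERS[name] = fn


def probability_map(v: Volume, provider: ProbabilityProvider) -> Volume:
    """Run the named voxel classifier; output is shape-preserving in [0,1]."""
    try:
        fn = _PROVIDERS[provider.name]
    except KeyError:
        raise ConfigError(
            f"unknown provider {provider.name!r}; registered: {sorted(_PROVIDERS)}") from None
    out = fn(v, provider.parameters)
    if out.min() < 0.0 or out.max() > 1.0:
        raise ValueError(f"provider {provider.name!r} produced values outside [0,1]")
    return Volume(data=out, voxel_size_nm=v.voxel_size_nm, origin_voxel=v.origin_voxel)


def _select_seeds(edt: np.ndarray, comp: np.ndarray, n_comp: int, min_sep: int) -> np.ndarray:
    """Deterministic watershed seeds: distance-transform local maxima with
    greedy suppression so no two seeds within one component lie closer than
    ``min_sep`` (candidates visited by descending distance, ties by raster
    order). Suppression is per component, so far-apart objects never interact
    — a requirement for blockwise/global equivalence."""
    maxf = ndimage.maximum_filter(edt, size=3, mode="constant")
    cand = (comp > 0) & (edt >= maxf)
    coords = np.argwhere(cand)
    if len(coords) == 0:
        return np.zeros(edt.shape, dtype=np.int32)
    vals = edt[tuple(coords.T)]
    comps = comp[tuple(coords.T)]
    order = np.lexsort((np.arange(len(coords)), -vals))  # by -value, then raster
    kept_by_comp: dict[int, list[np.ndarray]] = {}
    kept_coords: list[np.ndarray] = []
    min_sep2 = float(min_sep) ** 2
    for idx in order:
        c = coords[idx]
        lab = int(comps[idx])
        kept = kept_by_comp.setdefault(lab, [])
        if kept:
            arr = np.array(kept)
            if (((arr - c) ** 2).sum(axis=1) < min_sep2).any():
                continue
        kept.append(c)
        kept_coords.append(c)
    markers = np.zeros(edt.shape, dtype=np.int32)
    # marker ids in raster order of the kept seeds (final labels are
    # re-rastered anyway; this keeps intermediate output deterministic)
    kept_arr = np.array(kept_coords)
    raster = np.lexsort((kept_arr[:, 2], kept_arr[:, 1], kept_arr[:, 0]))
    for rank, idx in enumerate(raster, start=1):
        markers[tuple(kept_arr[idx])] = rank
    return markers


def watershed_instances(m: BinaryMask, min_seed_separation: int = 3) -> LabelVolume:
    """Split a punctate foreground into instances by watershed of the negated
    Euclidean distance transform, seeded at suppressed distance maxima.

    The output labels partition the foreground exactly: every foreground voxel
    receives a label, background stays 0.
    """
    if min_seed_separation < 1:
        raise ValueError("min_seed_separation must be positive")
    if not m.data.any():
        return LabelVolume(data=np.zeros(m.data.shape, dtype=np.int32),
                           voxel_size_nm=m.voxel_size_nm, origin_voxel=m.origin_voxel)
    edt = ndimage.distance_transform_edt(m.data)
    comp, n_comp = ndimage.label(m.data, structure=_STRUCTS[26])
    markers = _select_seeds(edt, comp, n_comp, min_seed_separation)
    lab = watershed(-edt, markers=markers, mask=m.data, connectivity=_STRUCTS[26])
    out = _relabel_raster(lab)
    assert ((out > 0) == m.data).all(), "watershed must partition the foreground exactly"
    return LabelVolume(data=out, voxel_size_nm=m.voxel_size_nm, origin_voxel=m.origin_voxel)


def extract_sites(labels: LabelVolume, role: str = "presynaptic") -> list[SynapseSite]:
    """Per-instance records: voxel count, unweighted centroid, inclusive bbox."""
    maxl = labels.max_label
    if maxl == 0:
        return []
    counts = np.bincount(labels.data.ravel(), minlength=maxl + 1)
    objects = ndimage.find_objects(labels.data)
    sites: list[SynapseSite] = []
    sums = np.zeros((maxl + 1, 3), dtype=np.float64)
    coords = np.argwhere(labels.data > 0)
    ids = labels.data[tuple(coords.T)]
    np.add.at(sums, ids, coords)
    for lid in range(1, maxl + 1):
        if counts[lid] == 0 or objects[lid - 1] is None:
            continue
        sz, sy, sx = objects[lid - 1]
        centroid = tuple(sums[lid] / counts[lid])
        sites.append(SynapseSite(
            id=lid,
            voxel_count=int(counts[lid]),
            centroid=centroid,
            bbox=(sz.start, sz.stop - 1, sy.start, sy.stop - 1, sx.start, sx.stop - 1),
            role=role,
        ))
    return sites


def detect_sites(v: Volume, provider: ProbabilityProvider,
                 profile: SegmentationProfile) -> tuple[LabelVolume, list[SynapseSite]]:
    """Full site detection: probability map -> threshold -> watershed -> size gate."""
    prob = probability_map(v, provider)
    mask = apply_threshold(prob, profile.prob_threshold)
    instances = watershed_instances(mask, profile.min_seed_separation_voxels)
    instances = size_filter(instances, profile.min_size_voxels)
    return instances, extract_sites(instances, profile.marker_role)
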