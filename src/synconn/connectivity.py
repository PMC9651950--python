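"""Colocalization-based connectivity analysis.

Two rules drive everything:

* assignment — a synaptic site belongs to a neuron if at least 50% of its
  volume overlaps the neuron mask (inclusive);
* contact — any pre/post overlap of at least 0.1% of the query object's
  volume counts as a connection (inclusive), i.e. essentially any contact.

Four workflows combine them:

1. sites of one marker assigned to a neuron mask;
2. neuron-1 presynaptic sites contacted by neuron-2 postsynaptic sites
   (polyadic contacts allowed: one connection per pre/post pair);
3. neuron-1 presynaptic sites contacting the neuron-2 membrane mask;
4. plain detection of every site in a volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .errors import ConfigError
from .synapse_seg import ProbabilityProvider, detect_sites, extract_sites
from .types import BinaryMask, Connection, LabelVolume, SynapseSite, Volume

__all__ = [
    "assign_sites_to_mask",
    "find_site_site_contacts",
    "find_site_mask_contacts",
    "WorkflowReport",
    "run_workflow",
]

_BOX3 = np.ones((3, 3, 3), dtype=bool)


def _label_counts(lab: np.ndarray) -> np.ndarray:
    maxl = int(lab.max()) if lab.size else 0
    return np.bincount(lab.ravel(), minlength=maxl + 1)


def assign_sites_to_mask(sites: LabelVolume, mask: BinaryMask,
                         fraction: float = 0.5) -> tuple[list[int], dict[int, float]]:
    """Assign each site to the mask if >= ``fraction`` of its voxels overlap it.

    Returns the assigned site ids (sorted) and the overlap fraction of every
    site regardless of outcome.
    """
    if sites.data.shape != mask.data.shape:
        raise ValueError(f"shape mismatch: {sites.data.shape} vs {mask.data.shape}")
    counts = _label_counts(sites.data)
    inside = np.bincount(sites.data[mask.data].ravel(), minlength=len(counts))
    fractions: dict[int, float] = {}
    assigned: list[int] = []
    for lid in range(1, len(counts)):
        if counts[lid] == 0:
            continue
        f = inside[lid] / counts[lid]
        fractions[lid] = float(f)
        if f >= fraction:
            assigned.append(lid)
    return assigned, fractions


def _pair_overlaps(pre: np.ndarray, post: np.ndarray):
    """Overlap voxel counts and centroids for every co-labeled (pre, post) pair."""
    both = (pre > 0) & (post > 0)
    coords = np.argwhere(both)
    if len(coords) == 0:
        return []
    p = pre[tuple(coords.T)].astype(np.int64)
    q = post[tuple(coords.T)].astype(np.int64)
    key = p * (int(post.max()) + 1) + q
    uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
    sums = np.zeros((len(uniq), 3), dtype=np.float64)
    np.add.at(sums, inv, coords)
    out = []
    for k in range(len(uniq)):
        pid = int(uniq[k] // (int(post.max()) + 1))
        qid = int(uniq[k] % (int(post.max()) + 1))
        out.append((pid, qid, int(counts[k]), tuple(sums[k] / counts[k])))
    return out


def find_site_site_contacts(pre: LabelVolume, post: LabelVolume,
                            cfg: PipelineConfig | None = None) -> list[Connection]:
    """Connections between presynaptic sites and postsynaptic query sites.

    The denominator of the colocalization fraction is the (undilated)
    postsynaptic site; one Connection per (pre, post) pair at most.
    """
    cfg = cfg or PipelineConfig()
    if pre.data.shape != post.data.shape:
        raise ValueError(f"shape mismatch: {pre.data.shape} vs {post.data.shape}")
    post_counts = _label_counts(post.data)
    conns: list[Connection] = []
    if cfg.contact_dilation_voxels == 0:
        for pid, qid, ov, cen in _pair_overlaps(pre.data, post.data):
            frac = ov / post_counts[qid]
            if frac >= cfg.contact_fraction:
                conns.append(Connection(pre_site_id=pid, post_object_id=qid,
                                        post_object_type="site", overlap_voxels=ov,
                                        overlap_fraction=float(frac), contact_centroid=cen))
    else:
        for qid in range(1, len(post_counts)):
            if post_counts[qid] == 0:
                continue
            qmask = post.data == qid
            qdil = ndimage.binary_dilation(qmask, structure=_BOX3,
                                           iterations=cfg.contact_dilation_voxels)
            for pid, _, ov, cen in _pair_overlaps(pre.data, qdil.astype(np.int32)):
                frac = ov / post_counts[qid]
                if frac >= cfg.contact_fraction:
                    conns.append(Connection(pre_site_id=pid, post_object_id=qid,
                                            post_object_type="site", overlap_voxels=ov,
                                            overlap_fraction=float(min(frac, 1.0)),
                                            contact_centroid=cen))
    conns.sort(key=lambda c: (c.pre_site_id, c.post_object_id))
    return conns


def find_site_mask_contacts(pre: LabelVolume, neuron2_mask: BinaryMask,
                            cfg: PipelineConfig | None = None) -> list[Connection]:
    """Connections between presynaptic query sites and a neuron membrane mask."""
    cfg = cfg or PipelineConfig()
    if pre.data.shape != neuron2_mask.data.shape:
        raise ValueError(f"shape mismatch: {pre.data.shape} vs {neuron2_mask.data.shape}")
    pre_counts = _label_counts(pre.data)
    target = neuron2_mask.data
    if cfg.contact_dilation_voxels > 0:
        target = ndimage.binary_dilation(target, structure=_BOX3,
                                         iterations=cfg.contact_dilation_voxels)
    conns: list[Connection] = []
    for pid, _, ov, cen in _pair_overlaps(pre.data, target.astype(np.int32)):
        frac = ov / pre_counts[pid]
        if frac >= cfg.contact_fraction:
            conns.append(Connection(pre_site_id=pid, post_object_id=1,
                                    post_object_type="mask", overlap_voxels=ov,
                                    overlap_fraction=float(min(frac, 1.0)),
                                    contact_centroid=cen))
    conns.sort(key=lambda c: c.pre_site_id)
    return conns


@dataclass
class WorkflowReport:
    """Per-stage outputs of one connectivity workflow run."""

    kind: int
    sites: dict[str, list[SynapseSite]] = field(default_factory=dict)
    connections: list[Connection] = field(default_factory=list)
    label_volumes: dict[str, LabelVolume] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


_REQUIRED = {
    1: ("marker", "neuron1_mask"),
    2: ("presyn", "neuron1_mask", "postsyn"),
    3: ("presyn", "neuron1_mask", "neuron2_mask"),
    4: ("marker",),
}


def _mark_assignment(sites: list[SynapseSite], assigned: list[int],
                     fractions: dict[int, float], mask_id: int = 1) -> None:
    aset = set(assigned)
    for s in sites:
        s.overlap_fraction = fractions.get(s.id)
        s.assigned_mask_id = mask_id if s.id in aset else None


def _restrict(labels: LabelVolume, keep_ids: list[int]) -> LabelVolume:
    lut = np.zeros(labels.max_label + 1, dtype=labels.data.dtype)
    lut[np.asarray(keep_ids, dtype=np.int64)] = np.asarray(keep_ids, dtype=labels.data.dtype)
    return LabelVolume(data=lut[labels.data], voxel_size_nm=labels.voxel_size_nm,
                       origin_voxel=labels.origin_voxel)


def run_workflow(kind: int, channels: dict, cfg: PipelineConfig | None = None) -> WorkflowReport:
    """Run one of the four connectivity workflows.

    ``channels`` maps names to inputs: ``marker``/``presyn``/``postsyn`` are
    Volumes (raw marker channels), ``neuron1_mask``/``neuron2_mask`` are
    BinaryMasks. Precomputed label volumes may be supplied as
    ``presyn_labels``/``postsyn_labels``/``marker_labels`` to skip detection.
    """
    cfg = cfg or PipelineConfig()
    if kind not in _REQUIRED:
        raise ConfigError(f"workflow kind must be 1..4, got {kind}")
    missing = [name for name in _REQUIRED[kind]
               if name not in channels and f"{name}_labels" not in channels]
    if missing:
        raise ConfigError(
            f"workflow {kind} requires channels {_REQUIRED[kind]}; missing {missing}")
    provider = ProbabilityProvider(cfg.provider, cfg.provider_params)
    report = WorkflowReport(kind=kind)

    def _detect(name: str, role: str) -> tuple[LabelVolume, list[SynapseSite]]:
        if f"{name}_labels" in channels:
            lbl = channels[f"{name}_labels"]
            from .mask_ops import size_filter
            lbl = size_filter(lbl, cfg.profile_for(role).min_size_voxels)
            return lbl, extract_sites(lbl, role)
        return detect_sites(channels[name], provider, cfg.profile_for(role))

    if kind == 4:
        labels, sites = _detect("marker", "presynaptic")
        report.sites["sites"] = sites
        report.label_volumes["sites"] = labels
        report.summary = {"sites_total": len(sites)}
        return report

    if kind == 1:
        labels, sites = _detect("marker", "presynaptic")
        assigned, fractions = assign_sites_to_mask(labels, channels["neuron1_mask"],
                                                   cfg.assignment_fraction)
        _mark_assignment(sites, assigned, fractions)
        report.sites["sites"] = sites
        report.label_volumes["sites"] = labels
        report.summary = {"sites_total": len(sites), "sites_on_neuron1": len(assigned)}
        return report

    # workflows 2 and 3 start identically: presyn detection + assignment to neuron 1
    pre_labels, pre_sites = _detect("presyn", "presynaptic")
    assigned, fractions = assign_sites_to_mask(pre_labels, channels["neuron1_mask"],
                                               cfg.assignment_fraction)
    _mark_assignment(pre_sites, assigned, fractions)
    assigned_labels = _restrict(pre_labels, assigned)
    report.sites["presyn"] = pre_sites
    report.label_volumes["presyn"] = pre_labels
    report.label_volumes["presyn_assigned"] = assigned_labels

    if kind == 2:
        post_labels, post_sites = _detect("postsyn", "postsynaptic")
        report.sites["postsyn"] = post_sites
        report.label_volumes["postsyn"] = post_labels
        conns = find_site_site_contacts(assigned_labels, post_labels, cfg)
    else:
        conns = find_site_mask_contacts(assigned_labels, channels["neuron2_mask"], cfg)

    report.connections = conns
    connected_pre = sorted({c.pre_site_id for c in conns})
    assert len(connected_pre) <= len(conns), \
        "distinct-presyn count can never exceed the connection count"
    report.summary = {
        "presyn_total": len(pre_sites),
        "presyn_on_neuron1": len(assigned),
        "connections": len(conns),
        "presyn_sites_connected": len(connected_pre),
    }
    return report
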