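"""Synthetic ground-truth phantoms.

Generates volumes with the statistical structure the pipeline assumes:

* tubular neurons — bounded-curvature random-walk tubes, one per neuron,
  each confined to its own slab of the volume so neurons never touch;
* labeling discontinuities — spherical carves along the tube producing
  inter-fragment gaps of a stated length (bridgeable at the default
  20-voxel setting);
* presynaptic sites — ellipsoids of 450-3000 voxels centred on the tube
  surface at local varicosities ("boutons" added to the neuron mask), so
  every site overlaps its neuron by at least the assignment fraction by
  construction;
* apposed postsynaptic sites — smaller ellipsoids sharing a controlled
  1-30 voxel overlap with their presynaptic partner (or merely touching,
  in ``apposition_mode='touching'``);
* nonspecific noise puncta — sub-gate blobs (20-350 voxels) in the
  presynaptic channel;
* optional additive Gaussian background noise.

Ground truth (label volumes, assignment table, connection table) is recorded
during placement, not re-derived. Generation is fully deterministic given
``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import GenerationError, PhantomValidationError
from .types import BinaryMask, LabelVolume, Volume

__all__ = ["PhantomSpec", "PhantomDataset", "generate_phantom", "validate_dataset",
           "save_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic dataset."""

    volume_shape: tuple[int, int, int] = (256, 256, 256)
    n_neurons: int = 3
    tube_radius_voxels: float = 4.0
    tube_step_count: int = 300
    tube_step_length: float = 4.0
    gap_count_per_neuron: int = 2
    gap_length_voxels: float = 12.0          # <= 15 so bridging at 20 closes them
    n_presyn_per_neuron: int = 40
    presyn_size_range: tuple[int, int] = (450, 3000)
    n_postsyn_apposed: int = 15              # apposed to neuron 1's presynaptic sites
    postsyn_size_range: tuple[int, int] = (250, 1000)
    contact_overlap_range: tuple[int, int] = (1, 30)
    n_polyadic_extra: int = 0                # extra post sites on the first apposed pre site
    n_noise_puncta: int = 0
    noise_size_range: tuple[int, int] = (20, 350)  # below the 400-voxel presynaptic gate
    background_sigma: float = 0.0
    neuron_intensity: int = 200
    site_intensity: int = 255
    noise_intensity: int = 255
    min_mask_overlap: float = 0.5            # assignment fraction the sites must satisfy
    apposition_mode: str = "overlap"         # or "touching"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.volume_shape):
            raise ValueError("volume_shape axes must be >= 32")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.tube_radius_voxels <= 0:
            raise ValueError("tube_radius_voxels must be positive")
        for name in ("presyn_size_range", "postsyn_size_range", "noise_size_range",
                     "contact_overlap_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.n_postsyn_apposed > self.n_presyn_per_neuron:
            raise ValueError("cannot appose more postsynaptic sites than neuron 1 has "
                             "presynaptic sites")
        if self.apposition_mode not in ("overlap", "touching"):
            raise ValueError("apposition_mode must be 'overlap' or 'touching'")


@dataclass
class PhantomDataset:
    """A generated phantom with full ground truth."""

    spec: PhantomSpec
    neuron_channels: list[Volume]
    presyn_channel: Volume
    postsyn_channel: Volume
    neuron_masks: list[BinaryMask]            # ground-truth mask per neuron
    presyn_labels: LabelVolume                # ground-truth site instances
    postsyn_labels: LabelVolume
    assignment: pd.DataFrame                  # site_id, neuron_id, overlap_fraction
    connections: pd.DataFrame                 # pre_site_id, post_site_id, overlap_voxels
    gap_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    g = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(g, g, g, indexing="ij")
    keep = dz ** 2 + dy ** 2 + dx ** 2 <= radius ** 2
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _ellipsoid_offsets(axes: np.ndarray) -> np.ndarray:
    r = np.floor(axes).astype(int)
    gz, gy, gx = (np.arange(-ri, ri + 1) for ri in r)
    dz, dy, dx = np.meshgrid(gz, gy, gx, indexing="ij")
    keep = (dz / axes[0]) ** 2 + (dy / axes[1]) ** 2 + (dx / axes[2]) ** 2 <= 1.0
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _stamp(grid: np.ndarray, center: np.ndarray, offsets: np.ndarray, value=True) -> np.ndarray:
    """Set grid[center+offsets] = value, clipping at bounds; returns the voxels set."""
    vox = np.rint(center).astype(np.int64) + offsets
    ok = ((vox >= 0) & (vox < np.array(grid.shape))).all(axis=1)
    vox = vox[ok]
    grid[vox[:, 0], vox[:, 1], vox[:, 2]] = value
    return vox


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _walk_skeleton(rng, lo: np.ndarray, hi: np.ndarray, n_steps: int,
                   step: float) -> np.ndarray:
    """Bounded-curvature random walk inside [lo, hi], densely resampled."""
    pos = lo + rng.uniform(0.25, 0.75, size=3) * (hi - lo)
    direction = _random_unit(rng)
    pts = [pos.copy()]
    for _ in range(n_steps):
        direction = direction + 0.35 * _random_unit(rng)
        direction /= np.linalg.norm(direction)
        nxt = pos + direction * step
        for k in range(3):  # reflect at the walls
            if nxt[k] < lo[k] or nxt[k] > hi[k]:
                direction[k] = -direction[k]
                nxt[k] = pos[k] + direction[k] * step
        pos = np.clip(nxt, lo, hi)
        pts.append(pos.copy())
    pts = np.array(pts)
    # densify so consecutive skeleton points are < 0.75 voxels apart
    dense = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / 0.75)), 1)
        for t in range(1, n + 1):
            dense.append(a + (b - a) * (t / n))
    return np.array(dense)


def _axes_for_size(rng, target_voxels: float) -> np.ndarray:
    """Mildly anisotropic ellipsoid semi-axes with the requested volume.

    Anisotropy is kept within +-10% so the distance-transform ridge stays
    shorter than the watershed seed-separation radius (one site -> one seed).
    """
    rho = (3.0 * target_voxels / (4.0 * np.pi)) ** (1.0 / 3.0)
    f = rng.uniform(0.9, 1.1, size=3)
    f /= np.prod(f) ** (1.0 / 3.0)
    return rho * f


def _sized_offsets(rng, size_range: tuple[int, int]) -> np.ndarray:
    """Ellipsoid offsets whose voxel count lands inside size_range."""
    target = rng.uniform(*size_range)
    axes = _axes_for_size(rng, target)
    for _ in range(60):
        off = _ellipsoid_offsets(axes)
        n = len(off)
        if size_range[0] <= n <= size_range[1]:
            return off
        axes = axes * (1.03 if n < size_range[0] else 0.97)
    raise GenerationError(f"could not realize an ellipsoid within {size_range} voxels")


def _expanded_offsets(off: np.ndarray, margin: float = 2.0) -> np.ndarray:
    """Offsets of the ellipsoid grown by ``margin`` voxels per axis (clearance
    footprint: no foreign object may occupy these voxels, which keeps distinct
    instances disconnected at 26-adjacency)."""
    axes = np.abs(off).max(axis=0).astype(np.float64) + margin
    return _ellipsoid_offsets(axes)


def _lookup(grid: np.ndarray, center: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Values of grid under center+offsets, clipped at bounds."""
    vox = np.rint(center).astype(np.int64) + offsets
    ok = ((vox >= 0) & (vox < np.array(grid.shape))).all(axis=1)
    vox = vox[ok]
    return grid[vox[:, 0], vox[:, 1], vox[:, 2]]


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomDataset:
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.volume_shape)
    r = spec.tube_radius_voxels
    max_site_axis = (3.0 * spec.presyn_size_range[1] / (4.0 * np.pi)) ** (1.0 / 3.0) * 1.1
    inset = int(np.ceil(r + max_site_axis + 3))

    # --- neurons: one slab per neuron along y ---------------------------------
    slab = shape[1] / spec.n_neurons
    if slab - 2 * inset < 8:
        raise GenerationError(
            f"volume too small for {spec.n_neurons} neuron slabs (shape {shape})")
    ball = _ball_offsets(r)
    neuron_masks_data = []
    skeletons = []
    carve_centers_all: list[np.ndarray] = []
    gap_rows = []
    for i in range(spec.n_neurons):
        lo = np.array([inset, i * slab + inset, inset])
        hi = np.array([shape[0] - 1 - inset, (i + 1) * slab - 1 - inset, shape[2] - 1 - inset])
        skel = _walk_skeleton(rng, lo, hi, spec.tube_step_count, spec.tube_step_length)
        tube = np.zeros(shape, dtype=bool)
        for p in skel:
            _stamp(tube, p, ball)
        # carve labeling gaps: sphere of radius sqrt((g/2)^2 + r^2) leaves an
        # inter-fragment gap of ~g for a locally straight tube
        carve_r = np.sqrt((spec.gap_length_voxels / 2.0) ** 2 + r ** 2)
        n_dense = len(skel)
        carves = []
        if spec.gap_count_per_neuron > 0:
            fracs = np.linspace(0.3, 0.7, spec.gap_count_per_neuron + 2)[1:-1]
            fracs = fracs + rng.uniform(-0.03, 0.03, size=len(fracs))
            carves = [skel[int(f * n_dense)] for f in fracs]
        for c in carves:
            coords = np.argwhere(tube)
            near = ((coords - c) ** 2).sum(axis=1) <= carve_r ** 2
            cut = coords[near]
            tube[cut[:, 0], cut[:, 1], cut[:, 2]] = False
            gap_rows.append({"neuron_id": i + 1, "nominal_gap_voxels": spec.gap_length_voxels,
                             "carve_z": c[0], "carve_y": c[1], "carve_x": c[2]})
        carve_centers_all.extend(carves)
        neuron_masks_data.append(tube)
        skeletons.append(skel)

    # --- presynaptic sites on tube-surface boutons ----------------------------
    presyn = np.zeros(shape, dtype=np.int32)
    postsyn = np.zeros(shape, dtype=np.int32)
    site_meta = []  # (site_id, neuron_id, center, out_dir, max_axis)
    assignment_rows = []
    site_id = 0
    carve_arr = np.array(carve_centers_all) if carve_centers_all else np.zeros((0, 3))
    carve_excl = (np.sqrt((spec.gap_length_voxels / 2.0) ** 2 + r ** 2)
                  + max_site_axis + 3.0)
    for i in range(spec.n_neurons):
        skel = skeletons[i]
        mask = neuron_masks_data[i]
        if len(carve_arr):
            dists = np.sqrt(((skel[:, None, :] - carve_arr[None, :, :]) ** 2).sum(axis=2))
            anchor_ok = (dists > carve_excl).all(axis=1)
        else:
            anchor_ok = np.ones(len(skel), dtype=bool)
        anchor_idx = np.flatnonzero(anchor_ok)
        if len(anchor_idx) < spec.n_presyn_per_neuron:
            raise GenerationError(f"neuron {i + 1} skeleton admits too few site anchors")
        # stratify anchors along the skeleton so sites pack evenly, then jitter
        strata = np.array_split(anchor_idx, spec.n_presyn_per_neuron)
        placed = 0
        while placed < spec.n_presyn_per_neuron:
            stratum = strata[placed]
            proposal = None
            for attempt in range(600):
                pool = stratum if attempt < 80 else anchor_idx
                anchor = skel[pool[rng.integers(len(pool))]]
                d = _random_unit(rng)
                center = anchor + d * r
                off = _sized_offsets(rng, spec.presyn_size_range)
                max_axis = float(np.abs(off).max())
                ci = np.rint(center).astype(np.int64)
                if ((ci - max_axis - 1 < 0).any()
                        or (ci + max_axis + 1 >= np.array(shape)).any()):
                    continue
                # clearance: the grown footprint must be free of other sites so
                # instances never touch at 26-adjacency
                if (_lookup(presyn, center, _expanded_offsets(off)) != 0).any():
                    continue
                proposal = (center, d, off, max_axis)
                break
            if proposal is None:
                raise GenerationError(
                    f"could not place {spec.n_presyn_per_neuron} presynaptic sites on "
                    f"neuron {i + 1}; use a larger volume or fewer/smaller objects")
            center, d, off, max_axis = proposal
            # bouton: varicosity sphere blended into the neuron at the site centre
            site_id += 1
            bouton = _ball_offsets(max(max_axis * 0.85, r))
            _stamp(mask, center, bouton)
            vox = _stamp(presyn, center, off, site_id)
            frac = float(mask[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
            grow = 0
            while frac < spec.min_mask_overlap + 0.05 and grow < 4:
                grow += 1
                bouton = _ball_offsets(max_axis * (0.85 + 0.1 * grow))
                _stamp(mask, center, bouton)
                frac = float(mask[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
            site_meta.append({"site_id": site_id, "neuron_id": i + 1,
                              "center": center, "out_dir": d, "max_axis": max_axis,
                              "voxels": vox})
            assignment_rows.append({"site_id": site_id, "neuron_id": i + 1,
                                    "overlap_fraction": frac})
            placed += 1

    # --- apposed postsynaptic sites -------------------------------------------
    neuron1_sites = [m for m in site_meta if m["neuron_id"] == 1]
    chosen = sorted(rng.choice(len(neuron1_sites), size=spec.n_postsyn_apposed,
                               replace=False).tolist())
    partners = [neuron1_sites[k] for k in chosen]
    spares = [neuron1_sites[k] for k in range(len(neuron1_sites)) if k not in set(chosen)]

    post_id = 0
    connection_rows = []
    apposed_pre: list[dict] = []

    def _place_post(pre) -> bool:
        nonlocal post_id
        for attempt in range(200):
            if attempt == 0:
                d = pre["out_dir"]
            else:  # jitter around the outward normal, staying on the far side
                d = pre["out_dir"] + rng.uniform(0.3, 1.2) * _random_unit(rng)
                d /= np.linalg.norm(d)
            if np.dot(d, pre["out_dir"]) < 0.1:
                continue
            off = _sized_offsets(rng, spec.postsyn_size_range)
            post_axis = float(np.abs(off).max())
            k_needed = max(1, int(np.ceil(0.001 * len(off))))
            k_target = int(rng.integers(max(spec.contact_overlap_range[0], k_needed),
                                        spec.contact_overlap_range[1] + 1))
            found = None
            pre_id = pre["site_id"]
            s = pre["max_axis"] + post_axis + 1.0
            while s > 0.5:
                center = pre["center"] + d * s
                ci = np.rint(center).astype(np.int64)
                if ((ci - post_axis - 1 < 0).any()
                        or (ci + post_axis + 1 >= np.array(shape)).any()):
                    break
                vox = np.rint(center).astype(np.int64) + off
                under_pre = presyn[vox[:, 0], vox[:, 1], vox[:, 2]]
                if ((under_pre != 0) & (under_pre != pre_id)).any():
                    break  # drifted onto a foreign site
                ov = int((under_pre == pre_id).sum())
                if spec.apposition_mode == "touching":
                    if ov >= 1:
                        s_touch = s + 1.5  # back off to merely-apposed
                        center = pre["center"] + d * s_touch
                        vox = np.rint(center).astype(np.int64) + off
                        ok = ((vox >= 0) & (vox < np.array(shape))).all(axis=1).all()
                        if ok and (presyn[vox[:, 0], vox[:, 1], vox[:, 2]] == 0).all():
                            found = (center, vox, 0)
                        break
                elif ov >= k_target:
                    if ov <= spec.contact_overlap_range[1]:
                        found = (center, vox, ov)
                    break
                s -= 0.1
            if found is None:
                continue
            center, vox, ov = found
            # clearance: the grown footprint may touch only the partner pre site
            exp = _expanded_offsets(off)
            under_pre_exp = _lookup(presyn, center, exp)
            under_post_exp = _lookup(postsyn, center, exp)
            clear = (not ((under_pre_exp != 0) & (under_pre_exp != pre_id)).any()
                     and not (under_post_exp != 0).any())
            if clear:
                post_id += 1
                postsyn[vox[:, 0], vox[:, 1], vox[:, 2]] = post_id
                connection_rows.append({"pre_site_id": pre_id, "post_site_id": post_id,
                                        "overlap_voxels": ov})
                return True
        return False

    for pre in partners:
        if _place_post(pre):
            apposed_pre.append(pre)
            continue
        # crowded partner: fall back to an unused neuron-1 site
        ok = False
        while spares:
            alt = spares.pop(0)
            if _place_post(alt):
                apposed_pre.append(alt)
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not appose a postsynaptic site to presynaptic site "
                f"{pre['site_id']} (or any spare); use a larger volume or fewer objects")
    for _ in range(spec.n_polyadic_extra):
        if not _place_post(apposed_pre[0]):
            raise GenerationError(
                "could not place a polyadic extra postsynaptic site; use a larger "
                "volume or fewer objects")

    # --- nonspecific noise puncta (presynaptic channel) -----------------------
    noise_mask = np.zeros(shape, dtype=bool)
    for n in range(spec.n_noise_puncta):
        placed = False
        for _ in range(400):
            off = _sized_offsets(rng, spec.noise_size_range)
            radius = float(np.abs(off).max())
            center = rng.uniform(radius + 2, np.array(shape) - radius - 2)
            exp = _expanded_offsets(off)
            if ((_lookup(presyn, center, exp) != 0).any()
                    or (_lookup(postsyn, center, exp) != 0).any()
                    or _lookup(noise_mask, center, exp).any()):
                continue
            _stamp(noise_mask, center, off)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place noise punctum {n + 1}; use a larger volume or fewer objects")

    # --- assemble channels -----------------------------------------------------
    def _channel(base: np.ndarray, intensity: int) -> Volume:
        data = base.astype(np.float64) * intensity
        if spec.background_sigma > 0:
            data = data + rng.normal(0.0, spec.background_sigma, size=shape)
        return Volume(data=np.clip(np.rint(data), 0, 255).astype(np.uint8))

    neuron_channels = [_channel(m, spec.neuron_intensity) for m in neuron_masks_data]
    presyn_fg = (presyn > 0).astype(np.float64) * spec.site_intensity \
        + (noise_mask & (presyn == 0)).astype(np.float64) * spec.noise_intensity
    if spec.background_sigma > 0:
        presyn_fg = presyn_fg + rng.normal(0.0, spec.background_sigma, size=shape)
    presyn_channel = Volume(data=np.clip(np.rint(presyn_fg), 0, 255).astype(np.uint8))
    postsyn_channel = _channel(postsyn > 0, spec.site_intensity)

    return PhantomDataset(
        spec=spec,
        neuron_channels=neuron_channels,
        presyn_channel=presyn_channel,
        postsyn_channel=postsyn_channel,
        neuron_masks=[BinaryMask(data=m) for m in neuron_masks_data],
        presyn_labels=LabelVolume(data=presyn),
        postsyn_labels=LabelVolume(data=postsyn),
        assignment=pd.DataFrame(assignment_rows,
                                columns=["site_id", "neuron_id", "overlap_fraction"]),
        connections=pd.DataFrame(connection_rows,
                                 columns=["pre_site_id", "post_site_id", "overlap_voxels"]),
        gap_table=pd.DataFrame(gap_rows, columns=["neuron_id", "nominal_gap_voxels",
                                                  "carve_z", "carve_y", "carve_x"]),
    )


def validate_dataset(d: PhantomDataset, cfg: PipelineConfig | None = None) -> dict:
    """Re-check every ground-truth invariant against the emitted volumes;
    raises PhantomValidationError naming the offending objects."""
    cfg = cfg or PipelineConfig()
    spec = d.spec
    problems: list[str] = []

    pre = d.presyn_labels.data
    post = d.postsyn_labels.data
    pre_counts = np.bincount(pre.ravel())
    post_counts = np.bincount(post.ravel())

    # site sizes within the spec ranges
    for lid in range(1, len(pre_counts)):
        if not (spec.presyn_size_range[0] <= pre_counts[lid] <= spec.presyn_size_range[1]):
            problems.append(f"presyn site {lid} has {pre_counts[lid]} voxels, outside "
                            f"{spec.presyn_size_range}")
    for lid in range(1, len(post_counts)):
        if not (spec.postsyn_size_range[0] <= post_counts[lid] <= spec.postsyn_size_range[1]):
            problems.append(f"postsyn site {lid} has {post_counts[lid]} voxels, outside "
                            f"{spec.postsyn_size_range}")

    # assignment invariant: each presyn site overlaps its neuron enough
    for row in d.assignment.itertuples():
        mask = d.neuron_masks[int(row.neuron_id) - 1].data
        vox = pre == int(row.site_id)
        n = int(vox.sum())
        if n == 0:
            problems.append(f"assignment row for presyn site {row.site_id} has no voxels")
            continue
        frac = int((vox & mask).sum()) / n
        if frac < cfg.assignment_fraction:
            problems.append(f"presyn site {row.site_id} overlaps neuron {row.neuron_id} "
                            f"by {frac:.3f} < {cfg.assignment_fraction}")

    # connection invariant: each recorded pair genuinely overlaps
    for row in d.connections.itertuples():
        ov = int(((pre == int(row.pre_site_id)) & (post == int(row.post_site_id))).sum())
        if ov != int(row.overlap_voxels):
            problems.append(f"connection {row.pre_site_id}->{row.post_site_id}: recorded "
                            f"{row.overlap_voxels} overlap voxels, measured {ov}")
        if spec.apposition_mode == "overlap" and ov < 1:
            problems.append(f"connection {row.pre_site_id}->{row.post_site_id} has no overlap")

    # table/label consistency
    if set(d.assignment["site_id"]) != set(np.unique(pre[pre > 0]).tolist()):
        problems.append("assignment table site ids do not match the presyn label volume")
    if set(d.connections["post_site_id"]) != set(np.unique(post[post > 0]).tolist()):
        problems.append("connection table post ids do not match the postsyn label volume")

    if problems:
        raise PhantomValidationError("; ".join(problems))
    return {
        "n_presyn_sites": int((pre_counts[1:] > 0).sum()) if len(pre_counts) > 1 else 0,
        "n_postsyn_sites": int((post_counts[1:] > 0).sum()) if len(post_counts) > 1 else 0,
        "n_connections": int(len(d.connections)),
        "n_assignments": int(len(d.assignment)),
    }


def save_dataset(d: PhantomDataset, outdir, format: str = "chunked_store") -> None:
    """Write channels, ground-truth volumes, tables and the spec echo to a directory."""
    import json
    from pathlib import Path

    from .io import write_volume

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (ch, m) in enumerate(zip(d.neuron_channels, d.neuron_masks), start=1):
        write_volume(ch, out / f"neuron{i}_channel", format)
        write_volume(m, out / f"neuron{i}_gt_mask", format)
    write_volume(d.presyn_channel, out / "presyn_channel", format)
    write_volume(d.postsyn_channel, out / "postsyn_channel", format)
    write_volume(d.presyn_labels, out / "presyn_gt_labels", format)
    write_volume(d.postsyn_labels, out / "postsyn_gt_labels", format)
    d.assignment.to_csv(out / "gt_assignment.csv", index=False)
    d.connections.to_csv(out / "gt_connections.csv", index=False)
    d.gap_table.to_csv(out / "gt_gaps.csv", index=False)
    (out / "phantom_spec.json").write_text(json.dumps(asdict(d.spec), sort_keys=True, indent=1))
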