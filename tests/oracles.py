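"""Independent brute-force oracles used to check the implementation.

These deliberately use naive algorithms (python BFS, explicit loops,
exhaustive scans) and share no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3):
        if (dz, dy, dx) == (0, 0, 0):
            continue
        order = abs(dz) + abs(dy) + abs(dx)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append((dz, dy, dx))
    return offs


def bfs_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Flood-fill labeling via an explicit BFS over voxel coordinates."""
    offs = neighbor_offsets(connectivity)
    shape = mask.shape
    fg = {tuple(c) for c in np.argwhere(mask)}
    out = np.zeros(shape, dtype=np.int32)
    label = 0
    # deterministic raster order over foreground voxels
    for seed in sorted(fg):
        if out[seed]:
            continue
        label += 1
        stack = [seed]
        out[seed] = label
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if n in fg and out[n] == 0:
                    out[n] = label
                    stack.append(n)
    return out


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition of the foreground."""
    if not ((a > 0) == (b > 0)).all():
        return False
    pairs = set(zip(a[a > 0].ravel().tolist(), b[b > 0].ravel().tolist()))
    return (len({p for p, _ in pairs}) == len(pairs)
            and len({q for _, q in pairs}) == len(pairs))


def brute_mip(data: np.ndarray, axis: int) -> np.ndarray:
    """Per-pixel maximum by explicit iteration along the collapsed axis."""
    moved = np.moveaxis(data, axis, 0)
    out = moved[0].copy()
    for k in range(1, moved.shape[0]):
        sl = moved[k]
        out = np.where(sl > out, sl, out)
    return out


def otsu_exhaustive(values: np.ndarray) -> float:
    """Exhaustive scan of all 256 candidate thresholds (foreground = v >= t),
    maximizing between-class variance; lowest optimum wins."""
    v = values.ravel().astype(np.float64)
    best_t, best_var = None, -1.0
    for t in range(256):
        bg = v[v < t]
        fg = v[v >= t]
        if len(bg) == 0 or len(fg) == 0:
            continue
        w0, w1 = len(bg) / len(v), len(fg) / len(v)
        var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_t = t
    return float(best_t)


def li_fixed_point(values: np.ndarray, tol: float = 1e-6) -> float:
    """Li's minimum cross-entropy threshold by fixed-point iteration."""
    v = values.ravel().astype(np.float64)
    t = v.mean()
    for _ in range(1000):
        fg = v[v > t]
        bg = v[v <= t]
        if len(fg) == 0 or len(bg) == 0:
            break
        mf, mb = fg.mean(), bg.mean()
        if mb <= 0:
            mb = 1e-9
        if mf <= 0:
            mf = 1e-9
        t_new = (mf - mb) / (np.log(mf) - np.log(mb))
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def overlap_fraction_loop(site_labels: np.ndarray, mask: np.ndarray) -> dict[int, float]:
    """Per-site in-mask fraction by an explicit voxel-membership loop."""
    totals: dict[int, int] = {}
    inside: dict[int, int] = {}
    for idx in np.ndindex(site_labels.shape):
        lab = int(site_labels[idx])
        if lab == 0:
            continue
        totals[lab] = totals.get(lab, 0) + 1
        if mask[idx]:
            inside[lab] = inside.get(lab, 0) + 1
    return {lab: inside.get(lab, 0) / n for lab, n in totals.items()}


def pair_overlaps_loop(pre: np.ndarray, post: np.ndarray) -> dict[tuple[int, int], int]:
    """Exhaustive (pre, post) co-label voxel counts."""
    out: dict[tuple[int, int], int] = {}
    for idx in np.ndindex(pre.shape):
        p, q = int(pre[idx]), int(post[idx])
        if p > 0 and q > 0:
            out[(p, q)] = out.get((p, q), 0) + 1
    return out
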