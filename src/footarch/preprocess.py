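"""Depth denoising, distance gating and largest-component foot extraction.

The raw depth raster is cleaned with an edge-preserving 3x3 median, pixels
farther than a distance threshold (600 mm by default: the footplate sits
~300 mm above the camera) are discarded, and the surviving pixels are reduced
to their largest 4-connected component, which is taken to be the foot.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_camera import FootPointCloud, RGBDFrame, register_color

__all__ = [
    "median_filter3",
    "depth_cut",
    "two_pass_label",
    "largest_component",
    "preprocess_frame",
    "NoFootError",
]

DEPTH_CUT_MM = 600.0


class NoFootError(RuntimeError):
    """No foot pixels survive preprocessing."""


def median_filter3(depth: np.ndarray) -> np.ndarray:
    """3x3 median filter; border pixels use the median of in-bounds values."""
    depth = np.asarray(depth, dtype=float)
    if depth.ndim != 2 or depth.shape[0] < 3 or depth.shape[1] < 3:
        raise ValueError("median_filter3 requires a grid of at least 3x3")
    h, w = depth.shape
    # Stack the 9 shifted copies padded with NaN so the border median is taken
    # over in-bounds neighbours only.
    stack = np.full((9, h, w), np.nan)
    k = 0
    for dv in (-1, 0, 1):
        for du in (-1, 0, 1):
            src = depth[
                max(0, -dv): h - max(0, dv),
                max(0, -du): w - max(0, du),
            ]
            stack[k,
                  max(0, dv): h - max(0, -dv),
                  max(0, du): w - max(0, -du)] = src
            k += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(stack, axis=0)


def depth_cut(depth: np.ndarray, t_max: float = DEPTH_CUT_MM) -> np.ndarray:
    """Invalidate (set to 0) pixels farther than ``t_max`` mm or already 0."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    depth = np.asarray(depth, dtype=float)
    out = depth.copy()
    out[(depth > t_max) | (depth == 0)] = 0.0
    return out


def two_pass_label(mask: np.ndarray) -> np.ndarray:
    """Two-pass connected component labeling, 4-connectivity.

    First pass scans left-to-right, top-to-bottom, assigning each foreground
    pixel the label of its left or top neighbour (recording equivalences when
    both are set and differ); the second pass relabels every pixel with the
    smallest label of its equivalence class. Returns an int label image with
    0 for background; component labels are consecutive from 1 in scan order
    of their representative.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int64)
    parent: list[int] = [0]  # union-find over provisional labels

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:  # path compression
            parent[a], a = root, parent[a]
        return root

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lowest label as the representative
            if ra < rb:
                parent[rb] = ra
            else:
                parent[ra] = rb

    nxt = 1
    for v in range(h):
        row = mask[v]
        for u in range(w):
            if not row[u]:
                continue
            left = labels[v, u - 1] if u > 0 else 0
            top = labels[v - 1, u] if v > 0 else 0
            if left and not top:
                labels[v, u] = left
            elif top and not left:
                labels[v, u] = top
            elif left and top:
                labels[v, u] = left
                if left != top:
                    union(left, top)
            else:
                labels[v, u] = nxt
                parent.append(nxt)
                nxt += 1
    if nxt == 1:
        return labels
    # second pass: lowest label of each equivalence set, then compact to 1..k
    roots = np.array([find(i) for i in range(nxt)], dtype=np.int64)
    remap = np.zeros(nxt, dtype=np.int64)
    next_id = 1
    for i in range(1, nxt):
        r = roots[i]
        if remap[r] == 0:
            remap[r] = next_id
            next_id += 1
    flat = remap[roots[labels]]
    return flat


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected component of a binary mask.

    Ties are broken toward the component first encountered in scan order
    (smallest compacted label). An empty mask yields an empty mask with a
    warning rather than an error.
    """
    labels = two_pass_label(mask)
    n = labels.max()
    if n == 0:
        warnings.warn("largest_component: empty input mask", stacklevel=2)
        return np.zeros_like(labels, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax takes the first (lowest) label
    return labels == best


def preprocess_frame(frame: RGBDFrame,
                     t_max: float = DEPTH_CUT_MM) -> FootPointCloud:
    """median filter -> depth cut -> largest component -> 6D foot cloud."""
    depth = median_filter3(frame.depth)
    depth = depth_cut(depth, t_max)
    mask = depth > 0
    if not mask.any():
        raise NoFootError("no foot detected: all pixels removed by depth cut")
    foot = largest_component(mask)
    if not foot.any():  # pragma: no cover - guarded by mask.any()
        raise NoFootError("no foot detected")
    clean = RGBDFrame(
        depth=np.where(foot, depth, 0.0),
        color=frame.color,
        intrinsics_depth=frame.intrinsics_depth,
        intrinsics_color=frame.intrinsics_color,
        extrinsics=frame.extrinsics,
    )
    cloud = register_color(clean)
    cloud.valid &= foot
    cloud.points[~cloud.valid] = 0.0
    cloud.colors[~cloud.valid] = 0.0
    return cloud
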