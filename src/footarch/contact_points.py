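"""Footplate plane estimation and sparse contact-point detection.

The footplate is not assumed parallel to the camera: it is recovered from the
foot cloud itself under the assumption that the contact region is the largest
population of points sharing a common surface normal. Per-pixel normals are
estimated from neighbour differences, voted into a 20x20x20 grid over
[-1, 1]^3 (cell size 0.1), adjacent clusters with close mean normals are
merged, and a least-squares (SVD) plane is fitted to the points of the largest
cluster. Contact points are the foot points whose absolute plane distance
falls at or below the modal bin of a 1 mm distance histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io_camera import FootPointCloud

__all__ = [
    "NormalField",
    "NormalClusterGrid",
    "Plane",
    "ContactPointSet",
    "estimate_normals",
    "cluster_normals",
    "fit_plane",
    "signed_distance",
    "detect_contact_points",
    "DegenerateGeometryError",
]

CELL_SIZE = 0.1  # side of a voxel cell in the normal grid
GRID_CELLS = 20  # per axis, spanning [-1, 1]
HIST_BIN_MM = 1.0
HIST_RANGE_MM = 20.0


class DegenerateGeometryError(RuntimeError):
    """Geometry too degenerate to fit a plane."""


@dataclass
class NormalField:
    """Per-pixel unit surface normals aligned with the foot-cloud grid."""

    normals: np.ndarray  # (H, W, 3), unit where valid
    valid: np.ndarray  # (H, W) bool


@dataclass
class NormalCluster:
    cells: set[tuple[int, int, int]]
    mean: np.ndarray  # mean normal (not re-normalized)
    members: np.ndarray  # flat indices into the (H*W) grid


@dataclass
class NormalClusterGrid:
    """Partition of the valid normals after voxel voting and merging."""

    clusters: list[NormalCluster]
    shape: tuple[int, int]

    @property
    def largest(self) -> NormalCluster:
        return max(self.clusters, key=lambda c: len(c.members))


@dataclass
class Plane:
    """Plane through ``centroid`` with unit ``normal``.

    Signed distance of a point p is n . (p - centroid).
    """

    normal: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a finite nonzero vector")
        self.normal = n / norm
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class ContactPointSet:
    """Sparse contact points: |distance to plane| <= d_star."""

    mask: np.ndarray  # (H, W) bool over the cloud grid
    d_star: float  # mm, upper edge of the modal distance bin
    distances: np.ndarray  # (H, W) float, signed plane distance (0 if invalid)


def estimate_normals(cloud: FootPointCloud) -> NormalField:
    """Cross-product normals from 4-neighbour differences, then smoothed.

    n_i = normalize((p_right - p_left) x (p_down - p_up)), oriented toward the
    camera (n_z < 0), averaged once over the valid 3x3 neighbourhood and
    re-normalized. Pixels lacking any of the four neighbours are invalid.
    """
    P = cloud.points
    V = cloud.valid
    h, w = V.shape
    nb_valid = np.zeros((h, w), dtype=bool)
    nb_valid[1:-1, 1:-1] = (
        V[1:-1, 1:-1]
        & V[1:-1, 2:] & V[1:-1, :-2] & V[2:, 1:-1] & V[:-2, 1:-1]
    )
    dx = np.zeros_like(P)
    dy = np.zeros_like(P)
    dx[1:-1, 1:-1] = P[1:-1, 2:] - P[1:-1, :-2]  # right - left
    dy[1:-1, 1:-1] = P[2:, 1:-1] - P[:-2, 1:-1]  # down - up
    n = np.cross(dx, dy)
    norms = np.linalg.norm(n, axis=-1)
    ok = nb_valid & (norms > 1e-12)
    n[ok] /= norms[ok][..., None]
    n[~ok] = 0.0
    # orient toward the camera
    flip = ok & (n[..., 2] > 0)
    n[flip] *= -1.0
    # one smoothing pass: average over valid 3x3 neighbours, re-normalize
    acc = np.zeros_like(n)
    cnt = np.zeros((h, w))
    for dv in (-1, 0, 1):
        for du in (-1, 0, 1):
            sv = slice(max(0, dv), h + min(0, dv))
            su = slice(max(0, du), w + min(0, du))
            tv = slice(max(0, -dv), h + min(0, -dv))
            tu = slice(max(0, -du), w + min(0, -du))
            acc[tv, tu] += np.where(ok[sv, su][..., None], n[sv, su], 0.0)
            cnt[tv, tu] += ok[sv, su]
    sm = np.where(cnt[..., None] > 0, acc / np.maximum(cnt, 1)[..., None], 0.0)
    norms = np.linalg.norm(sm, axis=-1)
    ok2 = ok & (norms > 1e-12)
    sm[ok2] /= norms[ok2][..., None]
    sm[~ok2] = 0.0
    return NormalField(normals=sm, valid=ok2)


def _cell_of(normals: np.ndarray) -> np.ndarray:
    """Voxel cell indices of unit vectors; +1.0 clamps into the last cell."""
    idx = np.floor((normals + 1.0) / CELL_SIZE).astype(int)
    return np.clip(idx, 0, GRID_CELLS - 1)


def cluster_normals(field: NormalField) -> NormalClusterGrid:
    """Voxel-vote the normals and merge adjacent clusters.

    Every non-empty cell starts as a cluster; clusters whose cells are
    26-neighbours are merged, closest-mean pair first, while the Euclidean
    distance between their mean normals is below the cell size, the mean being
    updated after each merge.
    """
    flat_valid = np.flatnonzero(field.valid.ravel())
    if flat_valid.size == 0:
        raise DegenerateGeometryError("no valid normals to cluster")
    normals = field.normals.reshape(-1, 3)[flat_valid]
    cells = _cell_of(normals)
    keys = (cells[:, 0] * GRID_CELLS + cells[:, 1]) * GRID_CELLS + cells[:, 2]
    order = np.argsort(keys, kind="stable")
    uniq, starts = np.unique(keys[order], return_index=True)
    clusters: list[NormalCluster] = []
    bounds = list(starts) + [len(keys)]
    for i, key in enumerate(uniq):
        sel = order[bounds[i]: bounds[i + 1]]
        cell = (int(key // (GRID_CELLS * GRID_CELLS)),
                int((key // GRID_CELLS) % GRID_CELLS),
                int(key % GRID_CELLS))
        clusters.append(NormalCluster(
            cells={cell},
            mean=normals[sel].mean(axis=0),
            members=flat_valid[sel],
        ))

    def adjacent(a: NormalCluster, b: NormalCluster) -> bool:
        for ca, cb in product(a.cells, b.cells):
            if max(abs(ca[0] - cb[0]), abs(ca[1] - cb[1]),
                   abs(ca[2] - cb[2])) <= 1:
                return True
        return False

    # merge closest qualifying pair until stable
    while True:
        best: tuple[float, int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(np.linalg.norm(clusters[i].mean - clusters[j].mean))
                if d < CELL_SIZE and adjacent(clusters[i], clusters[j]):
                    if best is None or d < best[0]:
                        best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = clusters[i], clusters[j]
        na, nb = len(a.members), len(b.members)
        merged = NormalCluster(
            cells=a.cells | b.cells,
            mean=(a.mean * na + b.mean * nb) / (na + nb),
            members=np.concatenate([a.members, b.members]),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return NormalClusterGrid(clusters=clusters, shape=field.valid.shape)


def fit_plane(points: np.ndarray) -> Plane:
    """Least-squares plane through a point set via SVD.

    The centroid anchors the plane; the normal is the right singular vector of
    the centered coordinate matrix with the smallest singular value, oriented
    toward the camera (n_z < 0).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit requires >= 3 points")
    centroid = pts.mean(axis=0)
    A = pts - centroid
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[1] <= 1e-9 * max(1.0, s[0]):
        raise DegenerateGeometryError("points are collinear")
    normal = vt[2]
    if normal[2] > 0:
        normal = -normal
    return Plane(normal=normal, centroid=centroid)


def signed_distance(plane: Plane, p: np.ndarray) -> np.ndarray:
    """Signed plane distance n . (p - centroid); vectorized over (..., 3)."""
    p = np.asarray(p, dtype=float)
    return (p - plane.centroid) @ plane.normal


def detect_contact_points(
    cloud: FootPointCloud,
    bin_mm: float = HIST_BIN_MM,
    hist_range_mm: float = HIST_RANGE_MM,
    n_refine: int = 3,
) -> tuple[Plane, ContactPointSet]:
    """Plane from the dominant normal cluster, then modal-distance gating.

    Absolute point-plane distances are histogrammed in ``bin_mm`` bins over
    [0, hist_range_mm]; the modal bin's upper edge d* defines the contact set
    {foot points : |d| <= d*}. Because single-pixel-baseline normals are
    noisy, the initial cluster-based plane can be tilted by a few degrees;
    the plane is therefore refit ``n_refine`` times on the gated contact
    points themselves (on noise-free input this changes nothing).
    """
    field = estimate_normals(cloud)
    grid = cluster_normals(field)
    largest = grid.largest
    if len(largest.members) < 3:
        raise DegenerateGeometryError("largest normal cluster is too small")
    pts = cloud.points.reshape(-1, 3)[largest.members]
    plane = fit_plane(pts)

    def _gate(plane: Plane) -> tuple[np.ndarray, float, np.ndarray]:
        dist = np.zeros(cloud.valid.shape)
        dist[cloud.valid] = signed_distance(plane, cloud.points[cloud.valid])
        absd = np.abs(dist[cloud.valid])
        nbins = int(round(hist_range_mm / bin_mm))
        hist, edges = np.histogram(absd, bins=nbins,
                                   range=(0.0, hist_range_mm))
        modal = int(np.argmax(hist))
        d_star = float(edges[modal + 1])
        mask = cloud.valid & (np.abs(dist) <= d_star)
        return dist, d_star, mask

    dist, d_star, mask = _gate(plane)
    for _ in range(n_refine):
        if mask.sum() < 3:
            break
        plane = fit_plane(cloud.points[mask])
        dist, d_star, mask = _gate(plane)
    return plane, ContactPointSet(mask=mask, d_star=d_star, distances=dist)
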