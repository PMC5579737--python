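"""Foot-arch parameters (AI, AW, AH) from the contact labeling.

The arch index is the percentage of the main-body footprint area falling in
the middle third of the L-K segment, where K is the heel center (detected as
the farthest salient point of the heel-side boundary profile) and L the foot
of the axis at the most anterior main-body point; the axis runs from K through
the user-supplied second-toe center. The medial border line (MBL) is the
convex-hull edge of the contact region spanning the deepest boundary
concavity — the arch indentation; the arch width is measured in-plane from its
midpoint to the contact region and the arch height along the footplate normal
up to the plantar surface.

2D image points are (row, col) float arrays throughout this module; all
metric quantities are read from the 3D points of the pixels involved, never
from a global mm-per-pixel scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter1d, sobel
from scipy.spatial import ConvexHull

from .contact_points import Plane, detect_contact_points
from .io_camera import FootPointCloud, RGBDFrame
from .mrf_segmentation import (
    CONTACT,
    DEFAULT_WEIGHTS,
    ContactLabeling,
    detect_contact_region,
)
from .preprocess import DEPTH_CUT_MM, largest_component, preprocess_frame

__all__ = [
    "AlignTransform",
    "BoundaryProfile",
    "FootAxis",
    "MedialBorderLine",
    "ArchParameters",
    "PipelineConfig",
    "moore_trace",
    "align_by_pca",
    "split_heel_toe",
    "boundary_profile",
    "detect_heel_center",
    "heel_center",
    "foot_axis",
    "segment_toes",
    "compute_ai",
    "detect_mbl",
    "compute_aw",
    "compute_ah",
    "measure",
]

SOBEL_THRESHOLD = 50.0  # vertical-gradient magnitude gate for the toe edge
BOUNDARY_SIGMA = 5.0  # samples, 1D Gaussian for the boundary profile


class DegenerateAxisError(ValueError):
    """Foot axis endpoints coincide."""


# ---------------------------------------------------------------------------
# geometry helpers


def moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered closed outer boundary of a binary mask (Moore tracing).

    Returns an (N, 2) int array of (row, col) boundary pixels in a consistent
    rotational order. Single-pixel masks yield that pixel.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    pad = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask
    # start: first foreground pixel in scan order
    vs, us = np.nonzero(pad)
    start = (int(vs[0]), int(us[0]))
    # Moore neighbourhood in clockwise order starting from west
    nbs = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
           (0, 1), (1, 1), (1, 0), (1, -1)]
    contour = [start]
    prev_dir = 0  # came from the west (backtrack is west neighbour)
    cur = start
    for _ in range(8 * pad.size):
        found = False
        for k in range(8):
            d = (prev_dir + k) % 8
            nv, nu = cur[0] + nbs[d][0], cur[1] + nbs[d][1]
            if pad[nv, nu]:
                nxt = (nv, nu)
                # next backtrack: neighbour preceding the found pixel
                prev_dir = (d + 5) % 8
                found = True
                break
        if not found:  # isolated pixel
            break
        if nxt == start and len(contour) > 1:
            break
        contour.append(nxt)
        cur = nxt
    return np.array(contour, dtype=int) - 1  # undo padding


def _perp_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray
                   ) -> np.ndarray:
    """Perpendicular distances of 2D points from the line through a and b."""
    ab = b - a
    n = np.linalg.norm(ab)
    if n == 0:
        return np.linalg.norm(points - a, axis=-1)
    d = ab / n
    rel = points - a
    return np.abs(d[0] * rel[..., 1] - d[1] * rel[..., 0])


def convex_hull_indices(points: np.ndarray) -> np.ndarray:
    """Indices of the convex hull vertices of an (N, 2) point set, in order."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return np.arange(len(pts))
    try:
        hull = ConvexHull(pts)
    except Exception:  # collinear sets
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        return np.array([order[0], order[-1]])
    return hull.vertices


# ---------------------------------------------------------------------------
# PCA alignment and heel detection


@dataclass
class AlignTransform:
    """Rigid map between the original and PCA-aligned rasters.

    ``rotation`` columns are the principal axes expressed in (row, col)
    coordinates; a point p_aligned maps back to the original raster as
    rotation @ (p_aligned - offset) + center.
    """

    rotation: np.ndarray  # 2x2, det +1
    center: np.ndarray  # centroid in the original raster
    offset: np.ndarray  # centroid position in the aligned raster
    shape: tuple[int, int]  # aligned raster shape

    def to_original(self, p_aligned: np.ndarray) -> np.ndarray:
        p = np.asarray(p_aligned, dtype=float)
        return (p - self.offset) @ self.rotation.T + self.center

    def to_aligned(self, p_original: np.ndarray) -> np.ndarray:
        p = np.asarray(p_original, dtype=float)
        return (p - self.center) @ self.rotation + self.offset


def align_by_pca(mask: np.ndarray) -> tuple[np.ndarray, AlignTransform]:
    """Rotate a mask about its centroid so the first principal axis is
    vertical (along rows). Returns the aligned mask and the transform."""
    mask = np.asarray(mask).astype(bool)
    coords = np.argwhere(mask).astype(float)
    if coords.size == 0:
        raise ValueError("align_by_pca: empty mask")
    c = coords.mean(axis=0)
    cov = np.cov((coords - c).T) if len(coords) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    if np.isclose(evals[0], evals[1], rtol=1e-6, atol=1e-9):
        warnings.warn("align_by_pca: isotropic mask, orientation tie "
                      "broken toward 0 degrees", stacklevel=2)
        R = np.eye(2)
    else:
        e1 = evecs[:, 1]  # largest eigenvalue last in eigh
        if e1[0] < 0:
            e1 = -e1
        R = np.column_stack([e1, [-e1[1], e1[0]]])
    q = (coords - c) @ R
    margin = 3.0
    qmin = q.min(axis=0)
    out_shape = tuple(int(np.ceil(x)) + 2 * int(margin) + 1
                      for x in (q.max(axis=0) - qmin))
    offset = margin - qmin
    aligned = affine_transform(
        mask.astype(np.uint8), R, offset=c - R @ offset,
        output_shape=out_shape, order=0,
    ).astype(bool)
    return aligned, AlignTransform(rotation=R, center=c, offset=offset,
                                   shape=out_shape)


def split_heel_toe(aligned: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Split an aligned mask at its centroid, perpendicular to the axis.

    The half with the greater maximum width (row extent perpendicular to the
    vertical principal axis) is the toe side. Returns (toe_mask, heel_mask) as
    full-size masks.
    """
    aligned = np.asarray(aligned).astype(bool)
    coords = np.argwhere(aligned)
    if coords.size == 0:
        raise ValueError("split_heel_toe: empty mask")
    vc = coords[:, 0].mean()
    rows = np.arange(aligned.shape[0])
    top = aligned & (rows[:, None] <= vc)
    bot = aligned & (rows[:, None] > vc)

    def max_width(m: np.ndarray) -> int:
        widths = [
            int(us.max() - us.min() + 1)
            for us in (np.nonzero(r)[0] for r in m) if us.size
        ]
        return max(widths, default=0)

    w_top, w_bot = max_width(top), max_width(bot)
    if w_top == w_bot:
        # tie: the half reaching farther from the centroid wins the toe label
        ext_top = vc - coords[:, 0].min()
        ext_bot = coords[:, 0].max() - vc
        warnings.warn("split_heel_toe: equal maximum widths; tie broken by "
                      "axial extent", stacklevel=2)
        return (top, bot) if ext_top >= ext_bot else (bot, top)
    return (top, bot) if w_top > w_bot else (bot, top)


@dataclass
class BoundaryProfile:
    """Centroid-to-boundary distance profile of a (heel-side) mask."""

    cn: np.ndarray  # reference centroid (row, col)
    boundary: np.ndarray  # (N, 2) ordered closed contour
    li: np.ndarray  # raw distances cn -> b_i
    l_hat: np.ndarray  # Gaussian-smoothed distances
    l_prime: np.ndarray  # central-difference derivative of l_hat
    salient: np.ndarray  # indices of local maxima of l_hat


def boundary_profile(mask: np.ndarray, cn: np.ndarray | None = None,
                     sigma: float = BOUNDARY_SIGMA) -> BoundaryProfile:
    """Trace the mask boundary and locate salient (locally farthest) points.

    Distances from ``cn`` (default: the mask centroid) are smoothed with a
    circular 1D Gaussian, differentiated by central differences, and the
    zero-crossing local maxima are marked as salient.
    """
    mask = np.asarray(mask).astype(bool)
    boundary = moore_trace(mask)
    if cn is None:
        cn = np.argwhere(mask).mean(axis=0)
    cn = np.asarray(cn, dtype=float)
    li = np.linalg.norm(boundary - cn, axis=1)
    n = len(li)
    if n < max(3, int(4 * sigma)):
        new_sigma = max(0.5, n / 8.0)
        if new_sigma < sigma:
            warnings.warn(
                f"boundary shorter than the smoothing kernel; "
                f"sigma reduced to {new_sigma:.2f}", stacklevel=2)
            sigma = new_sigma
    l_hat = gaussian_filter1d(li, sigma=sigma, mode="wrap")
    l_prime = (np.roll(l_hat, -1) - np.roll(l_hat, 1)) / 2.0
    # a strict local maximum of l_hat is exactly a +/- zero crossing of the
    # central-difference derivative (the crossing falls between samples, so
    # testing the derivative sign at the same index would miss it)
    prev = np.roll(l_hat, 1)
    nxt = np.roll(l_hat, -1)
    is_max = (l_hat >= prev) & (l_hat >= nxt) & ((l_hat > prev) | (l_hat > nxt))
    # require half-pixel prominence over a 2-sigma window so rasterization
    # ripples of a smooth boundary do not count as salient
    half = max(3, int(np.ceil(2 * sigma)))
    cand = np.flatnonzero(is_max)
    keep = []
    for i in cand:
        win = np.take(l_hat, np.arange(i - half, i + half + 1), mode="wrap")
        if l_hat[i] - win.min() >= 0.5:
            keep.append(i)
    salient = np.asarray(keep, dtype=int)
    return BoundaryProfile(cn=cn, boundary=boundary, li=li, l_hat=l_hat,
                           l_prime=l_prime, salient=salient)


def detect_heel_center(heel_mask: np.ndarray,
                       cn: np.ndarray | None = None,
                       sigma: float = BOUNDARY_SIGMA) -> np.ndarray:
    """Heel center K: the salient boundary point farthest from the centroid.

    Falls back to the globally farthest boundary point (with a warning) when
    no salient point exists.
    """
    prof = boundary_profile(heel_mask, cn=cn, sigma=sigma)
    if prof.salient.size:
        k = prof.salient[np.argmax(prof.li[prof.salient])]
    else:
        warnings.warn("no salient point on the heel boundary; falling back "
                      "to the farthest boundary point", stacklevel=2)
        k = int(np.argmax(prof.li))
    return prof.boundary[k].astype(float)


def heel_center(contact_mask: np.ndarray,
                sigma: float = BOUNDARY_SIGMA) -> np.ndarray:
    """K in original raster coordinates: align, split, detect, map back."""
    aligned, tf = align_by_pca(contact_mask)
    _, heel_half = split_heel_toe(aligned)
    cn = np.argwhere(aligned).mean(axis=0)
    k_aligned = detect_heel_center(heel_half, cn=cn, sigma=sigma)
    return tf.to_original(k_aligned)


# ---------------------------------------------------------------------------
# foot axis, toe removal, arch index


@dataclass
class FootAxis:
    """Foot axis through the heel center K and the second-toe center."""

    K: np.ndarray  # heel center, (row, col)
    toe2: np.ndarray  # second-toe center, (row, col)
    direction: np.ndarray  # unit (row, col), K -> toe2
    L: np.ndarray | None = None  # axis foot at the most anterior point


def _anterior_foot(mask: np.ndarray, K: np.ndarray,
                   direction: np.ndarray) -> np.ndarray:
    """L: intersection of the axis with the perpendicular tangent at the
    most anterior mask point; ties average to the midpoint of the tied run."""
    coords = np.argwhere(mask).astype(float)
    t = (coords - K) @ direction
    tmax = t.max()
    tied = coords[np.isclose(t, tmax, atol=1e-9)]
    ref = tied.mean(axis=0)
    return K + ((ref - K) @ direction) * direction


def foot_axis(contact_mask: np.ndarray, toe2_center: np.ndarray,
              K: np.ndarray | None = None,
              main_body_mask: np.ndarray | None = None,
              sigma: float = BOUNDARY_SIGMA) -> FootAxis:
    """Axis through the (detected) heel center and the given toe-2 center.

    ``toe2_center`` is a (row, col) pixel position — in the measurement system
    it comes from the operator clicking the second toe. ``main_body_mask``
    (toeless contact region) defines the anterior point for L; the full
    contact mask is used when it is not yet available.
    """
    if K is None:
        K = heel_center(contact_mask, sigma=sigma)
    K = np.asarray(K, dtype=float)
    toe2 = np.asarray(toe2_center, dtype=float)
    d = toe2 - K
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise DegenerateAxisError("toe-2 center coincides with heel center")
    direction = d / norm
    body = contact_mask if main_body_mask is None else main_body_mask
    L = _anterior_foot(body, K, direction)
    return FootAxis(K=K, toe2=toe2, direction=direction, L=L)


def segment_toes(
    color: np.ndarray,
    foot_mask: np.ndarray,
    axis: FootAxis,
    threshold: float = SOBEL_THRESHOLD,
) -> np.ndarray:
    """Remove the toes: keep the foot pixels posterior to the toe-gap edge.

    The image is rotated so the axis is vertical (toes up); within the
    anterior third each column keeps its strongest vertical Sobel response
    with magnitude strictly above ``threshold`` (per-column non-maximal
    suppression); edge positions are smoothed by neighbour averaging, columns
    without an edge are interpolated from their neighbours. Pixels anterior to
    the edge curve are removed. When no edge fires anywhere, the whole mask is
    returned (no toes found).
    """
    foot_mask = np.asarray(foot_mask).astype(bool)
    # rotation taking the axis direction to "up" (-v) in the rotated frame
    e1 = -axis.direction  # rotated rows increase toward the heel
    R = np.column_stack([e1, [-e1[1], e1[0]]])
    coords = np.argwhere(foot_mask).astype(float)
    c = coords.mean(axis=0)
    q = (coords - c) @ R
    margin = 3.0
    qmin, qmax = q.min(axis=0), q.max(axis=0)
    out_shape = tuple(int(np.ceil(x)) + 7 for x in (qmax - qmin))
    offset = margin - qmin
    gray = (0.299 * color[..., 0] + 0.587 * color[..., 1]
            + 0.114 * color[..., 2]).astype(float)
    rot = dict(matrix=R, offset=c - R @ offset, output_shape=out_shape)
    gray_r = affine_transform(gray, order=1, **rot)
    mask_r = affine_transform(foot_mask.astype(np.uint8), order=0,
                              **rot).astype(bool)
    if not mask_r.any():
        return foot_mask
    rows_present = np.nonzero(mask_r.any(axis=1))[0]
    v0, v1 = rows_present[0], rows_present[-1]
    cut = v0 + (v1 - v0) / 3.0  # anterior third of the rotated foot
    grad = sobel(gray_r, axis=0)
    mag = np.abs(grad)
    band = np.zeros_like(mask_r)
    band[: int(np.ceil(cut)) + 1] = True
    band &= mask_r
    mag_b = np.where(band, mag, 0.0)
    best_row = np.argmax(mag_b, axis=0)
    best_val = mag_b[best_row, np.arange(mag_b.shape[1])]
    has_edge = best_val > threshold  # strict: exactly-threshold is excluded
    cols = np.arange(mag_b.shape[1])
    cols_mask = mask_r.any(axis=0)
    if not has_edge.any():
        return foot_mask
    edge = np.interp(cols, cols[has_edge], best_row[has_edge].astype(float))
    # neighbour-average smoothing of the edge curve
    kernel = np.ones(5) / 5.0
    edge = np.convolve(np.pad(edge, 2, mode="edge"), kernel, mode="valid")
    keep_r = mask_r & (np.arange(mask_r.shape[0])[:, None] > edge[None, :])
    keep_r &= cols_mask[None, :]
    if not keep_r.any():
        return foot_mask
    # map the kept mask back to the original raster
    vv, uu = np.mgrid[0: foot_mask.shape[0], 0: foot_mask.shape[1]]
    pts = np.stack([vv.ravel(), uu.ravel()], axis=1).astype(float)
    q = (pts - c) @ R + offset
    qi = np.round(q).astype(int)
    ok = ((qi[:, 0] >= 0) & (qi[:, 0] < out_shape[0])
          & (qi[:, 1] >= 0) & (qi[:, 1] < out_shape[1]))
    keep = np.zeros(foot_mask.size, dtype=bool)
    keep[ok] = keep_r[qi[ok, 0], qi[ok, 1]]
    return keep.reshape(foot_mask.shape) & foot_mask


def compute_ai(contact_mask: np.ndarray, axis: FootAxis,
               main_body_mask: np.ndarray
               ) -> tuple[float, tuple[int, int, int], FootAxis]:
    """Arch index: middle-third share of the main-body contact area.

    The L-K segment is cut at 1/3 and 2/3 perpendicular to the axis; thirds
    use half-open intervals [0, 1/3), [1/3, 2/3), [2/3, 1] of the normalized
    axial coordinate (clamped) so no pixel is double counted.
    """
    body = np.asarray(contact_mask).astype(bool) \
        & np.asarray(main_body_mask).astype(bool)
    if not body.any():
        raise ValueError("empty main-body contact region: AI undefined")
    # the footprint main body is one region; drop stray specks left by the
    # toe-edge interpolation so they cannot drag the anterior point L
    body = largest_component(body)
    axis = FootAxis(K=axis.K, toe2=axis.toe2, direction=axis.direction,
                    L=_anterior_foot(body, axis.K, axis.direction))
    coords = np.argwhere(body).astype(float)
    u = -axis.direction  # from L (anterior) toward K (posterior)
    span = (axis.K - axis.L) @ u
    if span <= 0:
        raise ValueError("degenerate L-K segment")
    t = np.clip(((coords - axis.L) @ u) / span, 0.0, 1.0)
    anterior = int((t < 1.0 / 3.0).sum())
    middle = int(((t >= 1.0 / 3.0) & (t < 2.0 / 3.0)).sum())
    posterior = int((t >= 2.0 / 3.0).sum())
    total = anterior + middle + posterior
    ai = 100.0 * middle / total
    return ai, (anterior, middle, posterior), axis


# ---------------------------------------------------------------------------
# medial border line, arch width, arch height


@dataclass
class MedialBorderLine:
    """Convex-hull edge spanning the deepest contact-boundary concavity."""

    p_start: np.ndarray  # (row, col)
    p_end: np.ndarray  # (row, col)
    p_start_3d: np.ndarray
    p_end_3d: np.ndarray
    depth_px: float  # greatest gap between the edge and its boundary arc

    @property
    def midpoint_3d(self) -> np.ndarray:
        return (self.p_start_3d + self.p_end_3d) / 2.0

    @property
    def midpoint(self) -> np.ndarray:
        return (self.p_start + self.p_end) / 2.0


def detect_mbl(contact_mask: np.ndarray,
               cloud: FootPointCloud) -> MedialBorderLine:
    """Find the MBL: the hull edge with the greatest depth to the boundary.

    The convex hull of the contact region is computed on its traced boundary;
    for each hull edge the depth is the maximum perpendicular distance from
    the edge to the boundary arc it spans. A convex region (all depths ~ 0)
    returns the longest edge with depth 0 and a warning.
    """
    mask = largest_component(np.asarray(contact_mask).astype(bool))
    if not mask.any():
        raise ValueError("empty contact mask")
    boundary = moore_trace(mask)
    n = len(boundary)
    hull_idx = convex_hull_indices(boundary.astype(float))
    if len(hull_idx) < 2:
        raise ValueError("contact region is degenerate (a single point)")
    # orient the hull traversal along increasing boundary index
    h_sorted = np.sort(hull_idx)
    # merge pixel-staircase corners: a nearly straight run of boundary pixels
    # quantizes into small convex steps that would split a hull edge (and
    # displace the MBL midpoint); drop vertices deviating < 1.5 px from the
    # chord of their neighbours
    while len(h_sorted) > 2:
        pts = boundary[h_sorted].astype(float)
        dev = np.array([
            _perp_distance(pts[k][None, :], pts[k - 1],
                           pts[(k + 1) % len(pts)])[0]
            for k in range(len(pts))
        ])
        worst = int(np.argmin(dev))
        if dev[worst] >= 1.5:
            break
        h_sorted = np.delete(h_sorted, worst)
    best_depth, best_pair, best_len = -1.0, None, -1.0
    for k in range(len(h_sorted)):
        i0 = int(h_sorted[k])
        i1 = int(h_sorted[(k + 1) % len(h_sorted)])
        a, b = boundary[i0].astype(float), boundary[i1].astype(float)
        if i1 > i0:
            arc = boundary[i0: i1 + 1]
        else:  # wrap-around arc
            arc = np.vstack([boundary[i0:], boundary[: i1 + 1]])
        depth = float(_perp_distance(arc.astype(float), a, b).max()) \
            if len(arc) else 0.0
        length = float(np.linalg.norm(b - a))
        if depth > best_depth + 1e-9 or (
                abs(depth - best_depth) <= 1e-9 and length > best_len):
            best_depth, best_pair, best_len = depth, (a, b), length
    a, b = best_pair
    if best_depth < 1.0:
        warnings.warn("contact region is convex; MBL depth ~ 0",
                      stacklevel=2)
    pa = cloud.points[int(round(a[0])), int(round(a[1]))]
    pb = cloud.points[int(round(b[0])), int(round(b[1]))]
    return MedialBorderLine(p_start=a, p_end=b, p_start_3d=pa.copy(),
                            p_end_3d=pb.copy(), depth_px=best_depth)


def compute_aw(mbl: MedialBorderLine, contact_mask: np.ndarray,
               cloud: FootPointCloud, plane: Plane) -> float:
    """Arch width: distance from the MBL midpoint, perpendicular to the MBL
    and toward the foot interior, to the first contact-region point hit."""
    mask = np.asarray(contact_mask).astype(bool)
    mid = mbl.midpoint
    edge = mbl.p_end - mbl.p_start
    edge = edge / np.linalg.norm(edge)
    perp = np.array([-edge[1], edge[0]])
    centroid = np.argwhere(mask).mean(axis=0)
    if (centroid - mid) @ perp < 0:
        perp = -perp
    h, w = mask.shape
    start = mid.copy()
    ri, ci = int(round(start[0])), int(round(start[1]))
    if 0 <= ri < h and 0 <= ci < w and mask[ri, ci]:
        return 0.0
    step = 0.5
    tmax = float(np.hypot(h, w))
    t = step
    while t <= tmax:
        p = mid + t * perp
        ri, ci = int(round(p[0])), int(round(p[1]))
        if not (0 <= ri < h and 0 <= ci < w):
            raise ValueError("AW ray exited the image without hitting the "
                             "contact region")
        if mask[ri, ci]:
            hit3d = cloud.points[ri, ci]
            d3 = float(np.linalg.norm(hit3d - mbl.midpoint_3d))
            # sub-pixel refinement: the true boundary lies between the last
            # free sample and the hit sample
            return d3 * max(t - step / 2.0, 0.0) / t
        t += step
    raise ValueError("AW ray found no contact-region intersection")


def compute_ah(mbl: MedialBorderLine, cloud: FootPointCloud,
               plane: Plane, search_mm: float = 15.0) -> float:
    """Arch height: distance from the MBL midpoint, along the footplate
    normal, to the nearest plantar-surface point on that line.

    Raises when no foot point lies within ``search_mm`` of the line (about a
    10 px neighbourhood at the nominal working distance).
    """
    n = plane.normal
    # the MBL is a footprint line: project its midpoint into the plate plane
    # so depth noise on the endpoint pixels cannot offset the height origin
    mid = mbl.midpoint_3d
    mid = mid - ((mid - plane.centroid) @ n) * n
    pts = cloud.valid_points()
    q = pts - mid
    along = q @ n
    perp = np.linalg.norm(q - along[:, None] * n[None, :], axis=1)
    best = int(np.argmin(perp))
    if perp[best] > search_mm:
        raise ValueError("no plantar-surface point near the AH line")
    return float(np.linalg.norm(pts[best] - mid))


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """All tunable thresholds of the measurement pipeline in one place."""

    depth_cut_mm: float = DEPTH_CUT_MM
    hist_bin_mm: float = 1.0
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    beta: float | None = None  # None: contrast-normalized per frame
    n_per_class: int = 500
    dilation_radius: int = 5
    boundary_sigma: float = BOUNDARY_SIGMA
    sobel_threshold: float = SOBEL_THRESHOLD
    backend: str = "graphcut"

    def to_dict(self) -> dict:
        return {
            "depth_cut_mm": self.depth_cut_mm,
            "hist_bin_mm": self.hist_bin_mm,
            "weights": list(self.weights),
            "beta": self.beta,
            "n_per_class": self.n_per_class,
            "dilation_radius": self.dilation_radius,
            "boundary_sigma": self.boundary_sigma,
            "sobel_threshold": self.sobel_threshold,
            "backend": self.backend,
        }


@dataclass
class ArchParameters:
    """The three foot-arch parameters plus the geometry justifying them."""

    AI: float  # percent
    AW: float  # mm
    AH: float  # mm
    areas: tuple[int, int, int]  # anterior, middle, posterior pixel counts
    axis: FootAxis
    mbl: MedialBorderLine
    plane: Plane
    labeling: ContactLabeling | None = None
    contact_mask: np.ndarray | None = None
    main_body_mask: np.ndarray | None = None
    d_star: float | None = None

    def to_dict(self) -> dict:
        return {
            "AI_percent": self.AI,
            "AW_mm": self.AW,
            "AH_mm": self.AH,
            "areas_px": list(self.areas),
            "K_rc": self.axis.K.tolist(),
            "L_rc": self.axis.L.tolist() if self.axis.L is not None else None,
            "toe2_rc": self.axis.toe2.tolist(),
            "mbl_start_rc": self.mbl.p_start.tolist(),
            "mbl_end_rc": self.mbl.p_end.tolist(),
            "mbl_midpoint_3d_mm": self.mbl.midpoint_3d.tolist(),
            "plane_normal": self.plane.normal.tolist(),
            "plane_centroid_mm": self.plane.centroid.tolist(),
            "d_star_mm": self.d_star,
        }


def measure(frame: RGBDFrame, toe2_center: np.ndarray,
            config: PipelineConfig | None = None,
            seed: int = 0) -> ArchParameters:
    """Run the full pipeline on one frame.

    ``toe2_center`` is the second-toe center pixel as (row, col) — the manual
    input of the measurement protocol.
    """
    cfg = config or PipelineConfig()
    cloud = preprocess_frame(frame, t_max=cfg.depth_cut_mm)
    plane, contacts = detect_contact_points(cloud, bin_mm=cfg.hist_bin_mm)
    labeling = detect_contact_region(
        cloud, plane, contacts,
        weights=cfg.weights, seed=seed, n_per_class=cfg.n_per_class,
        dilation_radius=cfg.dilation_radius, beta=cfg.beta,
        backend=cfg.backend,
    )
    contact_mask = largest_component(labeling.labels == CONTACT)
    if not contact_mask.any():
        raise ValueError("MRF segmentation produced no contact region")
    K = heel_center(contact_mask, sigma=cfg.boundary_sigma)
    axis = foot_axis(contact_mask, toe2_center, K=K,
                     sigma=cfg.boundary_sigma)
    main_body = segment_toes(frame.color.astype(float), cloud.valid, axis,
                             threshold=cfg.sobel_threshold)
    ai, areas, axis = compute_ai(contact_mask, axis, main_body)
    body_contact = largest_component(contact_mask & main_body)
    mbl = detect_mbl(body_contact, cloud)
    aw = compute_aw(mbl, body_contact, cloud, plane)
    ah = compute_ah(mbl, cloud, plane)
    return ArchParameters(
        AI=ai, AW=aw, AH=ah, areas=areas, axis=axis, mbl=mbl, plane=plane,
        labeling=labeling, contact_mask=contact_mask,
        main_body_mask=main_body, d_star=contacts.d_star,
    )
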