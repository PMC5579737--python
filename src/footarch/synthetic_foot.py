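"""Synthetic RGB-D plantar scenes with exact ground truth.

Emulates the measurement geometry of the system: a camera looking up at a
(possibly tilted) transparent footplate ~300 mm away, a foot standing on it
with a dominant planar contact region, a raised medial arch dome, toes
separated from the main body by a dark gap band, contact-region skin
discoloration, and Gaussian depth noise at the sensor's relative error level
(~0.5-0.6 % of distance).

The foot template is parametric, so the ground-truth arch parameters are
known by construction: the medial silhouette edge is a straight line whose
midfoot stretch is recessed by up to ``arch_width`` (the MBL concavity), and
the dome apex above the medial-line midpoint is ``arch_height`` high. The
ground-truth arch index is obtained by counting rendered contact pixels in
the axial thirds, with an independent continuum-integral cross-check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contact_points import Plane
from .io_camera import (
    CameraIntrinsics,
    DepthToColorExtrinsics,
    RGBDFrame,
    save_frame,
)

__all__ = ["FootSceneParams", "SceneGroundTruth", "generate_scene",
           "make_fixture_suite", "PRESETS", "preset_params"]

BACKGROUND_DEPTH_MM = 2000.0


@dataclass(frozen=True)
class FootSceneParams:
    """Scene parameters; all lengths in mm unless suffixed ``_px``."""

    foot_length: float = 245.0
    heel_width: float = 60.0
    forefoot_width: float = 90.0
    arch_width: float = 33.0
    arch_height: float = 11.0
    toe_gap_px: float = 6.0
    gap_lift_mm: float = 3.0  # how far the toe-gap skin bridges off the plate
    plate_distance: float = 300.0
    plate_tilt: tuple[float, float] = (0.0, 0.0)  # deg about x and y
    depth_noise_sigma: float = 0.0  # mm
    color_noise_sigma: float = 10.0
    # relative lighting span across the raster (horizontal, vertical):
    # uneven illumination is what makes the color cue locally ambiguous
    illumination_gradient: tuple[float, float] = (0.15, 0.20)
    contact_color: tuple[int, int, int] = (228, 198, 186)
    noncontact_color: tuple[int, int, int] = (206, 170, 158)
    background_color: tuple[int, int, int] = (70, 72, 75)
    gap_color: tuple[int, int, int] = (12, 12, 12)
    frame_shape: tuple[int, int] = (480, 640)  # rows, cols
    focal_px: float = 410.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("foot_length", "heel_width", "forefoot_width",
                     "plate_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arch_width < 0 or self.arch_height < 0:
            raise ValueError("arch dimensions must be non-negative")
        if self.arch_height >= self.plate_distance:
            raise ValueError("arch_height must be below plate_distance")
        if max(abs(t) for t in self.plate_tilt) > 15.0:
            raise ValueError("plate tilt is limited to 15 degrees")
        if self.arch_width >= self.forefoot_width:
            raise ValueError("arch_width leaves no contact region")


@dataclass
class SceneGroundTruth:
    """Everything the generator knows exactly about the scene."""

    contact_mask: np.ndarray
    foot_mask: np.ndarray
    toe_mask: np.ndarray
    body_mask: np.ndarray  # main body: silhouette up to the toe gap
    plane: Plane
    toe2_center: np.ndarray  # (row, col)
    heel_apex: np.ndarray  # (row, col)
    AI_true: float  # percent, by pixel counting on the rendered masks
    AI_analytic: float  # percent, continuum integral of the template widths
    AW_true: float  # mm, by construction
    AH_true: float  # mm, by construction
    mm_per_px: float
    params: FootSceneParams


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


class _FootTemplate:
    """Continuum foot model in plate coordinates (xi lateral, eta axial).

    The medial silhouette edge sits at xi = x_M = 0 along the straight stretch
    of the main body; the lateral edge follows the heel->forefoot width blend.
    eta runs from 0 (heel apex) to foot_length (toe tips).
    """

    def __init__(self, p: FootSceneParams, gap_mm: float):
        self.p = p
        self.body_length = 0.72 * p.foot_length
        self.gap_mm = gap_mm
        self.r_heel = 0.42 * p.heel_width
        # straight stretch of the medial edge; the body front is flat so the
        # toe-gap band abuts it with no background wedge
        self.straight = (self.r_heel, self.body_length)
        mid = 0.5 * (self.straight[0] + self.straight[1])
        arch_len = 0.46 * self.body_length
        self.arch_span = (mid - arch_len / 2.0, mid + arch_len / 2.0)
        self.arch_mid = mid
        # toe layout: 5 ellipses, big toe at the medial side
        fr = np.array([0.26, 0.20, 0.18, 0.16, 0.14])
        widths = fr * p.forefoot_width * 0.96
        lengths = np.array([1.0, 0.95, 0.85, 0.75, 0.65]) * (
            p.foot_length - self.body_length - gap_mm)
        centers = -(np.cumsum(widths) - widths / 2.0) + 0.0
        self.toe_widths, self.toe_lengths, self.toe_centers = (
            widths, lengths, centers)

    def width(self, eta: np.ndarray) -> np.ndarray:
        """Total body width at eta (before end caps).

        Linear heel-to-forefoot taper: the lateral footprint border is then a
        straight line (as in real footprints), so the only deep boundary
        concavity is the medial arch indentation.
        """
        p = self.p
        s = np.clip(eta / self.body_length, 0.0, 1.0)
        return p.heel_width + (p.forefoot_width - p.heel_width) * s

    def body_edges(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(medial, lateral) silhouette edges of the main body at eta."""
        Lb = self.body_length
        W = self.width(eta)
        med = np.zeros_like(eta)
        lat = -W
        # rounded heel cap; the anterior end is flat against the toe gap
        r = self.r_heel
        cap = eta < r
        gh = np.sqrt(np.clip(1.0 - ((r - eta) / r) ** 2, 0.0, 1.0))
        g = np.where(cap, gh, 1.0)
        center = (med + lat) / 2.0
        half = (med - lat) / 2.0 * g
        out = eta < 0
        out |= eta > Lb
        med_e = np.where(out, np.nan, center + half)
        lat_e = np.where(out, np.nan, center - half)
        return med_e, lat_e

    def _axial(self, eta: np.ndarray) -> np.ndarray:
        """Axial arch profile: smooth flanks around a central plateau.

        The plateau makes the arch depth and height insensitive to small
        axial errors in locating the MBL midpoint, as in a real arch whose
        deepest section is broad.
        """
        e1, e2 = self.arch_span
        u = (eta - e1) / (e2 - e1)
        rise = _smoothstep(u / 0.3)
        fall = _smoothstep((1.0 - u) / 0.3)
        return np.where((u > 0) & (u < 1), np.minimum(rise, fall), 0.0)

    def arch_cut(self, eta: np.ndarray) -> np.ndarray:
        """Recession depth of the medial *contact* boundary at eta."""
        return self.p.arch_width * self._axial(eta)

    def dome_height(self, xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Foot-surface height above the plate (0 in the contact region)."""
        c = self.arch_cut(eta)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(c > 0, (xi - (0.0 - c)) / np.where(c > 0, c, 1.0),
                         0.0)
        # steep take-off at the contact edge: the contact boundary stays
        # sharp, i.e. insensitive to the distance threshold used to detect it
        ramp = np.sqrt(np.clip(t, 0.0, 1.0))
        h = self.p.arch_height * self._axial(eta) * ramp
        return np.where(c > 0, h, 0.0)

    def in_toe(self, xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        Lb, g = self.body_length, self.gap_mm
        base = Lb + g
        hit = np.zeros(xi.shape, dtype=bool)
        for w, ln, cx in zip(self.toe_widths, self.toe_lengths,
                             self.toe_centers):
            hit |= (((xi - cx) / (w / 2.0)) ** 2
                    + ((eta - (base + ln / 2.0)) / (ln / 2.0)) ** 2) <= 1.0
        return hit

    def in_gap(self, xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        Lb, g = self.body_length, self.gap_mm
        W = self.width(np.full_like(xi, Lb * 0.99))
        return ((eta >= Lb) & (eta < Lb + g)
                & (xi <= 0.0) & (xi >= -W))

    def toe2_center_plate(self) -> tuple[float, float]:
        w, ln, cx = (self.toe_widths[1], self.toe_lengths[1],
                     self.toe_centers[1])
        return cx, self.body_length + self.gap_mm + ln / 2.0

    def contact_width(self, eta: float) -> float:
        """Continuum contact width at eta (for the analytic AI integral)."""
        med, lat = self.body_edges(np.array([eta]))
        if np.isnan(med[0]):
            return 0.0
        return float(max(0.0, (med[0] - self.arch_cut(np.array([eta]))[0])
                         - lat[0]))


def _analytic_ai(tpl: _FootTemplate) -> float:
    """Continuum AI: thirds of [0, body_length] along the axis."""
    Lb = tpl.body_length
    eta = np.linspace(0.0, Lb, 4097)
    w = np.array([tpl.contact_width(e) for e in eta])
    cum = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2.0
                                           * np.diff(eta))])
    total = cum[-1]

    def area(a: float, b: float) -> float:
        return float(np.interp(b, eta, cum) - np.interp(a, eta, cum))

    middle = area(Lb / 3.0, 2.0 * Lb / 3.0)
    return 100.0 * middle / total


def generate_scene(params: FootSceneParams
                   ) -> tuple[RGBDFrame, SceneGroundTruth]:
    """Render one synthetic RGB-D frame with its exact ground truth."""
    p = params
    h, w = p.frame_shape
    f = p.focal_px
    K = CameraIntrinsics(fx=f, fy=f, cx=(w - 1) / 2.0, cy=(h - 1) / 2.0,
                         width=w, height=h)
    rng = np.random.default_rng(p.seed)

    # plate plane, tilted about the camera x/y axes; normal toward the camera
    R = _rot_x(p.plate_tilt[0]) @ _rot_y(p.plate_tilt[1])
    n = R @ np.array([0.0, 0.0, -1.0])
    p0 = np.array([0.0, 0.0, p.plate_distance])
    # in-plane frame: eta toward the image top (toes up), xi completes it
    up = np.array([0.0, -1.0, 0.0])
    e_eta = up - (up @ n) * n
    e_eta /= np.linalg.norm(e_eta)
    e_xi = np.cross(e_eta, n)

    mm_per_px = p.plate_distance / f
    gap_mm = p.toe_gap_px * mm_per_px
    tpl = _FootTemplate(p, gap_mm)
    # center the foot on the optical axis
    origin = p0 - (p.foot_length / 2.0) * e_eta \
        + (p.forefoot_width / 2.0) * e_xi

    uu, vv = np.meshgrid(np.arange(w, dtype=float),
                         np.arange(h, dtype=float))
    rays = np.stack([(uu - K.cx) / K.fx, (vv - K.cy) / K.fy,
                     np.ones_like(uu)], axis=-1)
    denom = rays @ n
    t = (p0 @ n) / denom
    plate_pts = rays * t[..., None]
    rel = plate_pts - origin
    xi = rel @ e_xi
    eta = rel @ e_eta

    med, lat = tpl.body_edges(eta)
    in_body = ~np.isnan(med) & (xi <= med) & (xi >= lat)
    in_gap = tpl.in_gap(xi, eta)
    in_toe = tpl.in_toe(xi, eta)
    foot = in_body | in_gap | in_toe

    height = np.zeros_like(xi)
    height[in_body] = tpl.dome_height(xi[in_body], eta[in_body])
    height[in_gap] = p.gap_lift_mm
    contact = foot & (height <= 0.0)

    if not contact.any():
        raise ValueError("scene parameters yield an empty contact region")

    away = -n  # unit normal pointing from the plate away from the camera
    surface = plate_pts + height[..., None] * away
    depth = np.where(foot, surface[..., 2], BACKGROUND_DEPTH_MM)
    if p.depth_noise_sigma > 0:
        depth = depth + rng.normal(0.0, p.depth_noise_sigma, size=depth.shape)
    depth = np.maximum(depth, 1.0)

    color = np.empty((h, w, 3), dtype=float)
    color[:] = p.background_color
    color[foot] = p.noncontact_color
    color[contact] = p.contact_color
    color[in_toe & contact] = p.contact_color
    color[in_gap] = p.gap_color
    gx, gy = p.illumination_gradient
    lighting = (1.0 + gx * (uu - K.cx) / w + gy * (vv - K.cy) / h)
    color *= lighting[..., None]
    if p.color_noise_sigma > 0:
        color = color + rng.normal(0.0, p.color_noise_sigma, size=color.shape)
    color = np.clip(color, 0, 255).astype(np.uint8)

    frame = RGBDFrame(depth=depth, color=color, intrinsics_depth=K,
                      intrinsics_color=K,
                      extrinsics=DepthToColorExtrinsics.identity())

    plane = Plane(normal=n, centroid=p0)

    # ground-truth key points (project template points through the camera)
    def _project_plate(xi_mm: float, eta_mm: float) -> np.ndarray:
        q = origin + xi_mm * e_xi + eta_mm * e_eta
        return np.array([K.fy * q[1] / q[2] + K.cy,
                         K.fx * q[0] / q[2] + K.cx])

    toe2_xi, toe2_eta = tpl.toe2_center_plate()
    toe2_rc = _project_plate(toe2_xi, toe2_eta)
    heel_rc = _project_plate(-p.heel_width / 2.0, 0.0)

    body_mask = in_body
    # AI by pixel counting with the true axis (pure-eta thirds)
    body_contact = contact & body_mask
    Lb = tpl.body_length
    tt = eta[body_contact] / Lb
    middle = int(((tt >= 1.0 / 3.0) & (tt < 2.0 / 3.0)).sum())
    total = int(body_contact.sum())
    ai_true = 100.0 * middle / total
    ai_analytic = _analytic_ai(tpl)

    gt = SceneGroundTruth(
        contact_mask=contact,
        foot_mask=foot,
        toe_mask=in_toe,
        body_mask=body_mask,
        plane=plane,
        toe2_center=toe2_rc,
        heel_apex=heel_rc,
        AI_true=ai_true,
        AI_analytic=ai_analytic,
        AW_true=p.arch_width,
        AH_true=p.arch_height,
        mm_per_px=mm_per_px,
        params=p,
    )
    return frame, gt


# ---------------------------------------------------------------------------
# canonical fixtures


def preset_params(name: str, seed: int = 0,
                  frame_shape: tuple[int, int] = (300, 400),
                  **overrides) -> FootSceneParams:
    """Named scene presets at the canonical test raster (300x400)."""
    scale = frame_shape[1] / 640.0
    base = dict(frame_shape=frame_shape, focal_px=410.0 * scale, seed=seed)
    presets = {
        "flat": dict(arch_height=0.0, arch_width=0.0, gap_lift_mm=0.0,
                     depth_noise_sigma=0.0),
        "clean": dict(depth_noise_sigma=0.0),
        "noisy": dict(depth_noise_sigma=1.65),  # ~0.55 % of 300 mm
        "tilted": dict(plate_tilt=(4.0, 3.0), depth_noise_sigma=0.0),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}")
    return FootSceneParams(**{**base, **presets[name], **overrides})


PRESETS = ("flat", "clean", "noisy", "tilted")


def _scene_catalog(seed: int = 0) -> dict[str, FootSceneParams]:
    return {
        "flat": preset_params("flat", seed=seed),
        "clean_arched": preset_params("clean", seed=seed),
        "noisy_arched_a": preset_params("noisy", seed=seed + 1),
        "noisy_arched_b": preset_params("noisy", seed=seed + 2),
        "noisy_arched_c": preset_params("noisy", seed=seed + 3),
        "tilted_plate": preset_params("tilted", seed=seed),
        "all_background": None,  # handled specially below
    }


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical test fixtures and their ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "scenes": {}}
    for name, params in _scene_catalog(seed).items():
        entry: dict = {}
        if name == "all_background":
            shape = (300, 400)
            K = CameraIntrinsics(fx=256.25, fy=256.25, cx=199.5, cy=149.5,
                                 width=400, height=300)
            depth = np.full(shape, 700.0)
            color = np.full(shape + (3,), 70, dtype=np.uint8)
            frame = RGBDFrame(depth, color, K, K)
            entry["ground_truth"] = None
        else:
            frame, gt = generate_scene(params)
            entry["ground_truth"] = {
                "AI_true": gt.AI_true,
                "AI_analytic": gt.AI_analytic,
                "AW_true": gt.AW_true,
                "AH_true": gt.AH_true,
                "toe2_center": gt.toe2_center.tolist(),
                "heel_apex": gt.heel_apex.tolist(),
                "depth_noise_sigma": params.depth_noise_sigma,
            }
        depth_path = out / f"{name}_depth.png"
        color_path = out / f"{name}_color.png"
        calib_path = out / f"{name}_calib.json"
        save_frame(frame, depth_path, color_path, calib_path)
        entry["files"] = {
            "depth": depth_path.name,
            "color": color_path.name,
            "calib": calib_path.name,
        }
        entry["depth_mm_sha256"] = hashlib.sha256(
            np.round(frame.depth).astype(np.uint16).tobytes()).hexdigest()
        manifest["scenes"][name] = entry
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
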