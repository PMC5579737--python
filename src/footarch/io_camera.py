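"""Camera model, raster I/O and color-to-depth registration.

The measurement input is a registered RGB-D frame: a per-pixel depth raster in
millimetres (0 marks an invalid pixel) and an 8-bit RGB color raster, together
with pinhole intrinsics for both cameras and the rigid depth->color extrinsics.
Every valid depth pixel deprojects to a 3D point in the depth-camera frame and
carries the color sampled at its projection into the color camera, giving the
6D points (x, y, z, r, g, b) the rest of the pipeline consumes.

Conventions: 0-based pixel indices with u = column, v = row; camera frame
x-right, y-down, z-forward along the optical axis; all lengths in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "DepthToColorExtrinsics",
    "RGBDFrame",
    "FootPointCloud",
    "load_frame",
    "save_frame",
    "deproject",
    "project",
    "register_color",
]


class CalibrationError(ValueError):
    """Raised when a calibration file cannot be interpreted."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics; focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    distortion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the raster")


@dataclass(frozen=True)
class DepthToColorExtrinsics:
    """Rigid transform taking depth-camera points into the color camera."""

    rotation: np.ndarray  # 3x3 orthonormal, det +1
    translation: np.ndarray  # 3-vector, mm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "DepthToColorExtrinsics":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class RGBDFrame:
    """A registered depth (mm, 0 = invalid) + color raster pair."""

    depth: np.ndarray  # (H, W) float mm
    color: np.ndarray  # (H, W, 3) uint8
    intrinsics_depth: CameraIntrinsics
    intrinsics_color: CameraIntrinsics
    extrinsics: DepthToColorExtrinsics = field(
        default_factory=DepthToColorExtrinsics.identity
    )

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.color = np.asarray(self.color)
        if self.depth.shape != self.color.shape[:2]:
            raise ValueError("depth and color rasters must share dimensions")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")


@dataclass
class FootPointCloud:
    """Per-pixel 6D points (x, y, z, r, g, b) with a validity mask."""

    points: np.ndarray  # (H, W, 3) float mm, depth-camera frame
    colors: np.ndarray  # (H, W, 3) float in [0, 255]
    valid: np.ndarray  # (H, W) bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def valid_points(self) -> np.ndarray:
        return self.points[self.valid]


def _intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    try:
        return CameraIntrinsics(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
            distortion=tuple(d.get("distortion", ())),
        )
    except KeyError as exc:  # pragma: no cover - message detail only
        raise CalibrationError(f"missing intrinsics key: {exc}") from exc


def load_calibration(
    path: str | Path,
) -> tuple[CameraIntrinsics, CameraIntrinsics, DepthToColorExtrinsics]:
    """Parse a YAML/JSON calibration file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise CalibrationError(f"unparseable calibration file {path}") from exc
    if not isinstance(data, dict):
        raise CalibrationError(f"calibration file {path} is not a mapping")
    try:
        kd = _intrinsics_from_dict(data["intrinsics_depth"])
        kc = _intrinsics_from_dict(data["intrinsics_color"])
        ext = data.get("extrinsics")
        if ext is None:
            extr = DepthToColorExtrinsics.identity()
        else:
            extr = DepthToColorExtrinsics(
                np.asarray(ext["rotation"], dtype=float).reshape(3, 3),
                np.asarray(ext["translation"], dtype=float),
            )
    except (KeyError, ValueError) as exc:
        raise CalibrationError(f"bad calibration file {path}: {exc}") from exc
    return kd, kc, extr


def save_calibration(
    path: str | Path,
    intrinsics_depth: CameraIntrinsics,
    intrinsics_color: CameraIntrinsics,
    extrinsics: DepthToColorExtrinsics,
) -> None:
    def _k(k: CameraIntrinsics) -> dict:
        return {
            "fx": k.fx, "fy": k.fy, "cx": k.cx, "cy": k.cy,
            "width": k.width, "height": k.height,
            "distortion": list(k.distortion),
        }

    data = {
        "intrinsics_depth": _k(intrinsics_depth),
        "intrinsics_color": _k(intrinsics_color),
        "extrinsics": {
            "rotation": [float(x) for x in extrinsics.rotation.ravel()],
            "translation": [float(x) for x in extrinsics.translation],
        },
    }
    Path(path).write_text(json.dumps(data, indent=2))


def _read_depth(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        depth = np.load(path).astype(float)
    else:
        import imageio.v3 as iio

        depth = iio.imread(path).astype(float)
    if depth.ndim != 2:
        raise ValueError(f"depth raster {path} is not single-channel")
    return depth


def load_frame(
    depth_path: str | Path, color_path: str | Path, calib_path: str | Path
) -> RGBDFrame:
    """Load a frame from a depth raster, a color raster and a calibration file.

    Depth may be a 16-bit single-channel PNG (value = millimetres) or a ``.npy``
    float array in mm; color is an 8-bit RGB image.
    """
    import imageio.v3 as iio

    depth = _read_depth(Path(depth_path))
    color = iio.imread(color_path)
    if color.ndim != 3 or color.shape[2] < 3:
        raise ValueError(f"color raster {color_path} is not RGB")
    color = color[:, :, :3]
    kd, kc, ext = load_calibration(calib_path)
    if depth.shape != (kd.height, kd.width):
        raise ValueError(
            f"depth raster {depth.shape} does not match calibration "
            f"({kd.height}, {kd.width})"
        )
    return RGBDFrame(depth, color, kd, kc, ext)


def save_frame(frame: RGBDFrame, depth_path: str | Path,
               color_path: str | Path, calib_path: str | Path) -> None:
    """Write a frame back to disk (depth as 16-bit PNG mm, color 8-bit RGB)."""
    import imageio.v3 as iio

    iio.imwrite(depth_path, np.round(frame.depth).astype(np.uint16))
    iio.imwrite(color_path, frame.color.astype(np.uint8))
    save_calibration(calib_path, frame.intrinsics_depth,
                     frame.intrinsics_color, frame.extrinsics)


def deproject(depth: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Back-project a depth raster into per-pixel 3D points.

    For pixel (u, v) with depth z:  x = (u - cx) z / fx, y = (v - cy) z / fy.
    Pixels with z = 0 yield the origin and must be masked by the caller.
    """
    depth = np.asarray(depth, dtype=float)
    h, w = depth.shape
    u = np.arange(w, dtype=float)[None, :]
    v = np.arange(h, dtype=float)[:, None]
    x = (u - K.cx) * depth / K.fx
    y = (v - K.cy) * depth / K.fy
    return np.stack([x, y, depth], axis=-1)


def project(points: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of (..., 3) points to (..., 2) pixel coords (u, v)."""
    p = np.asarray(points, dtype=float)
    z = p[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = K.fx * p[..., 0] / z + K.cx
        v = K.fy * p[..., 1] / z + K.cy
    return np.stack([u, v], axis=-1)


def register_color(frame: RGBDFrame) -> FootPointCloud:
    """Map the color raster onto the depth raster to form 6D points.

    Each valid depth pixel is deprojected, transformed into the color camera
    and sampled with nearest-neighbour lookup; points that project outside the
    color raster become invalid.
    """
    pts = deproject(frame.depth, frame.intrinsics_depth)
    valid = frame.depth > 0
    R, t = frame.extrinsics.rotation, frame.extrinsics.translation
    pts_c = pts @ R.T + t
    uv = project(pts_c, frame.intrinsics_color)
    uv = np.nan_to_num(uv, nan=-1.0, posinf=-1.0, neginf=-1.0)
    u = np.round(uv[..., 0]).astype(int)
    v = np.round(uv[..., 1]).astype(int)
    kc = frame.intrinsics_color
    inside = (u >= 0) & (u < kc.width) & (v >= 0) & (v < kc.height)
    valid = valid & inside
    colors = np.zeros(pts.shape, dtype=float)
    colors[valid] = frame.color[v[valid], u[valid], :3]
    pts = pts.copy()
    pts[~valid] = 0.0
    return FootPointCloud(points=pts, colors=colors, valid=valid)
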