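"""Pinhole camera model and turntable projection geometry.

Conventions used throughout the package
---------------------------------------

* World coordinates are in millimetres. The origin is the tool center
  point (TCP); the rotation axis is the world ``y`` axis, pointing *up*,
  so a seed sitting on the tool tip occupies ``y > 0``.
* Image coordinates are 0-based pixels, ``x`` to the right, ``y``
  *downward*, with pixel centers at integer coordinates.
* A positive turntable angle rotates the object counter-clockwise when
  viewed from above.  The world frame rotates with the object, so each
  view ``i`` has its own projection matrix ``P_i = K (R_i | t_i)``.
* The camera sits on the optical axis at working distance ``d`` in front
  of the world origin; the translation is a pure ``z`` shift of
  magnitude ``d`` (lateral drift is handled later by shifting the
  principal point, not the translation).

Internally all projection arithmetic is done in pixel units; world
coordinates stay metric.  The mapping between image-plane millimetres and
pixels is the physical pixel pitch ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, GeometryError, ProjectionError

__all__ = [
    "Intrinsics",
    "AcquisitionGeometry",
    "ProjectionMatrix",
    "rotation_about_vertical",
    "build_projection",
    "project",
    "radius_from_mask_area",
    "working_distance_from_ball",
    "set_principal_point",
    "shift_principal_point",
    "load_calibration",
]

# Rotation by pi about the camera x axis: world y-up -> image y-down,
# world z toward the camera -> camera z away from it.  det = +1.
_FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics of the acquisition camera.

    Parameters
    ----------
    focal_length_px
        Focal length expressed in pixels (focal length on the image side
        divided by the pixel pitch).
    principal_point
        ``(cx, cy)`` in pixels, 0-based.
    pixel_size_mm
        Physical pixel pitch ``mu`` of the (square-pixel) sensor in mm.
    image_size
        ``(width, height)`` in pixels.
    """

    focal_length_px: float
    principal_point: tuple[float, float]
    pixel_size_mm: float
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.focal_length_px > 0:
            raise ConfigError("focal_length_px must be positive")
        if not self.pixel_size_mm > 0:
            raise ConfigError("pixel_size_mm must be positive")
        w, h = self.image_size
        cx, cy = self.principal_point
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise ConfigError(
                f"principal point {self.principal_point} outside image bounds "
                f"{self.image_size}"
            )

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 intrinsic matrix ``K`` (pixel units, y down)."""
        cx, cy = self.principal_point
        f = self.focal_length_px
        return np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Turntable acquisition: working distance and rotation angles."""

    working_distance_mm: float
    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.working_distance_mm > 0:
            raise GeometryError("working distance must be positive")
        if len(self.angles_deg) < 1:
            raise ConfigError("at least one rotation angle is required")
        object.__setattr__(
            self, "angles_deg", tuple(float(a) % 360.0 for a in self.angles_deg)
        )

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    @classmethod
    def equal_steps(cls, n_views: int, working_distance_mm: float,
                    start_deg: float = 0.0) -> "AcquisitionGeometry":
        """``n_views`` equally spaced angles covering a full turn."""
        step = 360.0 / n_views
        return cls(working_distance_mm,
                   tuple(start_deg + i * step for i in range(n_views)))


@dataclass(frozen=True)
class ProjectionMatrix:
    """Homogeneous 3x4 projection ``P = K (R | t)`` for one view.

    The current principal point is carried along so that pose
    corrections can replace or shift it without re-deriving it from the
    matrix.
    """

    matrix: np.ndarray
    view_index: int = 0
    principal_point: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4):
            raise GeometryError("projection matrix must be 3x4")
        if abs(np.linalg.det(m[:, :3])) < 1e-12:
            raise GeometryError("left 3x3 block of projection is singular")
        object.__setattr__(self, "matrix", m)


def rotation_about_vertical(alpha_deg: float) -> np.ndarray:
    """Proper rotation by ``alpha_deg`` about the vertical world y axis.

    Positive angles rotate the object counter-clockwise seen from above.
    """
    a = np.deg2rad(alpha_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def build_projection(intr: Intrinsics, alpha_deg: float, d_mm: float,
                     view_index: int = 0) -> ProjectionMatrix:
    """Projection matrix for one turntable view.

    The world origin (the TCP) is placed on the optical axis at distance
    ``d_mm`` in front of the camera center, so it projects exactly to the
    principal point for every rotation angle.
    """
    if not d_mm > 0:
        raise GeometryError(f"working distance must be positive, got {d_mm}")
    r = _FLIP @ rotation_about_vertical(alpha_deg)
    rt = np.hstack([r, np.array([[0.0], [0.0], [d_mm]])])
    return ProjectionMatrix(intr.matrix @ rt, view_index=view_index,
                            principal_point=intr.principal_point)


def project(p: ProjectionMatrix, x) -> np.ndarray:
    """Project homogeneous world point(s) to pixel coordinates.

    ``x`` is a length-4 vector or an ``(n, 4)`` array.  Returns ``(2,)``
    or ``(n, 2)`` dehomogenized pixel coordinates ``(x, y)``.
    """
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    if pts.shape[-1] != 4:
        raise ProjectionError("points must be homogeneous (length 4)")
    h = pts @ p.matrix.T
    w = h[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ProjectionError("point projects to infinity (w = 0)")
    uv = h[:, :2] / w[:, None]
    return uv[0] if np.asarray(x).ndim == 1 else uv


def radius_from_mask_area(area_px: float, mu_mm: float) -> float:
    """Radius (mm) of the circle with the same area as a silhouette.

    ``r = mu * sqrt(A / pi)`` converts a foreground pixel count ``A``
    into the metric radius of the equal-area circle on the sensor.
    """
    if not area_px > 0:
        raise ConfigError(f"mask area must be positive, got {area_px}")
    return mu_mm * float(np.sqrt(area_px / np.pi))


def working_distance_from_ball(r_img_mm: float, r0_mm: float,
                               f_mm: float) -> float:
    """Working distance from the imaged radius of a calibration ball.

    Given the metric image radius ``r`` of a ball of physical radius
    ``r0`` and the (image-side) focal length ``f``, basic tangent-ray
    geometry gives ``d = sqrt(f^2 + r^2) * r0 / r``.
    """
    if not (r_img_mm > 0 and r0_mm > 0 and f_mm > 0):
        raise ConfigError("ball radii and focal length must be positive")
    return float(np.sqrt(f_mm**2 + r_img_mm**2) * r0_mm / r_img_mm)


def projected_ball_radius_px(r0_mm: float, d_mm: float,
                             f_px: float) -> float:
    """Exact silhouette radius (px) of a centred ball at distance ``d``.

    The silhouette of a sphere is bounded by the tangent rays, so its
    image radius is ``f * r0 / sqrt(d^2 - r0^2)``, slightly larger than
    the naive ``f * r0 / d``.
    """
    if not d_mm > r0_mm:
        raise GeometryError("camera must be outside the ball (d > r0)")
    return float(f_px * r0_mm / np.sqrt(d_mm**2 - r0_mm**2))


def set_principal_point(p: ProjectionMatrix,
                        tcp_px: Sequence[float],
                        image_size: tuple[int, int] | None = None,
                        ) -> ProjectionMatrix:
    """Return a copy of ``p`` with its principal point moved to ``tcp_px``.

    Because ``K`` enters ``P`` linearly, replacing ``(cx, cy)`` by
    ``(cx', cy')`` adds ``(cx'-cx)``/``(cy'-cy)`` times the third row of
    ``P`` to its first/second row.  Afterwards the world origin projects
    exactly to ``tcp_px``.
    """
    tx, ty = float(tcp_px[0]), float(tcp_px[1])
    if image_size is not None:
        w, h = image_size
        if not (0 <= tx <= w - 1 and 0 <= ty <= h - 1):
            import warnings

            warnings.warn(
                f"TCP {tcp_px} lies outside the image bounds {image_size}",
                stacklevel=2,
            )
    dx = tx - p.principal_point[0]
    dy = ty - p.principal_point[1]
    m = p.matrix.copy()
    m[0] += dx * m[2]
    m[1] += dy * m[2]
    return replace(p, matrix=m, principal_point=(tx, ty))


def shift_principal_point(p: ProjectionMatrix,
                          delta_px: Sequence[float]) -> ProjectionMatrix:
    """Shift the principal point of ``p`` by ``(dx, dy)`` pixels."""
    cx, cy = p.principal_point
    return set_principal_point(p, (cx + float(delta_px[0]),
                                   cy + float(delta_px[1])))


def load_calibration(path: str | Path
                     ) -> tuple[Intrinsics, AcquisitionGeometry]:
    """Load a YAML/JSON calibration file.

    Expected keys: ``focal_length_px``, ``pixel_size_mm``,
    ``principal_point``, ``image_size``, ``working_distance_mm`` and
    either an explicit ``angles_deg`` list or
    ``angles: {start, step, count}``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"calibration file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"calibration file {path} is not a mapping")
    try:
        intr = Intrinsics(
            focal_length_px=float(cfg["focal_length_px"]),
            principal_point=tuple(float(v) for v in cfg["principal_point"]),
            pixel_size_mm=float(cfg["pixel_size_mm"]),
            image_size=tuple(int(v) for v in cfg["image_size"]),
        )
        d = float(cfg["working_distance_mm"])
        if "angles_deg" in cfg:
            geom = AcquisitionGeometry(d, tuple(float(a)
                                                for a in cfg["angles_deg"]))
        else:
            spec = cfg["angles"]
            start = float(spec.get("start", 0.0))
            step = float(spec["step"])
            count = int(spec["count"])
            geom = AcquisitionGeometry(
                d, tuple(start + i * step for i in range(count)))
    except KeyError as exc:
        raise ConfigError(f"calibration file {path} misses key {exc}") from exc
    return intr, geom
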