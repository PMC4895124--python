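"""Synthetic silhouette stacks with exact ground truth.

Renders gray-value image stacks of analytic scenes — a sphere,
ellipsoid or superellipsoid "seed", optionally held on a truncated-cone
tool — under exactly the central-projection turntable model used for
carving.  Silhouettes are rasterized by supersampled ray tests against
the analytic surfaces and thresholded at 50% pixel coverage, so edge
placement is sub-pixel accurate.  Optional per-view TCP jitter emulates
the small elliptic drift of the physical tool tip (x follows a cosine,
y a sine of the rotation angle), and a simple noise model (salt
speckles, interior holes) exercises segmentation cleanup.

Every stack comes with its ground truth: the analytic object volume and
the true per-view TCP pixel location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import beta as beta_fn

from .camera import Intrinsics, rotation_about_vertical
from .carving import ToolModel
from .errors import RenderError

__all__ = [
    "SphereSpec",
    "EllipsoidSpec",
    "SuperellipsoidSpec",
    "JitterSpec",
    "NoiseSpec",
    "SceneSpec",
    "GroundTruth",
    "render_stack",
    "make_bearing_ball_stack",
    "masks_from_stack",
]

_FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class SphereSpec:
    radius_mm: float
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3

    @property
    def bound_radius_mm(self) -> float:
        return self.radius_mm


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid with semi-axes ``(a, b, c)`` (x, y, z)."""

    semi_axes_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def bound_radius_mm(self) -> float:
        return max(self.semi_axes_mm)


@dataclass(frozen=True)
class SuperellipsoidSpec:
    """Superellipsoid seed shape with vertical (y) as the polar axis.

    Exponents ``eps1`` (polar) and ``eps2`` (equatorial) interpolate
    between ellipsoid (1, 1) and box-like (-> 0) shapes.
    """

    semi_axes_mm: tuple[float, float, float]
    eps1: float = 1.0
    eps2: float = 1.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        e1, e2 = self.eps1, self.eps2
        return (2.0 * a * b * c * e1 * e2
                * beta_fn(e1 / 2.0 + 1.0, e1)
                * beta_fn(e2 / 2.0, e2 / 2.0))

    @property
    def bound_radius_mm(self) -> float:
        return float(np.sqrt(3.0) * max(self.semi_axes_mm))

    def inside(self, pts: np.ndarray) -> np.ndarray:
        """Inside-outside test in the object frame (y = polar axis)."""
        a, b, c = self.semi_axes_mm
        x = np.abs(pts[..., 0] / a)
        y = np.abs(pts[..., 1] / b)
        z = np.abs(pts[..., 2] / c)
        eq = (x ** (2.0 / self.eps2) + z ** (2.0 / self.eps2))
        return eq ** (self.eps2 / self.eps1) + y ** (2.0 / self.eps1) <= 1.0


@dataclass(frozen=True)
class JitterSpec:
    """Per-view TCP drift in pixels over the rotation angle.

    Models the elliptic trajectory of the physical tool tip:
    ``dx = ellipse_amp_x * cos(alpha + phase)``,
    ``dy = sine_amp_y * sin(alpha + phase)``.
    """

    ellipse_amp_x_px: float = 0.0
    sine_amp_y_px: float = 0.0
    phase_deg: float = 0.0

    def offsets(self, angles_deg) -> np.ndarray:
        a = np.deg2rad(np.asarray(angles_deg, dtype=float)
                       + self.phase_deg)
        return np.column_stack([self.ellipse_amp_x_px * np.cos(a),
                                self.sine_amp_y_px * np.sin(a)])


@dataclass(frozen=True)
class NoiseSpec:
    """Salt speckles in the background, pinholes in the foreground."""

    speckle_density: float = 0.0
    hole_density: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic acquisition."""

    objects: tuple
    intrinsics: Intrinsics
    d_mm: float
    angles_deg: tuple[float, ...]
    tool: ToolModel | None = None
    jitter: JitterSpec = field(default_factory=JitterSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    gray_levels: tuple[int, int] = (40, 220)  # (foreground, background)
    supersample: int = 4


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth accompanying a rendered stack."""

    true_volume_mm3: float
    tcp_px: np.ndarray  # (n_views, 2): true TCP pixel location per view
    description: dict


def _ray_hits_sphere(d_dir: np.ndarray, center: np.ndarray,
                     radius: float) -> np.ndarray:
    proj = d_dir @ center
    dd = np.einsum("ij,ij->i", d_dir, d_dir)
    dist2 = center @ center - proj * proj / dd
    return (proj > 0) & (dist2 <= radius * radius)


def _ray_hits_ellipsoid(d_dir: np.ndarray, rot: np.ndarray,
                        center: np.ndarray, semi_axes) -> np.ndarray:
    inv = np.asarray(semi_axes, dtype=float)
    o = (rot.T @ (-center)) / inv
    dd = (d_dir @ rot) / inv
    ddd = np.einsum("ij,ij->i", dd, dd)
    od = dd @ o
    dist2 = o @ o - od * od / ddd
    return (od < 0) & (dist2 <= 1.0)


def _ray_hits_superellipsoid(d_dir: np.ndarray, rot: np.ndarray,
                             center: np.ndarray, spec: SuperellipsoidSpec,
                             n_steps: int = 96) -> np.ndarray:
    # march samples along each ray inside the object's bounding sphere
    o = rot.T @ (-center)
    dd = d_dir @ rot
    rb = spec.bound_radius_mm
    ddd = np.einsum("ij,ij->i", dd, dd)
    tmid = -(dd @ o) / ddd
    half = rb / np.sqrt(ddd)
    hits = np.zeros(len(d_dir), dtype=bool)
    cand = tmid > 0
    if not cand.any():
        return hits
    t0 = (tmid - half)[cand]
    dt = (2.0 * half)[cand] / n_steps
    dc = dd[cand]
    inside = np.zeros(cand.sum(), dtype=bool)
    for k in range(n_steps + 1):
        t = t0 + k * dt
        pts = o[None, :] + t[:, None] * dc
        inside |= spec.inside(pts)
    hits[cand] = inside
    return hits


def _ray_hits_cone(d_dir: np.ndarray, rot_cam: np.ndarray, d_mm: float,
                   tool: ToolModel, y_floor_mm: float) -> np.ndarray:
    """Hit test against the (infinite, downward) tool cone.

    The cone apex is the virtual point above the tip where the radius
    profile reaches zero; hits are restricted to world heights between
    ``y_floor_mm`` (bottom of the visible field) and the tip.
    """
    slope = tool.slope
    y_apex = tool.tip_y_mm + tool.tip_radius_mm / slope
    apex_w = np.array([0.0, y_apex, 0.0])
    apex = rot_cam @ apex_w + np.array([0.0, 0.0, d_mm])
    w_axis = rot_cam @ np.array([0.0, -1.0, 0.0])  # down the tool
    c2 = 1.0 / (1.0 + slope * slope)  # cos^2 of the cone half-angle

    qw = d_dir @ w_axis
    qq = np.einsum("ij,ij->i", d_dir, d_dir)
    aw = apex @ w_axis
    qa = d_dir @ apex
    a2 = qw * qw - c2 * qq
    a1 = -qw * aw + c2 * qa
    a0 = aw * aw - c2 * (apex @ apex)
    disc = a1 * a1 - a2 * a0

    hits = np.zeros(len(d_dir), dtype=bool)
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        for sign in (-1.0, 1.0):
            t = (-a1 + sign * sq) / a2
            valid = ok & np.isfinite(t) & (t > 0)
            pt = t[:, None] * d_dir
            v = pt - apex
            y_world = (rot_cam.T @ (pt - np.array([0.0, 0.0, d_mm])).T).T[:, 1]
            nappe = (v @ w_axis) >= 0
            hits |= valid & nappe & (y_world <= tool.tip_y_mm) & (
                y_world >= y_floor_mm)
    return hits


def _render_view(spec: SceneSpec, alpha_deg: float,
                 pp: tuple[float, float]) -> np.ndarray:
    """Binary silhouette of one view by supersampled ray casting."""
    w, h = spec.intrinsics.image_size
    f = spec.intrinsics.focal_length_px
    cx, cy = pp
    rot = _FLIP @ rotation_about_vertical(alpha_deg)
    t = np.array([0.0, 0.0, spec.d_mm])

    # conservative pixel bounding box from object bounding spheres
    r0c, r1c = h, -1
    c0c, c1c = w, -1
    for obj in spec.objects:
        center_cam = rot @ np.asarray(obj.center_mm) + t
        rb = obj.bound_radius_mm
        z = center_cam[2]
        if z - rb <= 0:
            raise RenderError("object reaches the camera plane")
        u = cx + f * center_cam[0] / z
        v = cy + f * center_cam[1] / z
        rad = f * rb / (z - rb) + 2.0
        if (u - rad < -0.5 or u + rad > w - 0.5
                or v - rad < -0.5 or v + rad > h - 0.5):
            raise RenderError("object projects outside the image")
        r0c = min(r0c, int(np.floor(v - rad)))
        r1c = max(r1c, int(np.ceil(v + rad)))
        c0c = min(c0c, int(np.floor(u - rad)))
        c1c = max(c1c, int(np.ceil(u + rad)))

    y_floor = 0.0
    if spec.tool is not None:
        # tool occupies rows from just above its tip down to the border
        tip_cam = rot @ np.array([0.0, spec.tool.tip_y_mm, 0.0]) + t
        v_tip = cy + f * tip_cam[1] / tip_cam[2]
        y_floor = -(h - 1 + 1 - cy) * spec.d_mm / f  # world y at the border
        r_bot = spec.tool.radius_at(y_floor)
        half_px = f * r_bot / max(spec.d_mm - r_bot, 1e-6) + 2.0
        r0c = min(r0c, int(np.floor(v_tip - 2)))
        r1c = h - 1
        c0c = min(c0c, int(np.floor(cx - half_px)))
        c1c = max(c1c, int(np.ceil(cx + half_px)))
    if r1c < r0c:
        raise RenderError("scene is empty")
    r0c, c0c = max(r0c, 0), max(c0c, 0)
    r1c, c1c = min(r1c, h - 1), min(c1c, w - 1)

    ss = spec.supersample
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    rows = np.arange(r0c, r1c + 1)
    cols = np.arange(c0c, c1c + 1)
    cover = np.zeros((rows.size, cols.size), dtype=np.uint16)
    for dv in sub:
        for du in sub:
            uu, vv = np.meshgrid(cols + du, rows + dv)
            d_dir = np.column_stack([
                (uu.ravel() - cx) / f,
                (vv.ravel() - cy) / f,
                np.ones(uu.size),
            ])
            hit = np.zeros(len(d_dir), dtype=bool)
            for obj in spec.objects:
                center_cam = rot @ np.asarray(obj.center_mm) + t
                if isinstance(obj, SphereSpec):
                    hit |= _ray_hits_sphere(d_dir, center_cam,
                                            obj.radius_mm)
                elif isinstance(obj, EllipsoidSpec):
                    hit |= _ray_hits_ellipsoid(d_dir, rot, center_cam,
                                               obj.semi_axes_mm)
                elif isinstance(obj, SuperellipsoidSpec):
                    hit |= _ray_hits_superellipsoid(d_dir, rot,
                                                    center_cam, obj)
                else:
                    raise RenderError(f"unknown object type {type(obj)}")
            if spec.tool is not None:
                hit |= _ray_hits_cone(d_dir, rot, spec.d_mm, spec.tool,
                                      y_floor)
            cover += hit.reshape(cover.shape)

    mask = np.zeros((h, w), dtype=bool)
    mask[r0c:r1c + 1, c0c:c1c + 1] = cover * 2 >= ss * ss
    return mask


def _is_rotation_invariant(spec: SceneSpec) -> bool:
    """True if every view would render identically (no need to re-render)."""
    if (spec.jitter.ellipse_amp_x_px != 0 or spec.jitter.sine_amp_y_px != 0
            or spec.noise.speckle_density > 0 or spec.noise.hole_density > 0):
        return False
    for obj in spec.objects:
        on_axis = obj.center_mm[0] == 0.0 and obj.center_mm[2] == 0.0
        if isinstance(obj, SphereSpec) and on_axis:
            continue
        return False
    return True  # the tool is rotationally symmetric by construction


def render_stack(spec: SceneSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Render all views of a scene; returns gray images and ground truth."""
    fg, bg = spec.gray_levels
    offsets = spec.jitter.offsets(spec.angles_deg)
    cx, cy = spec.intrinsics.principal_point
    tcp = offsets + np.array([cx, cy])
    rng = np.random.default_rng(spec.noise.seed)

    images: list[np.ndarray] = []
    reuse = _is_rotation_invariant(spec)
    cached = None
    for i, alpha in enumerate(spec.angles_deg):
        if reuse and cached is not None:
            mask = cached
        else:
            mask = _render_view(spec, alpha, tuple(tcp[i]))
            if reuse:
                cached = mask
        img = np.where(mask, np.uint8(fg), np.uint8(bg))
        if spec.noise.speckle_density > 0:
            speck = (rng.random(img.shape) < spec.noise.speckle_density)
            img[speck & ~mask] = fg
        if spec.noise.hole_density > 0:
            holes = (rng.random(img.shape) < spec.noise.hole_density)
            img[holes & mask] = bg
        images.append(img)

    truth = GroundTruth(
        true_volume_mm3=float(sum(o.volume_mm3 for o in spec.objects)),
        tcp_px=tcp,
        description={
            "objects": [repr(o) for o in spec.objects],
            "tool": repr(spec.tool) if spec.tool is not None else None,
            "d_mm": spec.d_mm,
            "angles_deg": list(spec.angles_deg),
        },
    )
    return images, truth


def bearing_ball_intrinsics(image_size: tuple[int, int] = (2448, 2048),
                            pixel_size_mm: float = 0.00345,
                            d_mm: float = 69.9) -> Intrinsics:
    """Intrinsics of the production sensor at 1:1 magnification.

    2448 x 2048 square pixels of 3.45 um; the focal length in pixels is
    chosen so one sensor pixel sees exactly one pixel pitch at the
    working distance (the macro configuration of the rig).
    """
    w, h = image_size
    return Intrinsics(
        focal_length_px=d_mm / pixel_size_mm,
        principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
        pixel_size_mm=pixel_size_mm,
        image_size=image_size,
    )


def make_bearing_ball_stack(n_views: int = 36, d_mm: float = 69.9,
                            r0_mm: float = 1.5,
                            image_size: tuple[int, int] = (2448, 2048),
                            jitter: JitterSpec | None = None,
                            ) -> tuple[list[np.ndarray], GroundTruth,
                                       SceneSpec]:
    """Convenience preset: the 3.00 mm calibration bearing ball.

    A sphere of radius ``r0`` centred on the TCP, no tool, rendered for
    ``n_views`` equal turntable steps at the production working
    distance.  The true volume of the r0 = 1.5 mm ball is 14.137 mm^3.
    """
    if n_views < 2:
        raise RenderError("need at least two views")
    spec = SceneSpec(
        objects=(SphereSpec(radius_mm=r0_mm),),
        intrinsics=bearing_ball_intrinsics(image_size=image_size,
                                           d_mm=d_mm),
        d_mm=d_mm,
        angles_deg=tuple(i * 360.0 / n_views for i in range(n_views)),
        jitter=jitter if jitter is not None else JitterSpec(),
    )
    images, truth = render_stack(spec)
    return images, truth, spec


def masks_from_stack(images, spec: SceneSpec) -> list[np.ndarray]:
    """Binary masks from a rendered stack (threshold between fg and bg)."""
    fg, bg = spec.gray_levels
    thr = (int(fg) + int(bg)) / 2.0
    if fg < bg:
        return [np.asarray(im) < thr for im in images]
    return [np.asarray(im) > thr for im in images]
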