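"""Voxel volume carving, tool removal, surface extraction and QC.

The carved object is represented on an equidistant cubic ``R x R x R``
occupancy grid around the world origin (the TCP).  A voxel survives
carving iff its *center* projects into the silhouette foreground of
every view; voxel *corners* are only used when back-projecting the
reconstruction for quality control, mirroring how the acquisition
treats masks as binary indicator images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from skimage import draw, measure

from .camera import ProjectionMatrix, shift_principal_point
from .errors import (
    EmptyMaskError,
    EmptyVolumeError,
    FitFailureError,
    GeometryError,
)
from .silhouette import center_of_mass

__all__ = [
    "VoxelGrid",
    "ToolModel",
    "carve",
    "volume",
    "extract_surface",
    "remove_tool_known",
    "remove_tool_fit",
    "backproject",
    "overlap_ratio",
    "dice",
    "refine_poses",
]


@dataclass
class VoxelGrid:
    """Cubic binary occupancy grid, indexed ``[ix, iy, iz]``.

    ``origin_mode`` places the TCP either at the center of the grid's
    bottom face (``"bottom"``, small seeds: the seed occupies the
    ``y > 0`` half-space and the tool is never reconstructed) or at the
    grid center (``"center"``, when seed and tool may overlap).
    """

    resolution: int
    voxel_size_mm: float
    origin_mode: str = "center"
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise GeometryError("grid resolution must be >= 2")
        if not self.voxel_size_mm > 0:
            raise GeometryError("voxel size must be positive")
        if self.origin_mode not in ("center", "bottom"):
            raise GeometryError("origin_mode must be 'center' or 'bottom'")
        r = self.resolution
        if self.occupancy is None:
            self.occupancy = np.ones((r, r, r), dtype=bool)
        elif self.occupancy.shape != (r, r, r):
            raise GeometryError("occupancy shape does not match resolution")

    @classmethod
    def for_working_volume(cls, side_mm: float, resolution: int,
                           origin_mode: str = "center") -> "VoxelGrid":
        """Full grid covering a cubic working volume of ``side_mm``."""
        return cls(resolution, side_mm / resolution, origin_mode)

    @property
    def working_side_mm(self) -> float:
        return self.resolution * self.voxel_size_mm

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centers along each axis."""
        r, s = self.resolution, self.voxel_size_mm
        half = (np.arange(r) + 0.5 - r / 2.0) * s
        xs = half
        zs = half
        ys = (np.arange(r) + 0.5) * s if self.origin_mode == "bottom" else half
        return xs, ys, zs

    def copy(self) -> "VoxelGrid":
        return replace(self, occupancy=self.occupancy.copy())


@dataclass(frozen=True)
class ToolModel:
    """Truncated-cone model of the seed-holding vacuum nozzle.

    The cone axis is the vertical world axis through the TCP.  The tip
    sits at ``tip_y_mm`` (0 = at the TCP) with ``tip_radius_mm``; the
    radius grows linearly downward, reaching ``base_radius_mm`` at
    ``base_y_mm``, and the same slope is extrapolated further down (the
    physical tool continues below the working volume).
    """

    tip_radius_mm: float
    base_radius_mm: float
    tip_y_mm: float = 0.0
    base_y_mm: float = -1.0

    def __post_init__(self) -> None:
        if not 0 < self.tip_radius_mm < self.base_radius_mm:
            raise GeometryError("require 0 < tip radius < base radius")
        if not self.base_y_mm < self.tip_y_mm:
            raise GeometryError("tool base must lie below its tip")

    @property
    def slope(self) -> float:
        """Radius increase per mm measured downward from the tip."""
        return (self.base_radius_mm - self.tip_radius_mm) / (
            self.tip_y_mm - self.base_y_mm)

    def radius_at(self, y_mm) -> np.ndarray:
        """Tool radius at height ``y`` (only meaningful for y <= tip)."""
        return self.tip_radius_mm + self.slope * (self.tip_y_mm
                                                  - np.asarray(y_mm))


def carve(grid: VoxelGrid, masks, projections) -> VoxelGrid:
    """Carve the occupancy grid against a stack of silhouette masks.

    Implements the silhouette-consistency product: a voxel stays
    occupied iff its center projects to foreground in *every* mask.
    Projections falling outside an image count as background.  An empty
    input mask or an empty result raises instead of silently erasing
    the volume — both always indicate a segmentation or pose failure.
    """
    if len(masks) != len(projections) or len(masks) == 0:
        raise EmptyMaskError("need equally many masks and projections (>= 1)")
    for i, m in enumerate(masks):
        if not np.asarray(m).any():
            raise EmptyMaskError(f"mask {i} is empty; refusing to carve")
    out = grid.copy()
    occ = out.occupancy
    xs, ys, zs = grid.axis_coords()
    for mask, proj in zip(masks, projections):
        mask = np.asarray(mask)
        h, w = mask.shape
        p = proj.matrix
        # decompose P*(x,y,z,1) into per-axis contributions
        ax = p[:, 0:1] * xs[None, :]          # (3, R)
        ay = p[:, 1:2] * ys[None, :] + p[:, 3:4]
        az = p[:, 2:3] * zs[None, :]
        for iy in range(grid.resolution):
            slab = occ[:, iy, :]
            if not slab.any():
                continue
            num_x = ax[0][:, None] + az[0][None, :] + ay[0, iy]
            num_y = ax[1][:, None] + az[1][None, :] + ay[1, iy]
            den = ax[2][:, None] + az[2][None, :] + ay[2, iy]
            u = np.rint(num_x / den).astype(np.intp)
            v = np.rint(num_y / den).astype(np.intp)
            inb = (u >= 0) & (u < w) & (v >= 0) & (v < h)
            np.clip(u, 0, w - 1, out=u)
            np.clip(v, 0, h - 1, out=v)
            slab &= inb & mask[v, u]
    if not occ.any():
        raise EmptyVolumeError(
            "carving erased the whole volume; check masks and poses")
    return out


def volume(grid: VoxelGrid) -> float:
    """Object volume in mm^3 (occupied-voxel count times voxel volume)."""
    return float(grid.occupancy.sum()) * grid.voxel_size_mm**3


def surface_voxels(grid: VoxelGrid) -> np.ndarray:
    """Boolean array marking occupied voxels with an exposed face."""
    eroded = ndimage.binary_erosion(grid.occupancy,
                                    structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    return grid.occupancy & ~eroded


def extract_surface(grid: VoxelGrid) -> trimesh.Trimesh:
    """Triangle mesh of the 0.5-level set of the occupancy grid.

    The grid is zero-padded by one voxel so that the isosurface closes
    around occupancy touching the grid boundary; for a single connected
    component the result is watertight.
    """
    if not grid.occupancy.any():
        raise EmptyVolumeError("cannot mesh an empty grid")
    s = grid.voxel_size_mm
    padded = np.pad(grid.occupancy.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=(s, s, s))
    xs, ys, zs = grid.axis_coords()
    # padded index 1 is grid index 0, whose center sits at axis_coords[0]
    origin = np.array([xs[0] - s, ys[0] - s, zs[0] - s])
    mesh = trimesh.Trimesh(vertices=verts + origin, faces=faces,
                           process=False)
    if mesh.volume < 0:  # orient faces outward
        mesh.invert()
    return mesh


def remove_tool_known(grid: VoxelGrid, tool: ToolModel,
                      mode: str = "cone",
                      dilate_voxels: float = 1.0) -> VoxelGrid:
    """Delete the tool from a carved grid using its known geometry.

    ``mode="cone"`` removes voxel centers inside the truncated cone,
    inflated by ``dilate_voxels`` voxel widths to absorb digitization
    (avoiding a residual one-voxel shell around the tool).
    ``mode="plane"`` implements the small-seed shortcut: everything at
    or below the tool tip plane is discarded.
    """
    out = grid.copy()
    xs, ys, zs = grid.axis_coords()
    below = ys <= tool.tip_y_mm
    if mode == "plane":
        out.occupancy[:, below, :] = False
        return out
    if mode != "cone":
        raise GeometryError("tool removal mode must be 'cone' or 'plane'")
    if not below.any():
        return out
    rad_xz = np.hypot(xs[:, None], zs[None, :])  # (R, R) distance to axis
    margin = dilate_voxels * grid.voxel_size_mm
    for iy in np.nonzero(below)[0]:
        inside = rad_xz <= tool.radius_at(ys[iy]) + margin
        out.occupancy[:, iy, :][inside] = False
    return out


def remove_tool_fit(grid: VoxelGrid,
                    bottom_frac: float = 0.25,
                    tip_radius_mm: float = 0.0,
                    dilate_voxels: float = 1.0,
                    ) -> tuple[VoxelGrid, ToolModel]:
    """Estimate and delete the tool cone from the reconstruction itself.

    Summing voxels of horizontal planes in the bottom region of the
    grid measures the area of horizontal cuts through the tool.  Planes
    are deleted from the bottom up while these areas keep shrinking
    (pure tool); once they stop shrinking (the seed starts
    contributing) the cone's radius profile ``rho(y)`` is fit by least
    squares to the deleted areas via ``area = pi rho^2`` and the
    extrapolated cone — up to where its radius falls to
    ``tip_radius_mm`` — is removed from the remaining volume.
    """
    occ = grid.occupancy
    xs, ys, zs = grid.axis_coords()
    n_bottom = max(int(round(grid.resolution * bottom_frac)), 3)
    areas = occ[:, :n_bottom, :].sum(axis=(0, 2))
    occupied = np.nonzero(areas > 0)[0]
    if occupied.size == 0:
        raise FitFailureError("bottom region of the grid is empty")
    j = int(occupied[0])
    deleted: list[int] = [j]
    while j + 1 < n_bottom and 0 < areas[j + 1] <= areas[j]:
        j += 1
        deleted.append(j)
    if len(deleted) < 3 or areas[deleted[-1]] >= areas[deleted[0]]:
        raise FitFailureError(
            "tool cross-section areas never decrease; no tool to fit")

    s = grid.voxel_size_mm
    y_fit = ys[deleted]
    rho_fit = np.sqrt(areas[deleted] * s * s / np.pi)
    coef = np.polynomial.polynomial.polyfit(y_fit, rho_fit, 1)
    c0, c1 = float(coef[0]), float(coef[1])
    if c1 >= 0:
        raise FitFailureError("fitted tool radius does not shrink upward")
    tip_y = (tip_radius_mm - c0) / c1

    out = grid.copy()
    out.occupancy[:, deleted, :] = False
    rad_xz = np.hypot(xs[:, None], zs[None, :])
    margin = dilate_voxels * s
    for iy in range(deleted[-1] + 1, grid.resolution):
        if ys[iy] > tip_y:
            break
        rho = c0 + c1 * ys[iy]
        out.occupancy[:, iy, :][rad_xz <= rho + margin] = False

    base_y = float(y_fit[0])
    fitted = ToolModel(
        tip_radius_mm=max(tip_radius_mm, 1e-9),
        base_radius_mm=max(c0 + c1 * base_y, 2e-9),
        tip_y_mm=tip_y,
        base_y_mm=base_y if base_y < tip_y else tip_y - 1e-9,
    )
    return out, fitted


def _hull_order(points: np.ndarray) -> np.ndarray:
    """Order projected corner points counter-clockwise around their mean."""
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    return points[np.argsort(ang)]


def backproject(grid: VoxelGrid, proj: ProjectionMatrix,
                image_size: tuple[int, int]) -> np.ndarray:
    """Render the reconstruction back into one view as a mask.

    Every surface voxel's eight corners are projected and the convex
    hull of the projected points is filled.  Sub-pixel effects of the
    hull filling may leave the result slightly dilated with respect to
    the original segmentation mask.
    """
    w, h = image_size
    out = np.zeros((h, w), dtype=bool)
    surf = np.argwhere(surface_voxels(grid))
    if surf.size == 0:
        return out
    xs, ys, zs = grid.axis_coords()
    s = grid.voxel_size_mm
    centers = np.column_stack([xs[surf[:, 0]], ys[surf[:, 1]],
                               zs[surf[:, 2]]])
    offs = np.array([[sx, sy, sz] for sx in (-0.5, 0.5)
                     for sy in (-0.5, 0.5) for sz in (-0.5, 0.5)]) * s
    corners = centers[:, None, :] + offs[None, :, :]      # (n, 8, 3)
    hom = np.concatenate([corners, np.ones_like(corners[..., :1])], axis=-1)
    pix = hom @ proj.matrix.T
    uv = pix[..., :2] / pix[..., 2:3]                     # (n, 8, 2)
    for quad in uv:
        poly = _hull_order(quad)
        rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=out.shape)
        out[rr, cc] = True
    return out


def overlap_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two masks; 1 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two masks; 1 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("mask shapes differ")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def refine_poses(grid: VoxelGrid, masks, projections,
                 max_iter: int = 10,
                 min_improvement: float = 1e-3,
                 ) -> tuple[list[ProjectionMatrix], VoxelGrid, pd.DataFrame]:
    """Iterative recenter-and-recarve camera pose refinement.

    Each iteration (1) shifts every view's principal point so the
    center of mass of the back-projected reconstruction coincides with
    the center of mass of the segmentation mask, and (2) recarves the
    full grid with the corrected projections.  Iterations are accepted
    while the mean overlap ratio improves by at least
    ``min_improvement``; if a recarve empties the grid the last valid
    state is returned.

    Returns the refined projections, the final carved grid, and a
    per-view QC report (iteration, view, overlap, dice, applied shift).
    """
    if not grid.occupancy.any():
        raise EmptyVolumeError("initial carve is empty")
    image_size = (masks[0].shape[1], masks[0].shape[0])
    projections = list(projections)
    rows = []

    def _evaluate(g, projs, iteration, shifts):
        overlaps = []
        bps = []
        for i, (m, p) in enumerate(zip(masks, projs)):
            bp = backproject(g, p, image_size)
            bps.append(bp)
            ov, dc = overlap_ratio(bp, m), dice(bp, m)
            overlaps.append(ov)
            rows.append({"iteration": iteration, "view": i, "overlap": ov,
                         "dice": dc, "shift_x": shifts[i][0],
                         "shift_y": shifts[i][1]})
        return float(np.mean(overlaps)), bps

    zero = [(0.0, 0.0)] * len(masks)
    best_grid, best_projs = grid, projections
    best_score, best_bps = _evaluate(grid, projections, 0, zero)

    for it in range(1, max_iter + 1):
        shifts = []
        new_projs = []
        for m, p, bp in zip(masks, best_projs, best_bps):
            if not bp.any():
                shifts.append((0.0, 0.0))
                new_projs.append(p)
                continue
            mx, my = center_of_mass(m)
            bx, by = center_of_mass(bp)
            dxy = (mx - bx, my - by)
            shifts.append(dxy)
            new_projs.append(shift_principal_point(p, dxy))
        fresh = VoxelGrid(grid.resolution, grid.voxel_size_mm,
                          grid.origin_mode)
        try:
            new_grid = carve(fresh, masks, new_projs)
        except EmptyVolumeError:
            break  # abort, keep last valid state
        score, bps = _evaluate(new_grid, new_projs, it, shifts)
        if score >= best_score:
            improved = score - best_score
            best_grid, best_projs, best_bps = new_grid, new_projs, bps
            best_score = score
            if improved < min_improvement:
                break
        else:
            # drop the rejected iteration from the report and stop
            rows = [r for r in rows if r["iteration"] < it]
            break

    report = pd.DataFrame(rows)
    return best_projs, best_grid, report
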