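"""End-to-end reconstruction pipeline: images in, volume and mesh out.

Ties the stages together in acquisition order: segmentation, per-view
TCP estimation, sinusoid outlier correction, principal-point update,
carving, optional pose refinement, tool removal, surface extraction and
volume reporting.  Stage failures propagate with a stage-tagged message
and partial outputs are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import camera, carving, silhouette
from .errors import ConfigError, SeedCarveError

__all__ = ["RunConfig", "WORKING_VOLUME_PRESETS", "run_pipeline"]

# working-volume side presets (mm) per seed type
WORKING_VOLUME_PRESETS = {
    "arabidopsis": 1.0,
    "rapeseed": 2.9,
    "barley": 13.0,
    "maize": 13.0,
}


@dataclass
class RunConfig:
    """Resolved configuration of one reconstruction run."""

    images_dir: Path
    calibration: Path
    out_prefix: Path
    resolution: int = 256
    working_volume_mm: float | str = 13.0
    origin_mode: str = "bottom"
    threshold: float | str = "auto"
    foreground: str = "dark"
    min_object_px: int = 16
    max_hole_px: int = 16
    tcp_mode: str = "tool"  # 'tool' | 'none'
    tool_min_tip_width: int = 4
    tool_base_width: int = 60
    tcp_outlier_px: float | None = None
    tool_removal: str = "plane"  # 'none' | 'plane' | 'cone' | 'fit'
    tool_model: carving.ToolModel | None = None
    refine: bool = False
    refine_max_iter: int = 10
    refine_min_improvement: float = 1e-3

    def __post_init__(self) -> None:
        self.images_dir = Path(self.images_dir)
        self.calibration = Path(self.calibration)
        self.out_prefix = Path(self.out_prefix)
        if isinstance(self.working_volume_mm, str):
            key = self.working_volume_mm.lower()
            if key not in WORKING_VOLUME_PRESETS:
                raise ConfigError(
                    f"unknown seed-type preset {self.working_volume_mm!r}; "
                    f"known: {sorted(WORKING_VOLUME_PRESETS)}")
            self.working_volume_mm = WORKING_VOLUME_PRESETS[key]


def _stage(name: str):
    """Decorator tagging exceptions with the pipeline stage they hit."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SeedCarveError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc

        return inner

    return wrap


@_stage("load")
def _load_images(cfg: RunConfig) -> list[np.ndarray]:
    if not cfg.calibration.exists():
        raise ConfigError(f"calibration file missing: {cfg.calibration}")
    paths = sorted(p for p in cfg.images_dir.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise ConfigError(f"no PNG/TIFF images in {cfg.images_dir}")
    images = []
    for p in paths:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img.mean(axis=-1)
        images.append(img)
    return images


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full reconstruction and write all outputs.

    Returns the summary dictionary that is also written to
    ``<out_prefix>_summary.json``.
    """
    images = _load_images(cfg)
    intr, geom = camera.load_calibration(cfg.calibration)
    if len(images) != geom.n_views:
        raise ConfigError(
            f"{len(images)} images but {geom.n_views} calibration angles")

    masks = _stage("segment")(lambda: [
        silhouette.segment(im, threshold=cfg.threshold,
                           min_object_px=cfg.min_object_px,
                           max_hole_px=cfg.max_hole_px,
                           foreground=cfg.foreground)
        for im in images
    ])()

    projections = [camera.build_projection(intr, a, geom.working_distance_mm,
                                           view_index=i)
                   for i, a in enumerate(geom.angles_deg)]

    tcp_corrected = 0
    if cfg.tcp_mode == "tool":
        profile = silhouette.ToolProfile(cfg.tool_min_tip_width,
                                         cfg.tool_base_width)
        estimates = _stage("tcp")(lambda: [
            silhouette.find_tcp(m, profile, view_index=i)
            for i, m in enumerate(masks)
        ])()
        if len(estimates) >= 4:
            estimates = silhouette.correct_tcp_series(
                estimates, geom.angles_deg, outlier_px=cfg.tcp_outlier_px)
        tcp_corrected = sum(e.corrected for e in estimates)
        projections = [camera.set_principal_point(p, (e.x, e.y),
                                                  intr.image_size)
                       for p, e in zip(projections, estimates)]

    grid = carving.VoxelGrid.for_working_volume(
        float(cfg.working_volume_mm), cfg.resolution, cfg.origin_mode)
    grid = _stage("carve")(carving.carve)(grid, masks, projections)

    report = None
    if cfg.refine:
        projections, grid, report = _stage("refine")(carving.refine_poses)(
            grid, masks, projections, max_iter=cfg.refine_max_iter,
            min_improvement=cfg.refine_min_improvement)

    fitted_tool = None
    if cfg.tool_removal == "plane":
        tool = cfg.tool_model or carving.ToolModel(0.05, 0.5, 0.0, -1.0)
        grid = carving.remove_tool_known(grid, tool, mode="plane")
    elif cfg.tool_removal == "cone":
        if cfg.tool_model is None:
            raise ConfigError("tool_removal='cone' needs a tool_model")
        grid = carving.remove_tool_known(grid, cfg.tool_model, mode="cone")
    elif cfg.tool_removal == "fit":
        grid, fitted_tool = _stage("tool")(carving.remove_tool_fit)(grid)
    elif cfg.tool_removal != "none":
        raise ConfigError(f"unknown tool_removal {cfg.tool_removal!r}")

    vol = carving.volume(grid)
    mesh = carving.extract_surface(grid)

    out = cfg.out_prefix
    out.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(f"{out}_surface.ply")
    mesh.export(f"{out}_surface.obj")
    np.save(f"{out}_voxels.npy", grid.occupancy)
    sidecar = {
        "resolution": grid.resolution,
        "voxel_size_mm": grid.voxel_size_mm,
        "origin_mode": grid.origin_mode,
        "array_order": "ix, iy, iz (x right, y up, z toward camera at 0 deg)",
    }
    with open(f"{out}_voxels.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    if report is not None:
        report.to_csv(f"{out}_qc.csv", index=False)

    summary = {
        "volume_mm3": vol,
        "mesh_volume_mm3": float(mesh.volume) if mesh.is_watertight else None,
        "n_views": geom.n_views,
        "resolution": grid.resolution,
        "voxel_size_mm": grid.voxel_size_mm,
        "tcp_estimates_corrected": tcp_corrected,
        "refined": bool(cfg.refine),
        "fitted_tool": repr(fitted_tool) if fitted_tool is not None else None,
    }
    with open(f"{out}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
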