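import numpy as np
import pytest
from scipy import ndimage

from seedcarve import camera, carving
from seedcarve.carving import ToolModel, VoxelGrid
from seedcarve.errors import (
    EmptyMaskError,
    EmptyVolumeError,
    FitFailureError,
    GeometryError,
)


def _digitized_sphere(resolution, side, radius, center=(0.0, 0.0, 0.0)):
    g = VoxelGrid(resolution, side / resolution, "center")
    xs, ys, zs = g.axis_coords()
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
    occ = ((x - center[0]) ** 2 + (y - center[1]) ** 2
           + (z - center[2]) ** 2) <= radius**2
    return VoxelGrid(resolution, side / resolution, "center", occupancy=occ)


class TestCarve:
    def test_all_ones_masks_keep_every_voxel(self):
        intr = camera.Intrinsics(1000.0, (63.5, 63.5), 0.00345, (128, 128))
        projs = [camera.build_projection(intr, a, 100.0) for a in (0, 90)]
        masks = [np.ones((128, 128), bool)] * 2
        grid = VoxelGrid(16, 0.01, "center")
        out = carving.carve(grid, masks, projs)
        assert out.occupancy.all()

    def test_empty_mask_refused(self):
        intr = camera.Intrinsics(1000.0, (63.5, 63.5), 0.00345, (128, 128))
        projs = [camera.build_projection(intr, 0, 100.0)]
        with pytest.raises(EmptyMaskError):
            carving.carve(VoxelGrid(8, 0.01), [np.zeros((128, 128), bool)],
                          projs)

    def test_disjoint_masks_raise_empty_result(self):
        intr = camera.Intrinsics(1000.0, (63.5, 63.5), 0.00345, (128, 128))
        projs = [camera.build_projection(intr, a, 100.0) for a in (0, 180)]
        m1 = np.zeros((128, 128), bool)
        m1[:10, :10] = True
        m2 = np.zeros((128, 128), bool)
        m2[-10:, -10:] = True
        with pytest.raises(EmptyVolumeError):
            carving.carve(VoxelGrid(16, 0.01), [m1, m2], projs)

    def test_two_orthogonal_disks_give_steinmetz_volume(self):
        # parallel-like geometry: two circular masks 90 degrees apart carve
        # the bicylinder of volume 16/3 r^3, 27.3% above the sphere
        r, d = 1.0, 10000.0
        f = 2.0e6  # object-space pixel = d/f = 5 um
        intr = camera.Intrinsics(f, (255.5, 255.5), 0.005, (512, 512))
        rho = camera.projected_ball_radius_px(r, d, f)
        yy, xx = np.mgrid[0:512, 0:512]
        disk = (xx - 255.5) ** 2 + (yy - 255.5) ** 2 <= rho**2
        projs = [camera.build_projection(intr, a, d, i)
                 for i, a in enumerate((0.0, 90.0))]
        grid = VoxelGrid(128, 2.2 / 128, "center")
        out = carving.carve(grid, [disk, disk], projs)
        v = carving.volume(out)
        steinmetz = 16.0 / 3.0 * r**3
        assert v == pytest.approx(steinmetz, rel=0.02)
        sphere = 4.0 / 3.0 * np.pi * r**3
        assert (steinmetz - sphere) / sphere == pytest.approx(4 / np.pi - 1,
                                                              abs=1e-12)

    def test_monotone_in_views(self, small_ball_scene):
        _, _, masks, projs, _ = small_ball_scene
        g_few = carving.carve(VoxelGrid(48, 3.3 / 48), masks[:4], projs[:4])
        g_all = carving.carve(VoxelGrid(48, 3.3 / 48), masks, projs)
        # a superset of masks can only remove more voxels
        assert not (g_all.occupancy & ~g_few.occupancy).any()

    def test_visual_hull_contains_the_object(self, small_ball_scene):
        spec, _, masks, projs, _ = small_ball_scene
        g = carving.carve(VoxelGrid(48, 3.3 / 48), masks, projs)
        inner = _digitized_sphere(48, 3.3, 1.5 - 3.3 / 48)  # one-shell margin
        assert not (inner.occupancy & ~g.occupancy).any()
        assert carving.volume(g) >= 4 / 3 * np.pi * 1.5**3 - (3.3 / 48) ** 3

    def test_result_independent_of_view_order(self, small_ball_scene):
        _, _, masks, projs, _ = small_ball_scene
        a = carving.carve(VoxelGrid(32, 3.3 / 32), masks[:6], projs[:6])
        order = [3, 0, 5, 1, 4, 2]
        b = carving.carve(VoxelGrid(32, 3.3 / 32),
                          [masks[i] for i in order],
                          [projs[i] for i in order])
        assert (a.occupancy == b.occupancy).all()


class TestVolumeAndSurface:
    def test_volume_trivia(self):
        g = VoxelGrid(8, 0.5, "center",
                      occupancy=np.zeros((8, 8, 8), bool))
        assert carving.volume(g) == 0.0
        g2 = VoxelGrid(8, 0.5, "center")
        assert carving.volume(g2) == pytest.approx(4.0**3)

    def test_digitized_sphere_volume(self):
        g = _digitized_sphere(256, 3.3, 1.5)
        assert carving.volume(g) == pytest.approx(4 / 3 * np.pi * 1.5**3,
                                                  rel=0.002)

    def test_single_voxel_mesh(self):
        occ = np.zeros((4, 4, 4), bool)
        occ[2, 2, 2] = True
        g = VoxelGrid(4, 0.1, "center", occupancy=occ)
        mesh = carving.extract_surface(g)
        assert mesh.is_watertight
        # the 0.5-isosurface bevels an isolated voxel down to the dual
        # octahedron (volume s^3/6); at object scale this shell effect
        # vanishes (see the digitized-ball test)
        assert 0.1**3 / 6 <= mesh.volume <= 0.1**3
        xs, ys, zs = g.axis_coords()
        np.testing.assert_allclose(mesh.vertices.mean(axis=0),
                                   [xs[2], ys[2], zs[2]], atol=1e-9)

    def test_ball_mesh_volume_and_topology(self):
        g = _digitized_sphere(128, 3.3, 1.5)
        mesh = carving.extract_surface(g)
        assert mesh.is_watertight
        assert mesh.euler_number == 2  # genus-0 closed surface
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 1.5**3,
                                            rel=0.01)
        # voxel-count and mesh-enclosed volume agree within a voxel shell
        v_count = carving.volume(g)
        shell = 4 * np.pi * 1.5**2 * g.voxel_size_mm
        assert abs(mesh.volume - v_count) <= shell

    def test_empty_grid_cannot_be_meshed(self):
        g = VoxelGrid(8, 0.1, "center",
                      occupancy=np.zeros((8, 8, 8), bool))
        with pytest.raises(EmptyVolumeError):
            carving.extract_surface(g)


def _tool_fixture(resolution=96, side=4.0):
    g = VoxelGrid(resolution, side / resolution, "center")
    xs, ys, zs = g.axis_coords()
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
    tool = ToolModel(0.12, 0.8, tip_y_mm=0.0, base_y_mm=-2.0)
    rad = np.hypot(x, z)
    cone = (y <= 0.0) & (rad <= tool.radius_at(np.clip(y, None, 0.0)))
    return g, (x, y, z), tool, cone


class TestToolRemoval:
    def test_known_cone_empties_pure_tool(self):
        g, _, tool, cone = _tool_fixture()
        g.occupancy = cone.copy()
        out = carving.remove_tool_known(g, tool, mode="cone")
        assert not out.occupancy.any()

    def test_plane_cut_keeps_disjoint_seed(self):
        g, (x, y, z), tool, cone = _tool_fixture()
        ball = x**2 + (y - 0.9) ** 2 + z**2 <= 0.64
        g.occupancy = (cone | ball).copy()
        out = carving.remove_tool_known(g, tool, mode="plane")
        assert out.occupancy.sum() == ball[:, g.axis_coords()[1] > 0, :].sum()

    def test_known_cone_matches_pointwise_oracle(self):
        g, (x, y, z), tool, cone = _tool_fixture()
        ball = x**2 + (y - 0.5) ** 2 + z**2 <= 0.49
        g.occupancy = (cone | ball).copy()
        out = carving.remove_tool_known(g, tool, mode="cone",
                                        dilate_voxels=0.0)
        inside_cone = (y <= tool.tip_y_mm) & (np.hypot(x, z)
                                              <= tool.radius_at(y))
        assert (out.occupancy == ((cone | ball) & ~inside_cone)).all()

    def test_fit_on_pure_cone_recovers_tip_and_empties(self):
        g, _, tool, cone = _tool_fixture()
        g.occupancy = cone.copy()
        out, fitted = carving.remove_tool_fit(g, bottom_frac=0.6,
                                              tip_radius_mm=0.12)
        assert not out.occupancy.any()
        assert abs(fitted.tip_y_mm - tool.tip_y_mm) <= g.voxel_size_mm

    def test_fit_without_tool_fails(self):
        g, (x, y, z), _, _ = _tool_fixture()
        g.occupancy = (x**2 + y**2 + z**2 <= 1.0).copy()
        with pytest.raises(FitFailureError):
            carving.remove_tool_fit(g)

    def test_fit_with_overlapping_seed_preserves_seed_volume(self):
        g, (x, y, z), tool, cone = _tool_fixture()
        ball = x**2 + (y - 0.5) ** 2 + z**2 <= 0.49
        assert (cone & ball).any()  # genuine overlap
        g.occupancy = (cone | ball).copy()
        out, _ = carving.remove_tool_fit(g, bottom_frac=0.6,
                                         tip_radius_mm=0.12,
                                         dilate_voxels=0.5)
        truth = 4 / 3 * np.pi * 0.7**3
        assert carving.volume(out) == pytest.approx(truth, rel=0.02)


class TestBackprojection:
    def test_empty_grid_gives_blank_mask(self):
        intr = camera.Intrinsics(1000.0, (63.5, 63.5), 0.00345, (128, 128))
        p = camera.build_projection(intr, 0.0, 100.0)
        g = VoxelGrid(8, 0.05, "center",
                      occupancy=np.zeros((8, 8, 8), bool))
        assert not carving.backproject(g, p, intr.image_size).any()

    def test_single_voxel_projects_to_filled_quad(self):
        intr = camera.Intrinsics(2000.0, (63.5, 63.5), 0.00345, (128, 128))
        p = camera.build_projection(intr, 0.0, 50.0)
        occ = np.zeros((8, 8, 8), bool)
        occ[4, 4, 4] = True
        g = VoxelGrid(8, 0.1, "center", occupancy=occ)
        bp = carving.backproject(g, p, intr.image_size)
        # voxel corner projections bound the filled patch
        xs, ys, zs = g.axis_coords()
        assert bp.any()
        rows, cols = np.nonzero(bp)
        uv = camera.project(p, np.array(
            [[xs[4] + sx, ys[4] + sy, zs[4] + sz, 1.0]
             for sx in (-0.05, 0.05) for sy in (-0.05, 0.05)
             for sz in (-0.05, 0.05)]))
        assert cols.min() >= np.floor(uv[:, 0].min())
        assert cols.max() <= np.ceil(uv[:, 0].max())
        assert rows.min() >= np.floor(uv[:, 1].min())
        assert rows.max() <= np.ceil(uv[:, 1].max())

    def test_reprojection_sandwich_of_carved_ball(self):
        # carve a ball whose voxels project to about one pixel, then
        # back-project: the mask must match the segmentation within 1 px
        from seedcarve.camera import Intrinsics, build_projection
        from seedcarve.synthgen import (SceneSpec, SphereSpec,
                                        masks_from_stack, render_stack)

        intr = Intrinsics(4000.0, (159.5, 159.5), 0.00345, (320, 320))
        spec = SceneSpec(objects=(SphereSpec(0.8),), intrinsics=intr,
                         d_mm=69.9,
                         angles_deg=tuple(i * 60.0 for i in range(6)))
        images, _ = render_stack(spec)
        masks = masks_from_stack(images, spec)
        projs = [build_projection(intr, a, 69.9, i)
                 for i, a in enumerate(spec.angles_deg)]
        g = carving.carve(VoxelGrid(96, 1.8 / 96, "center"), masks, projs)
        bp = carving.backproject(g, projs[0], intr.image_size)
        m = masks[0]
        assert not (ndimage.binary_erosion(m) & ~bp).any()
        assert not (bp & ~ndimage.binary_dilation(m)).any()


class TestMaskMetrics:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        b = ~a
        assert carving.overlap_ratio(a, a) == 1.0
        assert carving.dice(a, a) == 1.0
        assert carving.overlap_ratio(a, b) == 0.0
        assert carving.dice(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.flat[:100] = True
        b.flat[50:150] = True
        assert carving.overlap_ratio(a, b) == pytest.approx(1 / 3)
        assert carving.dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        e = np.zeros((5, 5), bool)
        assert carving.overlap_ratio(e, e) == 1.0
        assert carving.dice(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            carving.dice(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestGridValidation:
    def test_invalid_grids(self):
        with pytest.raises(GeometryError):
            VoxelGrid(1, 0.1)
        with pytest.raises(GeometryError):
            VoxelGrid(8, -0.1)
        with pytest.raises(GeometryError):
            VoxelGrid(8, 0.1, "sideways")

    def test_bottom_mode_puts_tcp_on_bottom_face(self):
        g = VoxelGrid(8, 0.5, "bottom")
        xs, ys, zs = g.axis_coords()
        assert ys.min() == pytest.approx(0.25)   # first center above TCP
        assert xs.min() == pytest.approx(-1.75)  # centred laterally
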