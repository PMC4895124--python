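import numpy as np
import pytest

from seedcarve.camera import Intrinsics, build_projection
from seedcarve.synthgen import SceneSpec, SphereSpec, masks_from_stack, render_stack


def triangle_mask(height=50, width=41, apex=(20, 10), slope=0.6):
    """Exact triangular tool silhouette with apex at (x, y)."""
    mask = np.zeros((height, width), dtype=bool)
    ax, ay = apex
    for y in range(ay, height):
        half = (y - ay) * slope
        lo = max(0, int(np.ceil(ax - half)))
        hi = min(width - 1, int(np.floor(ax + half)))
        mask[y, lo:hi + 1] = True
    return mask


@pytest.fixture(scope="session")
def small_ball_scene():
    """Downscaled bearing-ball acquisition: 12 views on a 320x320 sensor."""
    intr = Intrinsics(focal_length_px=4000.0, principal_point=(159.5, 159.5),
                      pixel_size_mm=0.00345, image_size=(320, 320))
    spec = SceneSpec(objects=(SphereSpec(1.5),), intrinsics=intr, d_mm=69.9,
                     angles_deg=tuple(i * 30.0 for i in range(12)))
    images, truth = render_stack(spec)
    masks = masks_from_stack(images, spec)
    projections = [build_projection(intr, a, spec.d_mm, view_index=i)
                   for i, a in enumerate(spec.angles_deg)]
    return spec, images, masks, projections, truth
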