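"""Silhouette segmentation, tool-center-point estimation and registration.

Masks are plain boolean ``numpy`` arrays in image convention (row =
``y`` downward, column = ``x`` rightward), ``True`` at foreground (seed
plus gripping tool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, morphology

from .errors import (
    DegenerateToolError,
    EmptyMaskError,
    FitFailureError,
    SeedCarveError,
    ToolNotFoundError,
)

__all__ = [
    "ToolProfile",
    "TcpEstimate",
    "segment",
    "find_tcp",
    "correct_tcp_series",
    "register_by_template",
]


@dataclass(frozen=True)
class ToolProfile:
    """What the tool silhouette is expected to look like.

    The vacuum-nozzle gripper is a truncated cone entering the image
    from the bottom border and narrowing toward its tip (the TCP).
    """

    min_tip_width: int
    expected_base_width: int

    def __post_init__(self) -> None:
        if not 0 < self.min_tip_width < self.expected_base_width:
            raise SeedCarveError(
                "require 0 < min_tip_width < expected_base_width")


@dataclass(frozen=True)
class TcpEstimate:
    """Pixel location of the tool center point in one view."""

    x: float
    y: float
    view_index: int = 0
    corrected: bool = False


def segment(gray: np.ndarray,
            threshold: float | str = "auto",
            min_object_px: int = 16,
            max_hole_px: int = 16,
            foreground: str = "dark") -> np.ndarray:
    """Threshold a gray-value image into a cleaned binary silhouette.

    Foreground is everything darker (default; seeds and tool are imaged
    against a bright white background) or brighter than the threshold.
    Connected components smaller than ``min_object_px`` are discarded as
    noise and interior holes of at most ``max_hole_px`` pixels (e.g.
    specular reflections on the tool) are filled.

    Parameters
    ----------
    threshold
        A fixed gray value, or ``"auto"`` for Otsu's method.
    """
    img = np.asarray(gray)
    if img.ndim != 2:
        raise SeedCarveError("segment expects a single-channel image")
    if threshold == "auto":
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    if foreground == "dark":
        mask = img <= thr
    elif foreground == "bright":
        mask = img > thr
    else:
        raise SeedCarveError("foreground must be 'dark' or 'bright'")
    if min_object_px > 1:
        # keep exactly the components of >= min_object_px pixels
        mask = morphology.remove_small_objects(mask,
                                               max_size=min_object_px - 1)
    if max_hole_px > 0:
        # fill holes of area <= max_hole_px
        mask = morphology.remove_small_holes(mask, max_size=max_hole_px)
    if not mask.any():
        raise EmptyMaskError("segmentation produced an empty mask")
    if mask.all():
        raise EmptyMaskError(
            "thresholding found no background; image appears uniform")
    return mask


def _bottom_component(mask: np.ndarray) -> np.ndarray:
    """The connected component touching the bottom image border.

    If several components touch the border the widest one (the tool) is
    used; detached seed fragments are ignored.
    """
    labels = measure.label(mask, connectivity=2)
    bottom = labels[-1]
    ids, counts = np.unique(bottom[bottom > 0], return_counts=True)
    if ids.size == 0:
        raise ToolNotFoundError("no foreground touches the bottom border")
    return labels == ids[np.argmax(counts)]


def find_tcp(mask: np.ndarray, profile: ToolProfile,
             view_index: int = 0, jitter_px: int = 1) -> TcpEstimate:
    """Locate the tool center point from the tool silhouette.

    Following the tool's left and right edges upward from the bottom
    border:

    1. scan line by line while the visible tool width decreases (with a
       ``jitter_px`` aliasing allowance) and stays above the minimum tip
       width;
    2. ``x_tcp`` is the mean of all left/right edge x-positions found;
    3. each edge is then tracked independently as long as it keeps
       approaching ``x_tcp`` (rightmost point of the left edge, leftmost
       point of the right edge), which bridges partial occlusion of the
       tip by the seed;
    4. ``y_tcp`` is the smaller y (the higher point) of the two.
    """
    comp = _bottom_component(mask)
    h = comp.shape[0]
    rows_any = comp.any(axis=1)
    # per-row edges; argmax finds first True from either side
    left = np.where(rows_any, comp.argmax(axis=1), -1)
    right = np.where(rows_any, comp.shape[1] - 1
                     - comp[:, ::-1].argmax(axis=1), -1)
    width = np.where(rows_any, right - left + 1, 0)

    # step 1: upward while width non-increasing (jitter allowance) and
    # above the minimum tip width
    y = h - 1
    min_width = width[y]
    start_width = width[y]
    edge_rows = [y]
    while y - 1 >= 0 and rows_any[y - 1]:
        w_next = width[y - 1]
        if w_next > min_width + jitter_px:
            break  # edges diverge: seed bulge or tip passed
        if w_next <= profile.min_tip_width:
            break
        y -= 1
        min_width = min(min_width, width[y])
        edge_rows.append(y)
    if min_width >= start_width:
        raise DegenerateToolError("tool width never decreases")
    rows = np.asarray(edge_rows)

    # step 2
    x_tcp = float(np.concatenate([left[rows], right[rows]]).mean())

    # step 3: track each edge while it keeps approaching x_tcp
    def _track(edge: np.ndarray) -> int:
        y_best = rows[-1]
        d_best = abs(edge[y_best] - x_tcp)
        yy = y_best
        while yy - 1 >= 0 and rows_any[yy - 1]:
            d_next = abs(edge[yy - 1] - x_tcp)
            if d_next > d_best + jitter_px:
                break  # moving away from the axis again
            yy -= 1
            if d_next < d_best:
                d_best, y_best = d_next, yy
        return int(y_best)

    y_left = _track(left)
    y_right = _track(right)
    y_tcp = float(min(y_left, y_right))
    return TcpEstimate(x=x_tcp, y=y_tcp, view_index=view_index)


def _fit_sinusoid(angles_rad: np.ndarray, y: np.ndarray,
                  weights: np.ndarray) -> np.ndarray:
    """Weighted LS fit of ``y = A sin(a) + B cos(a) + C``."""
    design = np.column_stack([np.sin(angles_rad), np.cos(angles_rad),
                              np.ones_like(angles_rad)])
    wsqrt = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(design * wsqrt[:, None], y * wsqrt,
                               rcond=None)
    return coef


def correct_tcp_series(estimates: list[TcpEstimate],
                       angles_deg,
                       outlier_px: float | None = None,
                       correct_x: bool = False,
                       max_iter: int = 5) -> list[TcpEstimate]:
    """Replace outliers in a TCP series by a robust sinusoid fit.

    Lateral play of the tool makes the true TCP move on a small
    elliptic trajectory over a full turn, so its image y-coordinate is a
    sinusoid of the rotation angle, ``y(a) = amp*sin(a + phase) + c``.
    A least-squares fit with iterative outlier rejection (residual
    beyond twice the MAD-based robust sigma is dropped, at most
    ``max_iter`` refits) identifies views where the tip was occluded or
    mis-detected; their estimates are replaced by the fitted value and
    flagged ``corrected``.

    ``outlier_px`` is the replacement threshold; by default it adapts to
    the robust residual scale (``max(3*sigma_rob, 1 px)``).  With
    ``correct_x`` the same scheme is applied to the x-coordinates (the
    elliptic trajectory implies an x-sinusoid as well); off by default.
    """
    if len(estimates) < 4:
        raise FitFailureError(
            "need at least 4 TCP estimates to fit a 3-parameter sinusoid")
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if angles.size != len(estimates):
        raise FitFailureError("angles and estimates length mismatch")

    def _robust(values: np.ndarray) -> tuple[np.ndarray, float]:
        weights = np.ones_like(values)
        coef = _fit_sinusoid(angles, values, weights)
        for _ in range(max_iter):
            fitted = (coef[0] * np.sin(angles) + coef[1] * np.cos(angles)
                      + coef[2])
            resid = values - fitted
            med = np.median(resid)
            sigma = 1.4826 * np.median(np.abs(resid - med))
            new_w = (np.abs(resid - med)
                     <= max(2.0 * sigma, 1e-9)).astype(float)
            if new_w.sum() < 4 or np.array_equal(new_w, weights):
                break
            weights = new_w
            coef = _fit_sinusoid(angles, values, weights)
        fitted = coef[0] * np.sin(angles) + coef[1] * np.cos(angles) + coef[2]
        resid = values - fitted
        keep = weights > 0
        sigma = float(np.sqrt(np.mean(resid[keep] ** 2))) if keep.any() else 0.0
        return fitted, sigma

    ys = np.array([e.y for e in estimates])
    xs = np.array([e.x for e in estimates])
    fitted_y, sigma_y = _robust(ys)
    thr_y = outlier_px if outlier_px is not None else max(3.0 * sigma_y, 1.0)
    bad = np.abs(ys - fitted_y) > thr_y

    if correct_x:
        fitted_x, sigma_x = _robust(xs)
        thr_x = outlier_px if outlier_px is not None else max(3.0 * sigma_x,
                                                              1.0)
        bad_x = np.abs(xs - fitted_x) > thr_x
    else:
        fitted_x = xs
        bad_x = np.zeros_like(bad)

    out = []
    for i, est in enumerate(estimates):
        if bad[i] or bad_x[i]:
            out.append(TcpEstimate(
                x=float(fitted_x[i]) if bad_x[i] else est.x,
                y=float(fitted_y[i]) if bad[i] else est.y,
                view_index=est.view_index, corrected=True))
        else:
            out.append(est)
    return out


def register_by_template(image: np.ndarray, template: np.ndarray,
                         template_pos: tuple[int, int],
                         search_window: tuple[slice, slice] | None = None,
                         ) -> tuple[int, int, float]:
    """Locate ``template`` in ``image`` by normalized cross-correlation.

    ``template_pos`` is the (row, col) of the template's top-left corner
    in the reference image it was cut from.  Returns the integer shift
    ``(dx, dy)`` (x right, y down) that the image content moved by,
    together with the peak correlation value.  The shift is then applied
    to the view's projection matrix by moving its principal point.
    """
    img = np.asarray(image, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if tpl.std() == 0:
        raise SeedCarveError(
            "flat template: normalized cross-correlation undefined")
    region = img[search_window] if search_window is not None else img
    if any(t > r for t, r in zip(tpl.shape, region.shape)):
        raise SeedCarveError("template larger than search region")
    ncc = feature.match_template(region, tpl, pad_input=False)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    row0 = search_window[0].start or 0 if search_window is not None else 0
    col0 = search_window[1].start or 0 if search_window is not None else 0
    found = (peak[0] + row0, peak[1] + col0)
    dy = int(found[0] - template_pos[0])
    dx = int(found[1] - template_pos[1])
    return dx, dy, float(ncc[peak])


def center_of_mass(mask: np.ndarray) -> tuple[float, float]:
    """Foreground centroid as ``(x, y)`` pixel coordinates."""
    if not mask.any():
        raise EmptyMaskError("center of mass of an empty mask")
    cy, cx = ndimage.center_of_mass(mask)
    return float(cx), float(cy)
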