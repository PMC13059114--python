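"""Assembloid outline extraction and recentering.

The assembloid (a bright, roughly convex free-floating structure on a dark
background) is located by Gaussian smoothing, global thresholding (Otsu by
default), retaining the largest connected foreground component, and taking
the convex hull of that component. The hull doubles as a matching mask for
registration; its geometric centroid anchors the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import SegmentationError
from .frame_io import GrayFrame


@dataclass
class AssembloidMask:
    """Binary mask + convex hull + centroid of one assembloid.

    ``hull`` vertices are subpixel (x, y) points in pixel coordinates
    (origin top-left, x rightward, y downward); ``centroid`` is the mean
    pixel position of the filled hull; ``area_px`` the hull polygon area.
    """

    mask: np.ndarray
    hull: np.ndarray
    centroid: tuple[float, float]
    area_px: float

    @property
    def hull_radius(self) -> float:
        """Max distance from centroid to a hull vertex."""
        d = self.hull - np.asarray(self.centroid)
        return float(np.hypot(d[:, 0], d[:, 1]).max())


def _fill_hull(shape: tuple[int, int], hull_xy: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon

    rr, cc = polygon(hull_xy[:, 1], hull_xy[:, 0], shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def segment_assembloid(
    gray: GrayFrame | np.ndarray,
    smoothing_sigma: float = 2.0,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area_px: int = 1000,
) -> AssembloidMask:
    """Extract the assembloid hull mask from a grayscale frame.

    Raises :class:`SegmentationError` on a constant image or when no
    foreground component reaches ``min_area_px``.
    """
    img = gray.pixels if isinstance(gray, GrayFrame) else np.asarray(gray, float)
    if img.max() == img.min():
        raise SegmentationError("constant image: no assembloid found")
    smoothed = ndimage.gaussian_filter(img, smoothing_sigma)
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise SegmentationError("fixed threshold requested but no value given")
        thr = fixed_threshold
    else:
        thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    labels = label(fg)
    props = regionprops(labels)
    if not props:
        raise SegmentationError("no foreground component: no assembloid found")
    best = max(props, key=lambda r: r.area)
    if best.area < min_area_px:
        raise SegmentationError(
            f"largest component has {best.area} px < min_area_px={min_area_px}: "
            "no assembloid found"
        )
    component = labels == best.label
    ys, xs = np.nonzero(component)
    pts = np.column_stack([xs, ys]).astype(float)
    ch = ConvexHull(pts)
    hull_xy = pts[ch.vertices]  # counter-clockwise in (x, y)
    filled = _fill_hull(component.shape, hull_xy)
    fy, fx = np.nonzero(filled)
    centroid = (float(fx.mean()), float(fy.mean()))
    return AssembloidMask(
        mask=filled, hull=hull_xy, centroid=centroid, area_px=float(ch.volume)
    )


def recenter_frame(
    frame_channels: np.ndarray, centroid: tuple[float, float]
) -> tuple[np.ndarray, tuple[int, int]]:
    """Translate channels so ``centroid`` lands at the image center.

    The shift is integer-rounded (no interpolation); vacated pixels are
    zero-filled. Returns the shifted channels and the applied (dx, dy).
    """
    frame_channels = np.asarray(frame_channels)
    h, w = frame_channels.shape[-2:]
    dx = int(round(w / 2 - centroid[0]))
    dy = int(round(h / 2 - centroid[1]))
    if dx == 0 and dy == 0:
        return frame_channels.copy(), (0, 0)
    out = np.zeros_like(frame_channels)
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[..., dst_y, dst_x] = frame_channels[..., src_y, src_x]
    return out, (dx, dy)
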