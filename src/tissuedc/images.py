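"""Per-cell physical-phenotype features from brightfield frames.

The pipeline mirrors what deformability-cytometry acquisition software does
in real time: segment the cell against the channel background, trace its
outer contour, and reduce the contour plus the interior pixels to six
scalar features — cross-sectional area (µm²), deformation (1 − circularity
of the convex hull), aspect ratio (bounding-box extent along / across the
flow axis, reported as max/min), area ratio (convex-hull area over contour
area), and brightness mean / SD inside the contour.

Deformation is computed on the convex hull of the contour by default (the
community convention; robust to single-pixel roughness); pass
``use_hull=False`` for the raw-contour variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import draw, filters, measure, morphology

from .exceptions import GeometryError, ParameterError

__all__ = [
    "SegmentationResult",
    "segment_cell",
    "shape_features",
    "brightness_stats",
    "equivalent_radius",
    "extract_features",
    "DEFAULT_PIXEL_SIZE",
]

#: Default camera pixel size in µm/px, typical for this instrument class.
DEFAULT_PIXEL_SIZE = 0.34

#: Objects smaller than this many pixels are discarded as noise.
MIN_OBJECT_PX = 10


@dataclass
class SegmentationResult:
    """Outcome of segmenting one frame.

    ``contour`` is the outer boundary of the largest foreground object as an
    (n, 2) array of (x, y) pixel coordinates, or ``None`` when the frame
    holds no object above the minimum pixel count. ``n_objects`` counts all
    detected foreground objects.
    """

    contour: np.ndarray | None
    n_objects: int
    mask: np.ndarray | None = None

    @property
    def found(self) -> bool:
        return self.contour is not None


def segment_cell(frame: np.ndarray, background: np.ndarray | None = None,
                 min_object_px: int = MIN_OBJECT_PX) -> SegmentationResult:
    """Segment the largest cell in a brightfield frame.

    The background is subtracted (either an explicit reference frame or the
    frame's median as a flat estimate), the absolute difference is
    thresholded with Otsu's method, holes are filled, small specks removed,
    and the outer contour of the largest connected component returned.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ParameterError("frame must be a non-empty 2-D array")
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != frame.shape:
            raise ParameterError("background shape must match frame shape")
        diff = np.abs(frame - background)
    else:
        diff = np.abs(frame - np.median(frame))

    if np.ptp(diff) == 0:
        return SegmentationResult(contour=None, n_objects=0)
    thr = filters.threshold_otsu(diff)
    mask = diff > thr
    mask = ndimage.binary_fill_holes(mask)
    # drop specks below the minimum object size (max_size is exclusive-keep)
    mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    labels, n_objects = ndimage.label(mask)
    if n_objects == 0:
        return SegmentationResult(contour=None, n_objects=0)

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_objects + 1))
    largest = labels == (int(np.argmax(sizes)) + 1)
    # sub-pixel outer boundary; find_contours yields (row, col) -> map to (x, y)
    contours = measure.find_contours(largest.astype(float), 0.5)
    if not contours:  # pragma: no cover - nonempty mask always has a contour
        return SegmentationResult(contour=None, n_objects=n_objects)
    boundary = max(contours, key=len)
    contour = np.column_stack([boundary[:, 1], boundary[:, 0]])
    return SegmentationResult(contour=contour, n_objects=n_objects, mask=largest)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _smooth_closed(contour: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of the vertex chain of a closed contour."""
    kernel = np.ones(window) / window
    half = window // 2
    ext = np.vstack([contour[-half:], contour, contour[:half]])
    return np.column_stack([np.convolve(ext[:, 0], kernel, "valid"),
                            np.convolve(ext[:, 1], kernel, "valid")])


def shape_features(contour: np.ndarray, pixel_size: float = DEFAULT_PIXEL_SIZE,
                   use_hull: bool = True, smooth_window: int = 0
                   ) -> dict[str, float]:
    """Contour geometry: area (µm²), deformation, aspect and area ratios.

    deformation = 1 − 2·sqrt(π·A)/P with A, P the convex-hull area and
    perimeter (raw contour if ``use_hull`` is False); area_ratio =
    A_hull / A_contour; aspect_ratio = max/min of the axis-aligned
    bounding-box extents, so it is ≥ 1 for any orientation.

    ``smooth_window`` (odd, ≥ 3 to take effect) applies a circular moving
    average to the vertex chain before the deformation computation only —
    pixel-step boundaries otherwise inflate the hull perimeter of smooth
    shapes; area, area_ratio and aspect_ratio always use the raw contour.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3 or contour.shape[1] != 2:
        raise GeometryError("contour must be an (n>=3, 2) vertex array")
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    area_contour = _polygon_area(contour)
    if area_contour <= 0:
        raise GeometryError("degenerate contour with zero enclosed area")
    try:
        hull = ConvexHull(contour)
    except QhullError as exc:
        raise GeometryError(f"degenerate contour: {exc}") from exc
    hull_poly = contour[hull.vertices]
    area_hull = _polygon_area(hull_poly)

    deform_contour = contour
    if smooth_window >= 3 and contour.shape[0] > smooth_window:
        deform_contour = _smooth_closed(contour, smooth_window)
    if use_hull:
        dhull = ConvexHull(deform_contour)
        dpoly = deform_contour[dhull.vertices]
        deformation = (1.0 - 2.0 * np.sqrt(np.pi * _polygon_area(dpoly))
                       / _perimeter(dpoly))
    else:
        deformation = (1.0 - 2.0 * np.sqrt(np.pi * _polygon_area(deform_contour))
                       / _perimeter(deform_contour))
    extents = contour.max(axis=0) - contour.min(axis=0)
    if extents.min() <= 0:
        raise GeometryError("degenerate contour with zero bounding-box extent")
    return {
        "area_um2": area_contour * pixel_size**2,
        "deformation": float(max(deformation, 0.0)),
        "aspect_ratio": float(extents.max() / extents.min()),
        "area_ratio": float(area_hull / area_contour),
    }


def brightness_stats(frame: np.ndarray, contour: np.ndarray) -> tuple[float, float]:
    """Mean and population SD of pixel values strictly inside the contour."""
    frame = np.asarray(frame, dtype=float)
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise GeometryError("contour must be an (n>=3, 2) vertex array")
    # polygon2mask expects (row, col) = (y, x)
    mask = draw.polygon2mask(frame.shape, contour[:, ::-1])
    if not mask.any():
        raise GeometryError("contour encloses no pixels")
    inside = frame[mask]
    return float(inside.mean()), float(inside.std())


def equivalent_radius(area_um2: float) -> float:
    """Radius (µm) of the circle with the given cross-sectional area."""
    area_um2 = float(area_um2)
    if area_um2 <= 0:
        raise ParameterError(f"area must be positive, got {area_um2}")
    return float(np.sqrt(area_um2 / np.pi))


def extract_features(frame: np.ndarray, pixel_size: float = DEFAULT_PIXEL_SIZE,
                     background: np.ndarray | None = None,
                     use_hull: bool = True,
                     smooth_window: int = 5) -> dict[str, float] | None:
    """Segment one frame and compute the full six-feature set.

    Returns ``None`` when the frame contains no segmentable object. The
    pixel-boundary contour is smoothed (window ``smooth_window``) for the
    deformation estimate; see :func:`shape_features`.
    """
    seg = segment_cell(frame, background=background)
    if not seg.found:
        return None
    feats = shape_features(seg.contour, pixel_size=pixel_size, use_hull=use_hull,
                           smooth_window=smooth_window)
    avg, sd = brightness_stats(frame, seg.contour)
    feats["brightness_avg"] = avg
    feats["brightness_sd"] = sd
    feats["n_objects"] = seg.n_objects
    return feats
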