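"""Per-frame geometric features from binary object masks.

Every quantity is computed in image convention: x to the right, y down,
origin at the top-left pixel, 0-based frame and pixel indices.  A
:class:`Calibration` converts pixel geometry into physical units —
lengths scale with the mm-per-pixel factor, areas with its square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "Calibration",
    "EllipseFit",
    "DegenerateCalibrationError",
    "EmptyMaskError",
    "UnfittableObjectError",
    "compute_scale_factor",
    "mask_to_polygon",
    "polygon_centroid",
    "mask_area",
    "fit_object_ellipse",
    "axis_ratio",
]

FLAG_REASONS = (
    "none",
    "static_size",
    "size_jump",
    "size_drift",
    "id_switch",
    "size_outlier",
    "speed_outlier",
    "duplicate",
    "infill",
)

#: elongated / bent / undefined posture labels
STATES = ("elongated", "bent", "undefined")


class DegenerateCalibrationError(ValueError):
    """Raised when the two calibration points coincide."""


class EmptyMaskError(ValueError):
    """Raised when a mask contains no foreground pixels."""


class UnfittableObjectError(ValueError):
    """Raised when a contour is too small or degenerate for an ellipse fit."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a recording.

    Parameters
    ----------
    scale : float
        Millimetres per pixel; strictly positive.
    fps : float
        Frames per second of the analysed video; strictly positive.
    """

    scale: float
    fps: float

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not (self.fps > 0):
            raise ValueError(f"fps must be > 0, got {self.fps}")

    def length_mm(self, length_px):
        """Convert a pixel length to mm."""
        return np.asarray(length_px, dtype=float) * self.scale

    def area_mm2(self, area_px):
        """Convert a pixel area (pixel count) to mm^2."""
        return np.asarray(area_px, dtype=float) * self.scale**2


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse fitted to an object contour.

    ``major`` and ``minor`` are full axis lengths (diameters) in pixels,
    with ``major >= minor``; ``angle`` is the major-axis orientation in
    degrees, axial (in ``[0, 180)``).
    """

    center: tuple[float, float]
    major: float
    minor: float
    angle: float

    def __post_init__(self) -> None:
        if not (self.major >= self.minor > 0):
            raise ValueError(
                f"require major >= minor > 0, got {self.major}, {self.minor}"
            )
        if not (0.0 <= self.angle < 180.0):
            raise ValueError(f"angle must lie in [0, 180), got {self.angle}")


def compute_scale_factor(p1, p2, known_distance_mm: float) -> float:
    """mm-per-pixel scale from two image points a known distance apart.

    Raises
    ------
    DegenerateCalibrationError
        If the two points coincide.
    """
    if known_distance_mm <= 0:
        raise ValueError("known_distance_mm must be positive")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    dist = float(np.hypot(*(p2 - p1)))
    if dist == 0.0:
        raise DegenerateCalibrationError("calibration points coincide")
    return known_distance_mm / dist


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest connected foreground component."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Outer contour polygon of the largest foreground component.

    Returns an ``(n, 2)`` array of ``(x, y)`` vertices in a consistent
    winding order, traced at sub-pixel resolution along the 0.5 iso-level
    of the binary mask.
    """
    comp = largest_component(mask)
    # pad so components touching the border still yield a closed contour
    padded = np.pad(comp.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # (row, col) -> (x, y), undo padding
    return contour[:, ::-1] - 1.0


def polygon_centroid(polygon) -> tuple[float, float]:
    """Area centroid of a polygon given as an ``(n, 2)`` vertex array.

    Falls back to the vertex mean (with a warning) for zero-area
    degenerate polygons.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon(verts)
    if poly.area == 0:
        warnings.warn(
            "zero-area polygon; using vertex mean as centroid", stacklevel=2
        )
        c = verts.mean(axis=0)
        return float(c[0]), float(c[1])
    c = poly.centroid
    return float(c.x), float(c.y)


def mask_area(mask: np.ndarray, calibration: Calibration) -> float:
    """Mask area in mm^2: foreground pixel count times scale squared."""
    count = int(np.asarray(mask).astype(bool).sum())
    return float(calibration.area_mm2(count))


def fit_object_ellipse(contour) -> EllipseFit:
    """Least-squares ellipse fit to a contour.

    Axis lengths are full lengths (major >= minor, swapping if the fit
    returns them reversed) and the angle is normalised to [0, 180).

    Raises
    ------
    UnfittableObjectError
        For fewer than 5 contour points or a degenerate fit.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or len(pts) < 5:
        raise UnfittableObjectError(
            f"need >= 5 contour points for an ellipse fit, got {len(pts)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = measure.EllipseModel.from_estimate(pts)
        except AttributeError:  # scikit-image < 0.26
            model = measure.EllipseModel()
            if not model.estimate(pts):
                model = None
    if model is None or not np.all(np.isfinite(_ellipse_params(model))):
        raise UnfittableObjectError("degenerate contour, ellipse fit failed")
    xc, yc, a, b, theta = _ellipse_params(model)
    if a <= 0 or b <= 0:
        raise UnfittableObjectError("ellipse fit returned non-positive axis")
    angle = np.rad2deg(theta)
    if b > a:
        a, b = b, a
        angle += 90.0
    return EllipseFit(
        center=(float(xc), float(yc)),
        major=float(2 * a),
        minor=float(2 * b),
        angle=float(angle % 180.0),
    )


def _ellipse_params(model) -> tuple[float, float, float, float, float]:
    try:
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:
        xc, yc, a, b, theta = model.params
    return float(xc), float(yc), float(a), float(b), float(theta)


def axis_ratio(ellipse: EllipseFit) -> float:
    """Major/minor axis ratio R >= 1 of a fitted ellipse."""
    if ellipse.minor <= 0:
        raise UnfittableObjectError("minor axis is zero; ratio undefined")
    return ellipse.major / ellipse.minor
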