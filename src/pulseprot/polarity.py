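"""Growth-cone fluorescence quantification.

Implements the three immunofluorescence polarity measures used in
growth-cone gradient assays:

* background-subtracted mean ROI intensity per unit area;
* the near/far ratio, obtained by bisecting the traced growth-cone ROI
  with a line drawn through the axon shaft and comparing the
  background-subtracted mean of the gradient-facing ("near") half with
  the opposite ("far") half;
* the center-of-mass shift: the intensity-weighted centroid of the
  fluorescence signal minus that of the brightfield channel, projected
  onto the axis pointing toward the gradient source (positive = toward
  the source; a repulsive redistribution gives a negative projection).

Coordinate conventions: pixel coordinates are 0-based pixel centers,
``(x, y) = (column, row)``.  Pixels exactly on the bisection line belong
to neither half.  Background subtraction applies to the mean and ratio
measures only; centroid weighting uses raw intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import GeometryError, ValidationError

__all__ = [
    "GrowthConeImage",
    "PolarityMeasures",
    "roi_mean_intensity",
    "near_far_ratio",
    "center_of_mass_shift",
    "compute_polarity",
    "load_geometry",
    "rasterize_polygon",
]

Point = tuple[float, float]


@dataclass
class GrowthConeImage:
    """A single growth cone: pixel grids plus quantification geometry.

    Attributes
    ----------
    fluorescence, brightfield : 2-D float arrays of identical shape.
    roi_mask : boolean grid — the traced growth-cone outline.
    background_mask : boolean grid disjoint from the ROI, used for
        background estimation.
    shaft_axis : two distinct points defining the bisection line through
        the axon shaft.
    gradient_source : the position of the gradient source (e.g. pipette
        tip), defining which side of the shaft line is "near".
    """

    fluorescence: np.ndarray
    brightfield: np.ndarray
    roi_mask: np.ndarray
    background_mask: np.ndarray
    shaft_axis: tuple[Point, Point]
    gradient_source: Point

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        shape = self.fluorescence.shape
        for name in ("brightfield", "roi_mask", "background_mask"):
            if getattr(self, name).shape != shape:
                raise GeometryError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if (self.fluorescence < 0).any():
            raise GeometryError("fluorescence intensities must be >= 0")
        if not self.roi_mask.any():
            raise GeometryError("ROI mask is empty")
        if (self.roi_mask & self.background_mask).any():
            raise GeometryError("ROI and background masks overlap")
        (x1, y1), (x2, y2) = self.shaft_axis
        if x1 == x2 and y1 == y2:
            raise GeometryError("shaft axis points must be distinct")


@dataclass
class PolarityMeasures:
    """All polarity measures for one growth cone.

    ``near_far_ratio`` is NaN when the far-half background-subtracted mean
    is not positive (halves are still reported).  ``com_shift_projected``
    is the signed component of the centroid shift along the unit vector
    from the ROI centroid toward the gradient source.
    """

    mean_intensity: float
    near_mean: float
    far_mean: float
    near_far_ratio: float
    n_near: int
    n_far: int
    com_fluor: Point
    com_bright: Point
    com_shift: Point
    com_shift_projected: float


def _pixel_centers(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.nonzero(mask)
    return xs.astype(float), ys.astype(float)


def _background_mean(image: GrowthConeImage) -> float:
    if not image.background_mask.any():
        raise GeometryError("background mask is empty")
    return float(image.fluorescence[image.background_mask].mean())


def roi_mean_intensity(image: GrowthConeImage) -> float:
    """Background-subtracted mean fluorescence per unit area over the ROI.

    Negative results are allowed (the ROI can be dimmer than the chosen
    background region) and reported as-is.
    """
    roi_mean = float(image.fluorescence[image.roi_mask].mean())
    return roi_mean - _background_mean(image)


def _half_masks(image: GrowthConeImage) -> tuple[np.ndarray, np.ndarray]:
    """Split the ROI into near/far halves by the shaft line.

    The signed half-plane test uses the cross product against the shaft
    direction; the sign of the gradient source defines "near".  Pixels
    exactly on the line are excluded from both halves.
    """
    (x1, y1), (x2, y2) = image.shaft_axis
    dx, dy = x2 - x1, y2 - y1
    ys, xs = np.mgrid[0 : image.fluorescence.shape[0], 0 : image.fluorescence.shape[1]]
    signed = dx * (ys - y1) - dy * (xs - x1)
    sx, sy = image.gradient_source
    source_sign = dx * (sy - y1) - dy * (sx - x1)
    if source_sign == 0:
        raise GeometryError("gradient source lies on the shaft line; near side undefined")
    near = image.roi_mask & (np.sign(signed) == np.sign(source_sign))
    far = image.roi_mask & (np.sign(signed) == -np.sign(source_sign))
    return near, far


def near_far_ratio(image: GrowthConeImage) -> tuple[float, float, float]:
    """Near/far bisection measure.

    Returns ``(near_mean, far_mean, ratio)`` where the means are
    background-subtracted and ``ratio = near_mean / far_mean`` (NaN when
    ``far_mean <= 0``).
    """
    near, far = _half_masks(image)
    if not near.any() or not far.any():
        raise GeometryError("shaft line does not bisect the ROI (one half is empty)")
    bg = _background_mean(image)
    near_mean = float(image.fluorescence[near].mean()) - bg
    far_mean = float(image.fluorescence[far].mean()) - bg
    ratio = near_mean / far_mean if far_mean > 0 else float("nan")
    return near_mean, far_mean, ratio


def _weighted_centroid(values: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> Point:
    total = values.sum()
    if total <= 0:
        raise ValidationError("zero total intensity; center of mass undefined")
    return (float((values * xs).sum() / total), float((values * ys).sum() / total))


def center_of_mass_shift(
    image: GrowthConeImage, restrict_to_roi: bool = True
) -> tuple[Point, Point, Point, float]:
    """Brightfield-corrected intensity-weighted center of mass.

    Each channel's center of mass is the average of all pixel locations
    weighted by intensity; the shift is the fluorescence centroid minus
    the brightfield centroid.  The scalar projection is onto the unit
    vector from the ROI centroid toward the gradient source (positive
    toward the source).

    ``restrict_to_roi=False`` computes both centroids over the whole image
    instead of the traced ROI.
    """
    if restrict_to_roi:
        mask = image.roi_mask
    else:
        mask = np.ones_like(image.roi_mask, dtype=bool)
    xs, ys = _pixel_centers(mask)
    com_f = _weighted_centroid(image.fluorescence[mask], xs, ys)
    com_b = _weighted_centroid(image.brightfield[mask], xs, ys)
    shift = (com_f[0] - com_b[0], com_f[1] - com_b[1])

    rx, ry = _pixel_centers(image.roi_mask)
    centroid = (rx.mean(), ry.mean())
    gx, gy = image.gradient_source
    axis = np.array([gx - centroid[0], gy - centroid[1]])
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("gradient source coincides with the ROI centroid")
    axis /= norm
    projected = float(shift[0] * axis[0] + shift[1] * axis[1])
    return com_f, com_b, shift, projected


def compute_polarity(image: GrowthConeImage, restrict_to_roi: bool = True) -> PolarityMeasures:
    """All polarity measures for one growth cone in a single pass."""
    near, far = _half_masks(image)
    if not near.any() or not far.any():
        raise GeometryError("shaft line does not bisect the ROI (one half is empty)")
    bg = _background_mean(image)
    near_mean = float(image.fluorescence[near].mean()) - bg
    far_mean = float(image.fluorescence[far].mean()) - bg
    ratio = near_mean / far_mean if far_mean > 0 else float("nan")
    com_f, com_b, shift, projected = center_of_mass_shift(image, restrict_to_roi)
    return PolarityMeasures(
        mean_intensity=roi_mean_intensity(image),
        near_mean=near_mean,
        far_mean=far_mean,
        near_far_ratio=ratio,
        n_near=int(near.sum()),
        n_far=int(far.sum()),
        com_fluor=com_f,
        com_bright=com_b,
        com_shift=shift,
        com_shift_projected=projected,
    )


# ---------------------------------------------------------------------------
# Geometry sidecar
# ---------------------------------------------------------------------------


def rasterize_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon.

    Uses the even-odd rule on 0-based pixel centers.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    points = np.column_stack([xs.ravel(), ys.ravel()])
    # contains_points implicitly closes the ring; an explicit CLOSEPOLY code
    # would swallow the final vertex
    inside = MplPath(verts).contains_points(points)
    return inside.reshape(h, w)


def load_geometry(
    path: str | Path,
    fluorescence: np.ndarray,
    brightfield: np.ndarray,
) -> GrowthConeImage:
    """Build a :class:`GrowthConeImage` from a JSON geometry sidecar.

    The sidecar holds ``roi_polygon``, ``background_polygon`` (lists of
    ``[x, y]`` vertices), ``shaft_axis`` (two points) and
    ``gradient_source`` (one point).
    """
    with open(path) as fh:
        geom = json.load(fh)
    for key in ("roi_polygon", "background_polygon", "shaft_axis", "gradient_source"):
        if key not in geom:
            raise GeometryError(f"geometry sidecar missing key {key!r}")
    shape = np.asarray(fluorescence).shape
    roi = rasterize_polygon(geom["roi_polygon"], shape)
    bg = rasterize_polygon(geom["background_polygon"], shape)
    if (roi & bg).any():
        bg &= ~roi
    (p1, p2) = geom["shaft_axis"]
    return GrowthConeImage(
        fluorescence=fluorescence,
        brightfield=brightfield,
        roi_mask=roi,
        background_mask=bg,
        shaft_axis=((p1[0], p1[1]), (p2[0], p2[1])),
        gradient_source=tuple(geom["gradient_source"]),
    )
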